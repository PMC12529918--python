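"""Generic external energy-engine adapter.

Any program that can read a fragment geometry as plain XYZ and print a
single energy can serve as a fragment backend: the adapter writes the
fragment, runs a shell command, parses one number from its output with a
configurable regular expression, and caches the result by a geometry hash
so identical fragments are never dispatched twice.
"""

from __future__ import annotations

import hashlib
import logging
import re
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .potentials import EnergyBackend, Fragment

__all__ = [
    "EngineAdapterSpec",
    "ExternalEngineBackend",
    "external_engine_evaluate",
    "EngineError",
    "EngineExitError",
    "EngineParseError",
    "EngineTimeoutError",
    "geometry_hash",
]

log = logging.getLogger(__name__)


class EngineError(RuntimeError):
    """Base class for external-engine failures."""


class EngineExitError(EngineError):
    pass


class EngineParseError(EngineError):
    pass


class EngineTimeoutError(EngineError):
    pass


@dataclass
class EngineAdapterSpec:
    """How to dispatch one fragment to an external engine.

    ``command_template`` is a shell command with an ``{xyz}`` placeholder
    for the fragment file path.  ``energy_parse_pattern`` is a regex whose
    first group captures the energy (kJ·mol⁻¹) in the command's stdout.
    """

    command_template: str
    energy_parse_pattern: str = r"ENERGY\s*=?\s*(-?\d+\.?\d*(?:[eE][+-]?\d+)?)"
    workdir: str | None = None
    timeout: float = 60.0
    cache: dict[str, float] = field(default_factory=dict)
    dispatch_count: int = 0


def geometry_hash(fragment: Fragment) -> str:
    """Hash of elements + coordinates rounded to 1e-6 Å, in atom order."""
    rounded = np.round(fragment.positions, 6) + 0.0  # normalize -0.0
    h = hashlib.sha256()
    h.update(" ".join(fragment.elements).encode())
    h.update(rounded.tobytes())
    return h.hexdigest()


def _fragment_identity(fragment: Fragment) -> str:
    from collections import Counter

    c = Counter(fragment.elements)
    formula = "".join(f"{el}{n}" for el, n in sorted(c.items()))
    return f"{formula} ({fragment.n_molecules} molecule(s))"


def write_fragment_xyz(fragment: Fragment, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(fragment.elements)}\n")
        fh.write("fragment\n")
        for el, pos in zip(fragment.elements, fragment.positions):
            fh.write(f"{el} {pos[0]:.8f} {pos[1]:.8f} {pos[2]:.8f}\n")


def external_engine_evaluate(spec: EngineAdapterSpec, fragment: Fragment) -> float:
    """Evaluate a fragment energy through the external command.

    Results are cached by geometry hash; cache hits perform no dispatch.
    Non-zero exit status, unparseable output and timeouts raise distinct
    errors, each naming the fragment.
    """
    key = geometry_hash(fragment)
    if key in spec.cache:
        return spec.cache[key]
    ident = _fragment_identity(fragment)
    workdir = Path(spec.workdir) if spec.workdir else Path(tempfile.mkdtemp(prefix="framonc_engine_"))
    workdir.mkdir(parents=True, exist_ok=True)
    xyz_path = workdir / f"fragment_{key[:16]}.xyz"
    write_fragment_xyz(fragment, xyz_path)
    cmd = spec.command_template.format(xyz=str(xyz_path))
    try:
        proc = subprocess.run(
            cmd, shell=True, capture_output=True, text=True,
            timeout=spec.timeout, cwd=str(workdir),
        )
    except subprocess.TimeoutExpired as exc:
        log.error("engine timeout after %.1fs for %s", spec.timeout, ident)
        raise EngineTimeoutError(f"engine timed out for fragment {ident}") from exc
    spec.dispatch_count += 1
    if proc.returncode != 0:
        log.error("engine exit %d for %s: %s", proc.returncode, ident, proc.stderr)
        raise EngineExitError(
            f"engine exited with status {proc.returncode} for fragment {ident}"
        )
    m = re.search(spec.energy_parse_pattern, proc.stdout)
    if m is None:
        log.error("engine output parse failure for %s", ident)
        raise EngineParseError(
            f"could not parse energy from engine output for fragment {ident}"
        )
    energy = float(m.group(1))
    spec.cache[key] = energy
    return energy


class ExternalEngineBackend(EnergyBackend):
    """Fragment-only energy tier delegating to an external command."""

    capabilities = frozenset({"monomer", "dimer"})

    def __init__(self, spec: EngineAdapterSpec, name: str = "external") -> None:
        self.spec = spec
        self.name = name

    def fragment_energy(self, fragment: Fragment) -> float:
        return external_engine_evaluate(self.spec, fragment)
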