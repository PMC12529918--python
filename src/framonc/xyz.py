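"""Extended-XYZ reading and writing.

Implements the common extended-XYZ dialect: line 1 is the atom count,
line 2 a set of ``key=value`` pairs (values quoted when they contain
spaces), including ``Lattice="ax ay az bx by bz cx cy cz"`` and a
``Properties=`` column descriptor, followed by one line per atom.

Two layers are provided: generic :class:`XYZFrame` objects (used for
fragment exchange with external engines and for the pair-interaction
library) and configuration-level helpers that serialize a periodic
:class:`~framonc.system.Configuration` with per-site labels and molecule
indices so that coordinates round-trip exactly at the printed precision.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .system import Box, Configuration, MoleculeInstance, MoleculeTemplate, instance_coordinates

__all__ = ["XYZFrame", "read_frames", "write_frames", "configuration_to_frame", "frame_to_configuration"]

_KV_RE = re.compile(r'(\S+?)=(?:"([^"]*)"|(\S+))')

# 12 decimals: steep short-range pair energies must replay from stored
# geometries to ~1e-6 kJ/mol, which needs coordinates well below 1e-8 A
_COORD_FMT = "%.12f"


@dataclass
class XYZFrame:
    """One extended-XYZ frame: symbols, coordinates, comment key–values."""

    symbols: list[str]
    positions: np.ndarray
    info: dict[str, object] = field(default_factory=dict)
    arrays: dict[str, list] = field(default_factory=dict)  # extra per-atom columns

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.symbols), 3):
            raise ValueError("positions shape mismatch")


def _format_value(v: object) -> str:
    if isinstance(v, bool):
        s = "T" if v else "F"
    elif isinstance(v, float):
        s = repr(v)
    elif isinstance(v, np.ndarray):
        s = " ".join(repr(float(x)) for x in v.ravel())
    else:
        s = str(v)
    if " " in s or s == "":
        return f'"{s}"'
    return s


def _parse_value(s: str) -> object:
    if s == "T":
        return True
    if s == "F":
        return False
    try:
        return int(s)
    except ValueError:
        pass
    try:
        return float(s)
    except ValueError:
        pass
    parts = s.split()
    if len(parts) > 1:
        try:
            return np.array([float(p) for p in parts])
        except ValueError:
            pass
    return s


def _properties_spec(arrays: dict[str, list]) -> str:
    cols = ["species:S:1", "pos:R:3"]
    for name, vals in arrays.items():
        kind = "I" if all(isinstance(v, (int, np.integer)) for v in vals) else "S"
        cols.append(f"{name}:{kind}:1")
    return "=".join(["Properties", ":".join(cols)])


def write_frames(frames: list[XYZFrame], path) -> None:
    """Write frames to an extended-XYZ file (overwrites)."""
    with open(path, "w") as fh:
        for fr in frames:
            fh.write(frame_to_string(fr))


def frame_to_string(fr: XYZFrame) -> str:
    lines = [str(len(fr.symbols))]
    kv = [_properties_spec(fr.arrays)]
    for k, v in fr.info.items():
        kv.append(f"{k}={_format_value(v)}")
    lines.append(" ".join(kv))
    extra_cols = list(fr.arrays.values())
    for i, (sym, pos) in enumerate(zip(fr.symbols, fr.positions)):
        cols = [sym] + [_COORD_FMT % x for x in pos]
        for col in extra_cols:
            cols.append(str(col[i]))
        lines.append(" ".join(cols))
    return "\n".join(lines) + "\n"


def read_frames(path) -> list[XYZFrame]:
    """Read all frames from an extended-XYZ file.

    Malformed frames raise ``ValueError`` naming the frame index; a file
    truncated mid-frame is refused rather than partially read.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames: list[XYZFrame] = []
    i = 0
    while i < len(lines):
        if lines[i].strip() == "":
            i += 1
            continue
        idx = len(frames)
        try:
            natoms = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"frame {idx}: bad atom count line {lines[i]!r}") from exc
        if i + 1 + natoms >= len(lines) + 1 and i + 1 + natoms > len(lines):
            raise ValueError(f"frame {idx}: truncated (expected {natoms} atoms)")
        info: dict[str, object] = {}
        props = "species:S:1:pos:R:3"
        for m in _KV_RE.finditer(lines[i + 1]):
            key = m.group(1)
            raw = m.group(2) if m.group(2) is not None else m.group(3)
            if key == "Properties":
                props = raw
            else:
                info[key] = _parse_value(raw)
        col_spec = props.split(":")
        names = col_spec[0::3]
        kinds = col_spec[1::3]
        widths = [int(w) for w in col_spec[2::3]]
        symbols: list[str] = []
        positions = np.zeros((natoms, 3))
        arrays: dict[str, list] = {
            n: [] for n, w in zip(names, widths) if n not in ("species", "pos")
        }
        for j in range(natoms):
            toks = lines[i + 2 + j].split()
            expected = sum(widths)
            if len(toks) != expected:
                raise ValueError(
                    f"frame {idx}, atom {j}: expected {expected} columns, got {len(toks)}"
                )
            c = 0
            for name, kind, w in zip(names, kinds, widths):
                vals = toks[c : c + w]
                c += w
                if name == "species":
                    symbols.append(vals[0])
                elif name == "pos":
                    positions[j] = [float(v) for v in vals]
                else:
                    arrays[name].append(int(vals[0]) if kind == "I" else vals[0])
        frames.append(XYZFrame(symbols, positions, info, arrays))
        i += 2 + natoms
    return frames


def configuration_to_frame(
    config: Configuration,
    templates: dict[str, MoleculeTemplate],
    info: dict[str, object] | None = None,
) -> XYZFrame:
    """Serialize a periodic configuration: lattice, site labels, molecule ids.

    Orientation quaternions and conformer indices are stored in the comment
    line so that :func:`frame_to_configuration` reconstructs the rigid-body
    state exactly (coordinates to the printed precision).
    """
    symbols: list[str] = []
    labels: list[str] = []
    mol_ids: list[int] = []
    pos_blocks: list[np.ndarray] = []
    for i, mol in enumerate(config.molecules):
        tmpl = templates[mol.template_id]
        coords = instance_coordinates(mol, templates)
        pos_blocks.append(coords)
        symbols.extend(s.element for s in tmpl.sites)
        labels.extend(s.site_label for s in tmpl.sites)
        mol_ids.extend([i] * tmpl.n_sites)
    L = config.box.edge_lengths
    full_info: dict[str, object] = {
        "Lattice": np.array(
            [L[0], 0, 0, 0, L[1], 0, 0, 0, L[2]], dtype=float
        ),
        "template_ids": ",".join(m.template_id for m in config.molecules),
        "quaternions": np.concatenate([m.orientation for m in config.molecules])
        if config.molecules
        else "",
        "conformers": ",".join(str(m.conformer_index) for m in config.molecules),
    }
    if config.cached_energy_low is not None:
        full_info["energy_low"] = float(config.cached_energy_low)
    if config.cached_energy_high is not None:
        full_info["energy_high"] = float(config.cached_energy_high)
    if info:
        full_info.update(info)
    positions = np.vstack(pos_blocks) if pos_blocks else np.zeros((0, 3))
    return XYZFrame(
        symbols,
        positions,
        full_info,
        {"site_label": labels, "mol_id": mol_ids},
    )


def frame_to_configuration(
    frame: XYZFrame, templates: dict[str, MoleculeTemplate]
) -> Configuration:
    """Rebuild a configuration from a frame written by this module."""
    lat = np.asarray(frame.info["Lattice"], dtype=float).reshape(3, 3)
    box = Box(np.diag(lat))
    tids_raw = frame.info.get("template_ids", "")
    tids = str(tids_raw).split(",") if tids_raw else []
    quats_raw = frame.info.get("quaternions", "")
    quats = (
        np.asarray(quats_raw, dtype=float).reshape(-1, 4)
        if not isinstance(quats_raw, str)
        else np.zeros((0, 4))
    )
    confs_raw = frame.info.get("conformers", "")
    confs = [int(c) for c in str(confs_raw).split(",")] if confs_raw != "" else []
    molecules: list[MoleculeInstance] = []
    cursor = 0
    for i, tid in enumerate(tids):
        tmpl = templates[tid]
        coords = frame.positions[cursor : cursor + tmpl.n_sites]
        cursor += tmpl.n_sites
        m = tmpl.masses
        com = (coords * m[:, None]).sum(axis=0) / m.sum()
        q = quats[i] / np.linalg.norm(quats[i])
        molecules.append(MoleculeInstance(tid, com, q, confs[i]))
    config = Configuration(box, molecules)
    if "energy_low" in frame.info:
        config.cached_energy_low = float(frame.info["energy_low"])  # type: ignore[arg-type]
    if "energy_high" in frame.info:
        config.cached_energy_high = float(frame.info["energy_high"])  # type: ignore[arg-type]
    return config
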