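"""Built-in toy liquids.

Four presets make every stage of the pipeline testable without external
data or engines:

* ``lj_fluid`` — a single-site Lennard-Jones (argon-like) fluid;
* ``toy_water`` — a rigid 3-site water-like model (charged O/H sites at a
  bent geometry; hydrogen-bonding);
* ``toy_methanol`` — a rigid 3-site amphiphilic model (hydroxyl O–H plus a
  united-atom methyl site; hydrogen-bonding and dispersion);
* ``toy_ether`` — a rigid 3-site bent non-protic model with small charges
  (dimethyl-ether-like; dispersion-dominated).

The charged presets use TIP3P/OPLS-style parameter magnitudes as
qualitative analogs; they make no claim of reproducing any published
force field's observables.  Production-sized boxes of ~100 / 50 / 40
molecules of the three materials contain 300, 150 and 120 sites
(300–360 *atoms* in all-atom terms); tests use ~30 molecules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .system import Box, Configuration, MoleculeTemplate, PackingError, SiteSpec, place_molecules
from .units import MASS_PER_A3_TO_G_PER_CM3

__all__ = ["ToySystemSpec", "toy_template", "generate_toy_system", "PRESETS"]

PRESETS = ("lj_fluid", "toy_water", "toy_methanol", "toy_ether")

_DEFAULT_DENSITY = {
    "lj_fluid": 1.40,  # g·cm⁻³ (liquid argon)
    "toy_water": 1.00,
    "toy_methanol": 0.79,
    "toy_ether": 0.74,
}


@dataclass
class ToySystemSpec:
    """Fully determined toy box: preset, size, target density, conditions."""

    preset: str
    n_molecules: int = 30
    density: float | None = None  # g·cm⁻³; None → preset default
    temperature: float = 300.0
    pressure: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {PRESETS}")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.density is None:
            self.density = _DEFAULT_DENSITY[self.preset]
        if self.density <= 0:
            raise ValueError("density must be positive")


def _water_template() -> MoleculeTemplate:
    # bent 3-site geometry: O–H 0.9572 Å, H–O–H 104.52°
    r_oh, theta = 0.9572, np.deg2rad(104.52)
    h1 = (r_oh * np.sin(theta / 2), r_oh * np.cos(theta / 2), 0.0)
    h2 = (-r_oh * np.sin(theta / 2), r_oh * np.cos(theta / 2), 0.0)
    return MoleculeTemplate(
        "toy_water",
        [
            SiteSpec("O", "O", -0.834, 3.15061, 0.6364, (0.0, 0.0, 0.0)),
            SiteSpec("H", "H1", 0.417, 0.0, 0.0, h1),
            SiteSpec("H", "H2", 0.417, 0.0, 0.0, h2),
        ],
        bonds=[(0, 1), (0, 2)],
    )


def _methanol_template() -> MoleculeTemplate:
    # hydroxyl O–H 0.945 Å, O–C 1.43 Å, C–O–H 108.5°; C is a united-atom
    # methyl site (mass of CH3 approximated by C's atomic mass here)
    theta = np.deg2rad(108.5)
    h = (0.945 * np.sin(theta), 0.945 * np.cos(theta), 0.0)
    return MoleculeTemplate(
        "toy_methanol",
        [
            SiteSpec("O", "O", -0.700, 3.070, 0.7113, (0.0, 0.0, 0.0)),
            SiteSpec("H", "H", 0.435, 0.0, 0.0, h),
            SiteSpec("C", "Me", 0.265, 3.775, 0.8661, (0.0, 1.430, 0.0)),
        ],
        bonds=[(0, 1), (0, 2)],
    )


def _ether_template() -> MoleculeTemplate:
    # bent C–O–C, O–C 1.41 Å, angle 112°; united-atom methyls, small charges
    theta = np.deg2rad(112.0)
    c1 = (1.41 * np.sin(theta / 2), 1.41 * np.cos(theta / 2), 0.0)
    c2 = (-1.41 * np.sin(theta / 2), 1.41 * np.cos(theta / 2), 0.0)
    return MoleculeTemplate(
        "toy_ether",
        [
            SiteSpec("O", "O", -0.400, 3.000, 0.7113, (0.0, 0.0, 0.0)),
            SiteSpec("C", "Me1", 0.200, 3.800, 0.8661, c1),
            SiteSpec("C", "Me2", 0.200, 3.800, 0.8661, c2),
        ],
        bonds=[(0, 1), (0, 2)],
    )


def _lj_template() -> MoleculeTemplate:
    return MoleculeTemplate(
        "lj_fluid",
        [SiteSpec("Ar", "Ar", 0.0, 3.405, 0.9960, (0.0, 0.0, 0.0))],
    )


_BUILDERS = {
    "lj_fluid": _lj_template,
    "toy_water": _water_template,
    "toy_methanol": _methanol_template,
    "toy_ether": _ether_template,
}


def toy_template(preset: str) -> MoleculeTemplate:
    """The rigid molecule template of a preset."""
    if preset not in _BUILDERS:
        raise ValueError(f"unknown preset {preset!r}")
    return _BUILDERS[preset]()


def generate_toy_system(
    spec: ToySystemSpec,
    min_separation: float = 1.5,
) -> tuple[Configuration, dict[str, MoleculeTemplate]]:
    """Build a periodic toy box at the spec's target density.

    The cubic edge follows from ``N·M/(N_A·ρ)``; molecules are inserted at
    random positions and orientations subject to a hard minimum contact.
    Deterministic for a fixed seed.
    """
    tmpl = toy_template(spec.preset)
    templates = {tmpl.name: tmpl}
    volume = spec.n_molecules * tmpl.molar_mass * MASS_PER_A3_TO_G_PER_CM3 / spec.density
    edge = volume ** (1.0 / 3.0)
    box = Box(np.full(3, edge))
    config = place_molecules(
        templates, {tmpl.name: spec.n_molecules}, box, min_separation, spec.seed
    )
    return config, templates
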