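"""Geometry and state representation for rigid-molecule liquids.

A simulated system is a periodic orthorhombic :class:`Box` containing
:class:`MoleculeInstance` objects, each referring to a shared
:class:`MoleculeTemplate`.  Templates carry the per-site force-field
parameters (partial charge, Lennard-Jones σ/ε) and one or more rigid
body-frame geometries ("conformers"); instances carry only a center-of-mass
position, an orientation quaternion and a conformer index.  This keeps the
Markov-chain state small and makes rigid-body moves exact.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .units import ATOMIC_MASSES

__all__ = [
    "SiteSpec",
    "MoleculeTemplate",
    "MoleculeInstance",
    "Box",
    "Configuration",
    "minimum_image_displacement",
    "quaternion_to_matrix",
    "random_unit_quaternion",
    "site_positions",
    "place_molecules",
]


class PackingError(RuntimeError):
    """Raised when random insertion cannot place all molecules."""


@dataclass(frozen=True)
class SiteSpec:
    """One interaction site of a molecule template.

    Parameters are in the package unit system: ``charge`` in elementary
    charges, ``lj_sigma`` in Å, ``lj_epsilon`` in kJ·mol⁻¹ and
    ``ref_position`` in Å in the template's body frame.
    """

    element: str
    site_label: str
    charge: float
    lj_sigma: float
    lj_epsilon: float
    ref_position: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.lj_sigma < 0 or self.lj_epsilon < 0:
            raise ValueError("LJ parameters must be non-negative")
        if self.element not in ATOMIC_MASSES:
            raise ValueError(f"unknown element symbol {self.element!r}")


@dataclass
class MoleculeTemplate:
    """A rigid molecule type: sites, bonds, conformer pool, molar mass.

    ``conformers[0]`` is the reference geometry and must equal the sites'
    ``ref_position`` stack.  Additional conformers act as a discrete
    presampled pool of alternative rigid geometries that conformer-swap
    moves can select from.
    """

    name: str
    sites: list[SiteSpec]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    conformers: list[np.ndarray] = field(default_factory=list)
    net_charge: float = 0.0

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("template needs at least one site")
        ref = np.asarray([s.ref_position for s in self.sites], dtype=float)
        if not self.conformers:
            self.conformers = [ref]
        self.conformers = [np.asarray(c, dtype=float) for c in self.conformers]
        for i, c in enumerate(self.conformers):
            if c.shape != (len(self.sites), 3):
                raise ValueError(f"conformer {i} has wrong shape {c.shape}")
        if not np.allclose(self.conformers[0], ref, atol=1e-10):
            raise ValueError("conformer 0 must be the reference geometry")
        q = sum(s.charge for s in self.sites)
        if abs(q - self.net_charge) > 1e-9:
            raise ValueError(
                f"site charges sum to {q:.6g}, declared net charge {self.net_charge:.6g}"
            )
        for a, b in self.bonds:
            if not (0 <= a < len(self.sites) and 0 <= b < len(self.sites)):
                raise ValueError(f"bond ({a},{b}) out of range")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def masses(self) -> np.ndarray:
        return np.asarray([ATOMIC_MASSES[s.element] for s in self.sites])

    @property
    def molar_mass(self) -> float:
        """Molar mass as the sum of site atomic masses, g·mol⁻¹."""
        return float(self.masses.sum())

    def body_frame(self, conformer_index: int = 0) -> np.ndarray:
        """Body-frame coordinates of a conformer, centered on its COM."""
        coords = self.conformers[conformer_index]
        m = self.masses
        com = (coords * m[:, None]).sum(axis=0) / m.sum()
        return coords - com

    @property
    def site_params(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], list[str]]:
        """Cached per-site (charges, sigmas, epsilons, elements, labels)."""
        cached = getattr(self, "_site_params", None)
        if cached is None:
            cached = (
                np.asarray([s.charge for s in self.sites]),
                np.asarray([s.lj_sigma for s in self.sites]),
                np.asarray([s.lj_epsilon for s in self.sites]),
                [s.element for s in self.sites],
                [s.site_label for s in self.sites],
            )
            self._site_params = cached
        return cached

    def bonded_neighbors(self, site_index: int) -> list[int]:
        out = []
        for a, b in self.bonds:
            if a == site_index:
                out.append(b)
            elif b == site_index:
                out.append(a)
        return out


@dataclass
class MoleculeInstance:
    """Placement of one template copy: COM position, orientation, conformer."""

    template_id: str
    com_position: np.ndarray
    orientation: np.ndarray  # unit quaternion (w, x, y, z)
    conformer_index: int = 0

    def __post_init__(self) -> None:
        self.com_position = np.asarray(self.com_position, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        n = np.linalg.norm(self.orientation)
        if abs(n - 1.0) > 1e-10:
            raise ValueError(f"quaternion norm {n} != 1")

    def copy(self) -> "MoleculeInstance":
        return MoleculeInstance(
            self.template_id,
            self.com_position.copy(),
            self.orientation.copy(),
            self.conformer_index,
        )


@dataclass
class Box:
    """Orthorhombic periodic cell with edge lengths in Å."""

    edge_lengths: np.ndarray

    def __post_init__(self) -> None:
        self.edge_lengths = np.asarray(self.edge_lengths, dtype=float)
        if self.edge_lengths.shape != (3,) or np.any(self.edge_lengths <= 0):
            raise ValueError("box needs three positive edge lengths")

    @property
    def volume(self) -> float:
        return float(np.prod(self.edge_lengths))

    def scaled(self, factor: float) -> "Box":
        return Box(self.edge_lengths * factor)

    def wrap(self, r: np.ndarray) -> np.ndarray:
        return np.mod(r, self.edge_lengths)


@dataclass
class Configuration:
    """The Markov-chain state: box, molecule placements, cached energies.

    ``cached_energy_low`` / ``cached_energy_high`` hold the most recent
    generator-level and composite-level energies (kJ·mol⁻¹) or ``None``;
    recomputation from scratch must reproduce a cache to 1e-8 relative.
    """

    box: Box
    molecules: list[MoleculeInstance]
    cached_energy_low: float | None = None
    cached_energy_high: float | None = None

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    def copy(self) -> "Configuration":
        return Configuration(
            Box(self.box.edge_lengths.copy()),
            [m.copy() for m in self.molecules],
            self.cached_energy_low,
            self.cached_energy_high,
        )


def minimum_image_displacement(r_a: np.ndarray, r_b: np.ndarray, box: Box) -> np.ndarray:
    """Displacement ``r_b - r_a`` wrapped into ``[-L/2, L/2)`` per component.

    Supports broadcasting over leading axes of ``r_a``/``r_b``.
    """
    L = box.edge_lengths
    d = np.asarray(r_b, dtype=float) - np.asarray(r_a, dtype=float)
    return d - L * np.floor(d / L + 0.5)


def quaternion_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of a unit quaternion (w, x, y, z)."""
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def quaternion_multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = q1
    w2, x2, y2, z2 = q2
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def random_unit_quaternion(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation (Shoemake's subgroup algorithm)."""
    u1, u2, u3 = rng.random(3)
    a, b = np.sqrt(1 - u1), np.sqrt(u1)
    return np.array(
        [
            a * np.sin(2 * np.pi * u2),
            a * np.cos(2 * np.pi * u2),
            b * np.sin(2 * np.pi * u3),
            b * np.cos(2 * np.pi * u3),
        ]
    )


def axis_angle_quaternion(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    half = 0.5 * angle
    return np.concatenate([[np.cos(half)], np.sin(half) * axis])


def instance_coordinates(
    mol: MoleculeInstance, templates: dict[str, MoleculeTemplate]
) -> np.ndarray:
    """Lab-frame site coordinates of one molecule, (n_sites, 3) Å."""
    tmpl = templates.get(mol.template_id)
    if tmpl is None:
        raise KeyError(f"unknown template_id {mol.template_id!r}")
    if mol.conformer_index >= len(tmpl.conformers):
        raise IndexError(
            f"conformer {mol.conformer_index} out of range for {tmpl.name}"
        )
    body = tmpl.body_frame(mol.conformer_index)
    rot = quaternion_to_matrix(mol.orientation)
    return body @ rot.T + mol.com_position


def site_positions(
    mol: MoleculeInstance, templates: dict[str, MoleculeTemplate]
) -> list[tuple[str, str, np.ndarray]]:
    """Per-site ``(site_label, element, position)`` for one molecule."""
    tmpl = templates[mol.template_id] if mol.template_id in templates else None
    if tmpl is None:
        raise KeyError(f"unknown template_id {mol.template_id!r}")
    coords = instance_coordinates(mol, templates)
    return [
        (s.site_label, s.element, coords[i]) for i, s in enumerate(tmpl.sites)
    ]


def _min_contact(
    coords_a: np.ndarray, coords_b: np.ndarray, box: Box
) -> float:
    d = minimum_image_displacement(coords_a[:, None, :], coords_b[None, :, :], box)
    return float(np.sqrt((d ** 2).sum(axis=-1)).min())


def place_molecules(
    templates: dict[str, MoleculeTemplate],
    counts: dict[str, int],
    box: Box,
    min_separation: float = 1.5,
    seed: int | np.random.Generator = 0,
    max_attempts_per_molecule: int = 20000,
) -> Configuration:
    """Randomly insert rigid molecules with a hard-contact constraint.

    Each molecule gets a uniform COM position and a uniform random
    orientation; a placement is accepted when its closest intermolecular
    site–site distance under minimum image is at least ``min_separation``.
    Deterministic for a fixed integer seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    molecules: list[MoleculeInstance] = []
    placed_coords: list[np.ndarray] = []
    for tid, n in counts.items():
        if tid not in templates:
            raise KeyError(f"unknown template_id {tid!r}")
        for _ in range(n):
            for _attempt in range(max_attempts_per_molecule):
                com = rng.random(3) * box.edge_lengths
                q = random_unit_quaternion(rng)
                mol = MoleculeInstance(tid, com, q)
                coords = instance_coordinates(mol, templates)
                ok = all(
                    _min_contact(coords, other, box) >= min_separation
                    for other in placed_coords
                )
                if ok:
                    molecules.append(mol)
                    placed_coords.append(coords)
                    break
            else:
                raise PackingError(
                    f"could not place molecule {len(molecules) + 1} after "
                    f"{max_attempts_per_molecule} attempts; box too small for "
                    f"min_separation={min_separation} Å"
                )
    return Configuration(box, molecules)
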