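"""Energy backends.

The sampling engine distinguishes up to three potential tiers: a cheap
generator potential driving the inner Monte Carlo loop, a medium-level
full-system potential, and a high-level potential applied to proximate
dimer fragments only.  All tiers satisfy one :class:`EnergyBackend`
contract, so a classical force field, a rescaled copy of it (a convenient
surrogate "higher level" for testing) or an external quantum-chemistry
engine are interchangeable.

The built-in classical force field is a rigid-molecule site model:
Lennard-Jones 12-6 with Lorentz–Berthelot or geometric combining, truncated
at ``r_cut`` (optional analytic tail correction), plus damped shifted-force
(Wolf-type) Coulomb electrostatics which vanish smoothly at the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erfc

from .system import (
    Box,
    Configuration,
    MoleculeInstance,
    MoleculeTemplate,
    instance_coordinates,
    minimum_image_displacement,
)
from .units import COULOMB_K

__all__ = [
    "FFParameters",
    "EnergyBackend",
    "ForceFieldBackend",
    "ZeroBackend",
    "Fragment",
    "lj_pair_energy",
    "dsf_coulomb_energy",
    "ff_configuration_energy",
    "pair_interaction_energy",
    "fragment_from_molecules",
    "OverlapError",
]

#: Any intermolecular site pair closer than this (Å) marks a degenerate state.
OVERLAP_DISTANCE = 0.1

#: Effective cutoff used for free-space fragments when the configured
#: cutoff is dynamic (box-dependent): large enough that the shifted-force
#: terms are negligible, i.e. plain damped Coulomb.
_FREE_SPACE_RCUT = 1.0e6


class OverlapError(ValueError):
    """Two intermolecular sites closer than the overlap threshold."""


@dataclass(frozen=True)
class FFParameters:
    """Force-field evaluation settings.

    ``r_cut`` is the spherical truncation radius in Å; ``None`` selects a
    dynamic cutoff of half the smallest box edge at evaluation time (useful
    under NpT volume moves).  ``coulomb_damping`` is the Wolf damping
    parameter in Å⁻¹; 0 gives the undamped shifted-force form.
    """

    combining_rule: str = "lorentz_berthelot"
    r_cut: float | None = None
    coulomb_damping: float = 0.2
    tail_correction: bool = False

    def __post_init__(self) -> None:
        if self.combining_rule not in ("lorentz_berthelot", "geometric"):
            raise ValueError(f"unknown combining rule {self.combining_rule!r}")
        if self.r_cut is not None and self.r_cut <= 0:
            raise ValueError("r_cut must be positive")

    def effective_r_cut(self, box: Box | None) -> float:
        if self.r_cut is not None:
            if box is not None and self.r_cut > 0.5 * box.edge_lengths.min() + 1e-9:
                raise ValueError(
                    f"r_cut={self.r_cut} exceeds half the smallest box edge "
                    f"({0.5 * box.edge_lengths.min():.4f} Å)"
                )
            return self.r_cut
        if box is None:
            return _FREE_SPACE_RCUT
        return 0.5 * float(box.edge_lengths.min()) * (1 - 1e-12)


def lj_pair_energy(r: float, sigma: float, epsilon: float) -> float:
    """12-6 Lennard-Jones pair energy ``4ε[(σ/r)¹² − (σ/r)⁶]`` in kJ·mol⁻¹."""
    if r <= 0:
        raise OverlapError("site distance r must be positive")
    sr6 = (sigma / r) ** 6
    return 4.0 * epsilon * (sr6 * sr6 - sr6)


def dsf_coulomb_energy(
    r: float, q_a: float, q_b: float, damping: float, r_cut: float
) -> float:
    """Damped shifted-force Coulomb pair energy, kJ·mol⁻¹.

    ``u(r) = k q_a q_b [erfc(αr)/r − erfc(αr_c)/r_c + F_c·(r − r_c)]`` where
    ``F_c`` is the magnitude of the damped-Coulomb force at the cutoff, so
    both the energy and its first derivative vanish at ``r = r_cut``.
    Returns 0 for ``r > r_cut`` by contract.
    """
    if r <= 0:
        raise OverlapError("site distance r must be positive")
    if r > r_cut:
        return 0.0
    a = damping
    shift = erfc(a * r_cut) / r_cut
    force_c = shift / r_cut + 2 * a / np.sqrt(np.pi) * np.exp(-(a * r_cut) ** 2) / r_cut
    return float(
        COULOMB_K * q_a * q_b * (erfc(a * r) / r - shift + force_c * (r - r_cut))
    )


# ---------------------------------------------------------------------------
# Vectorized site-array machinery shared by the full-system and fragment paths
# ---------------------------------------------------------------------------

def _pair_energy_arrays(
    r: np.ndarray,
    qq: np.ndarray,
    sig: np.ndarray,
    epsi: np.ndarray,
    damping: float,
    r_cut: float,
) -> float:
    """Total LJ + DSF-Coulomb energy over flattened pair arrays within r_cut."""
    if r.size == 0:
        return 0.0
    if np.any(r < OVERLAP_DISTANCE):
        raise OverlapError(
            f"intermolecular site distance {r.min():.4f} Å below overlap "
            f"threshold {OVERLAP_DISTANCE} Å"
        )
    mask = r <= r_cut
    r = r[mask]
    qq = qq[mask]
    sig = sig[mask]
    epsi = epsi[mask]
    sr6 = np.zeros_like(r)
    nz = epsi > 0
    sr6[nz] = (sig[nz] / r[nz]) ** 6
    e_lj = float(np.sum(4.0 * epsi * (sr6 * sr6 - sr6)))
    a = damping
    shift = erfc(a * r_cut) / r_cut
    force_c = shift / r_cut + 2 * a / np.sqrt(np.pi) * np.exp(-(a * r_cut) ** 2) / r_cut
    e_c = float(
        COULOMB_K * np.sum(qq * (erfc(a * r) / r - shift + force_c * (r - r_cut)))
    )
    return e_lj + e_c


def _combine(si, sj, ei, ej, rule: str):
    if rule == "lorentz_berthelot":
        sig = 0.5 * (si + sj)
    else:
        sig = np.sqrt(si * sj)
    return sig, np.sqrt(ei * ej)


@dataclass
class SiteArrays:
    """Flattened per-site parameter arrays for one configuration."""

    positions: np.ndarray  # (n, 3)
    charges: np.ndarray
    sigmas: np.ndarray
    epsilons: np.ndarray
    mol_index: np.ndarray  # (n,) int
    elements: list[str]
    labels: list[str]
    mol_slices: list[slice]

    @classmethod
    def from_configuration(
        cls,
        config: Configuration,
        templates: dict[str, MoleculeTemplate],
        epsilon_scale: float = 1.0,
        charge_scale: float = 1.0,
    ) -> "SiteArrays":
        pos, q, sg, ep, mi, el, lb, slices = [], [], [], [], [], [], [], []
        cursor = 0
        for i, mol in enumerate(config.molecules):
            tmpl = templates[mol.template_id]
            coords = instance_coordinates(mol, templates)
            pos.append(coords)
            for s in tmpl.sites:
                q.append(s.charge * charge_scale)
                sg.append(s.lj_sigma)
                ep.append(s.lj_epsilon * epsilon_scale)
                el.append(s.element)
                lb.append(s.site_label)
                mi.append(i)
            slices.append(slice(cursor, cursor + tmpl.n_sites))
            cursor += tmpl.n_sites
        return cls(
            np.vstack(pos) if pos else np.zeros((0, 3)),
            np.asarray(q),
            np.asarray(sg),
            np.asarray(ep),
            np.asarray(mi, dtype=int),
            el,
            lb,
            slices,
        )


def _total_energy(sa: SiteArrays, box: Box | None, params: FFParameters) -> float:
    n = len(sa.charges)
    if n < 2:
        return 0.0
    r_cut = params.effective_r_cut(box)
    iu, ju = np.triu_indices(n, k=1)
    inter = sa.mol_index[iu] != sa.mol_index[ju]
    iu, ju = iu[inter], ju[inter]
    if box is not None:
        d = minimum_image_displacement(sa.positions[iu], sa.positions[ju], box)
    else:
        d = sa.positions[ju] - sa.positions[iu]
    r = np.sqrt((d ** 2).sum(axis=1))
    sig, epsi = _combine(
        sa.sigmas[iu], sa.sigmas[ju], sa.epsilons[iu], sa.epsilons[ju],
        params.combining_rule,
    )
    e = _pair_energy_arrays(
        r, sa.charges[iu] * sa.charges[ju], sig, epsi, params.coulomb_damping, r_cut
    )
    if params.tail_correction and box is not None:
        e += _tail_correction(sa, box, params, r_cut, iu, ju)
    return e


def _tail_correction(
    sa: SiteArrays, box: Box, params: FFParameters, r_cut: float, iu, ju
) -> float:
    # mean-field correction assuming g(r)=1 beyond the cutoff, summed over
    # the same intermolecular pair list that the truncated sum uses
    sig, epsi = _combine(
        sa.sigmas[iu], sa.sigmas[ju], sa.epsilons[iu], sa.epsilons[ju],
        params.combining_rule,
    )
    nz = epsi > 0
    sig, epsi = sig[nz], epsi[nz]
    integral = 4.0 * epsi * (
        sig ** 12 / (9.0 * r_cut ** 9) - sig ** 6 / (3.0 * r_cut ** 3)
    )
    return float(4.0 * np.pi / box.volume * integral.sum())


def _molecule_energy(
    sa: SiteArrays, mol_i: int, box: Box | None, params: FFParameters
) -> float:
    """Interaction energy of molecule ``mol_i`` with all other molecules."""
    sl = sa.mol_slices[mol_i]
    other = sa.mol_index != mol_i
    if not other.any():
        return 0.0
    r_cut = params.effective_r_cut(box)
    pa = sa.positions[sl][:, None, :]
    pb = sa.positions[other][None, :, :]
    if box is not None:
        d = minimum_image_displacement(pa, pb, box)
    else:
        d = pb - pa
    r = np.sqrt((d ** 2).sum(axis=-1)).ravel()
    qa = np.repeat(sa.charges[sl], other.sum())
    qb = np.tile(sa.charges[other], sl.stop - sl.start)
    si = np.repeat(sa.sigmas[sl], other.sum())
    sj = np.tile(sa.sigmas[other], sl.stop - sl.start)
    ei = np.repeat(sa.epsilons[sl], other.sum())
    ej = np.tile(sa.epsilons[other], sl.stop - sl.start)
    sig, epsi = _combine(si, sj, ei, ej, params.combining_rule)
    return _pair_energy_arrays(r, qa * qb, sig, epsi, params.coulomb_damping, r_cut)


def ff_configuration_energy(
    config: Configuration,
    templates: dict[str, MoleculeTemplate],
    params: FFParameters | None = None,
) -> float:
    """Total intermolecular force-field energy of a periodic configuration.

    Sums LJ (truncated, optional tail correction) and damped shifted-force
    Coulomb over all intermolecular site pairs under the minimum-image
    convention.  Raises :class:`OverlapError` when any intermolecular site
    pair is closer than 0.1 Å.
    """
    params = params or FFParameters()
    sa = SiteArrays.from_configuration(config, templates)
    return _total_energy(sa, config.box, params)


# ---------------------------------------------------------------------------
# Backend contract and implementations
# ---------------------------------------------------------------------------

@dataclass
class Fragment:
    """A free-space fragment (one or more whole molecules) for evaluation."""

    elements: list[str]
    positions: np.ndarray
    charges: np.ndarray
    sigmas: np.ndarray
    epsilons: np.ndarray
    mol_index: np.ndarray
    labels: list[str]

    @property
    def n_molecules(self) -> int:
        return int(self.mol_index.max()) + 1 if len(self.mol_index) else 0


def fragment_from_molecules(
    mols: list[MoleculeInstance],
    templates: dict[str, MoleculeTemplate],
    box: Box | None = None,
) -> Fragment:
    """Build a contiguous free-space fragment from whole molecules.

    When a ``box`` is given, each molecule after the first is shifted by
    whole box vectors so its center of mass sits at the minimum-image
    position relative to the first molecule — dimers spanning a periodic
    boundary are reassembled into one contiguous piece of free space.
    """
    coords_list = [instance_coordinates(m, templates) for m in mols]
    return fragment_from_coords(mols, coords_list, templates, box)


def fragment_from_coords(
    mols: list[MoleculeInstance],
    coords_list: list[np.ndarray],
    templates: dict[str, MoleculeTemplate],
    box: Box | None = None,
) -> Fragment:
    """As :func:`fragment_from_molecules`, reusing precomputed coordinates."""
    pos_blocks, q, sg, ep, mi, el, lb = [], [], [], [], [], [], []
    ref_com = None
    for i, (mol, coords) in enumerate(zip(mols, coords_list)):
        tmpl = templates[mol.template_id]
        com = mol.com_position
        if box is not None:
            if ref_com is None:
                ref_com = com
            else:
                target = ref_com + minimum_image_displacement(ref_com, com, box)
                coords = coords + (target - com)
        pos_blocks.append(coords)
        qs, sgs, eps, els, lbs = tmpl.site_params
        q.append(qs)
        sg.append(sgs)
        ep.append(eps)
        el.extend(els)
        lb.extend(lbs)
        mi.append(np.full(tmpl.n_sites, i, dtype=int))
    return Fragment(
        el,
        np.vstack(pos_blocks),
        np.concatenate(q),
        np.concatenate(sg),
        np.concatenate(ep),
        np.concatenate(mi),
        lb,
    )


class EnergyBackend:
    """Contract for an energy tier.

    ``capabilities`` declares which evaluation modes the backend supports:
    ``full_system`` (a periodic configuration), ``monomer`` and ``dimer``
    (free-space fragments).  Fragment evaluations must be pure functions of
    geometry, and dimer energies symmetric under argument swap.
    """

    name: str = "backend"
    capabilities: frozenset = frozenset()

    def full_system_energy(
        self, config: Configuration, templates: dict[str, MoleculeTemplate]
    ) -> float:
        raise NotImplementedError

    def fragment_energy(self, fragment: Fragment) -> float:
        raise NotImplementedError


class ZeroBackend(EnergyBackend):
    """The non-interacting (ideal-gas) potential: every energy is zero."""

    name = "zero"
    capabilities = frozenset({"full_system", "monomer", "dimer"})

    def full_system_energy(self, config, templates) -> float:
        return 0.0

    def fragment_energy(self, fragment) -> float:
        return 0.0


class ForceFieldBackend(EnergyBackend):
    """The built-in classical force field as an energy tier.

    ``epsilon_scale`` / ``charge_scale`` uniformly rescale the LJ well
    depths / partial charges, producing a controlled surrogate for a
    distinct (e.g. higher-level) potential in desk-scale experiments.
    Fragment energies use the same truncated pair functions; since
    intramolecular pairs are excluded and molecules are rigid, every
    monomer energy is exactly zero and dimer energies reduce to the
    intermolecular cross terms.
    """

    capabilities = frozenset({"full_system", "monomer", "dimer"})

    def __init__(
        self,
        params: FFParameters | None = None,
        epsilon_scale: float = 1.0,
        charge_scale: float = 1.0,
        name: str | None = None,
    ) -> None:
        self.params = params or FFParameters()
        self.epsilon_scale = epsilon_scale
        self.charge_scale = charge_scale
        if name is None:
            name = "ff" if epsilon_scale == charge_scale == 1.0 else (
                f"ff(eps×{epsilon_scale:g},q×{charge_scale:g})"
            )
        self.name = name

    def full_system_energy(self, config, templates) -> float:
        sa = SiteArrays.from_configuration(
            config, templates, self.epsilon_scale, self.charge_scale
        )
        return _total_energy(sa, config.box, self.params)

    def fragment_energy(self, fragment: Fragment) -> float:
        n_mol = fragment.n_molecules
        if n_mol < 2:
            return 0.0
        r_cut = self.params.effective_r_cut(None)
        slices = [
            np.flatnonzero(fragment.mol_index == k) for k in range(n_mol)
        ]
        e = 0.0
        for a in range(n_mol - 1):
            ia = slices[a]
            for b in range(a + 1, n_mol):
                jb = slices[b]
                d = fragment.positions[jb][None, :, :] - fragment.positions[ia][:, None, :]
                r = np.sqrt((d ** 2).sum(axis=-1)).ravel()
                sig, epsi = _combine(
                    np.repeat(fragment.sigmas[ia], len(jb)),
                    np.tile(fragment.sigmas[jb], len(ia)),
                    np.repeat(fragment.epsilons[ia], len(jb)) * self.epsilon_scale,
                    np.tile(fragment.epsilons[jb], len(ia)) * self.epsilon_scale,
                    self.params.combining_rule,
                )
                qq = (
                    np.repeat(fragment.charges[ia], len(jb))
                    * np.tile(fragment.charges[jb], len(ia))
                    * self.charge_scale ** 2
                )
                e += _pair_energy_arrays(
                    r, qq, sig, epsi, self.params.coulomb_damping, r_cut
                )
        return e


def pair_interaction_energy(
    backend: EnergyBackend,
    mol_i: MoleculeInstance,
    mol_j: MoleculeInstance,
    templates: dict[str, MoleculeTemplate],
    box: Box | None = None,
) -> float:
    """Two-body interaction energy ``E(dimer) − E(monomer i) − E(monomer j)``.

    The dimer is evaluated at its minimum-image-reassembled free-space
    geometry.  Symmetric in the two molecules.
    """
    if not {"monomer", "dimer"} <= backend.capabilities:
        raise ValueError(f"backend {backend.name!r} lacks fragment capabilities")
    try:
        dimer = fragment_from_molecules([mol_i, mol_j], templates, box)
        e_dimer = backend.fragment_energy(dimer)
        e_i = backend.fragment_energy(fragment_from_molecules([mol_i], templates))
        e_j = backend.fragment_energy(fragment_from_molecules([mol_j], templates))
    except Exception as exc:
        raise RuntimeError(
            f"fragment evaluation failed for dimer "
            f"({mol_i.template_id}, {mol_j.template_id}) with backend "
            f"{backend.name!r}: {exc}"
        ) from exc
    return e_dimer - e_i - e_j
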