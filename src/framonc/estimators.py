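"""Thermodynamic observables and their uncertainties.

Implements the estimator chain used to turn sampled configurations into
material properties: bulk density ρ, vaporization enthalpy ΔvapH (liquid
run plus an ideal-gas single-molecule vapor run), thermal expansivity
α = −(1/ρ)(∂ρ/∂T)_p and the vapor–liquid heat-capacity difference
ΔvapCp = ∂ΔvapH/∂T, both by finite differences over a temperature grid,
and site–site radial distribution functions.  Statistical uncertainties of
correlated Markov-chain series come from block-doubling (Flyvbjerg–
Petersen) analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .system import Box, Configuration, MoleculeTemplate, instance_coordinates, minimum_image_displacement
from .units import BAR_A3_TO_KJ_PER_MOL, MASS_PER_A3_TO_G_PER_CM3, R_GAS

__all__ = [
    "ScalarSeries",
    "ThermoResult",
    "RdfResult",
    "block_uncertainty",
    "running_average",
    "density",
    "vaporization_enthalpy",
    "thermal_expansivity",
    "heat_capacity_difference",
    "radial_distribution",
]


@dataclass
class ScalarSeries:
    """An ordered stream of samples of one observable.

    All statistics are computed on the post-burn-in part only.
    """

    values: np.ndarray
    units: str = ""
    burn_in: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.burn_in < 0 or self.burn_in > len(self.values):
            raise ValueError("burn_in out of range")

    @property
    def production(self) -> np.ndarray:
        return self.values[self.burn_in :]

    @property
    def mean(self) -> float:
        return float(self.production.mean())

    @property
    def sem(self) -> float:
        return block_uncertainty(self)


@dataclass
class ThermoResult:
    """Derived observables over a strictly increasing temperature grid."""

    T_grid: np.ndarray
    rho: np.ndarray
    rho_err: np.ndarray
    dvap_h: np.ndarray
    dvap_h_err: np.ndarray
    alpha: np.ndarray | None = None
    alpha_err: np.ndarray | None = None
    dvap_cp: np.ndarray | None = None
    dvap_cp_err: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.T_grid = np.asarray(self.T_grid, dtype=float)
        if np.any(np.diff(self.T_grid) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        for errs in (self.rho_err, self.dvap_h_err):
            if np.any(np.asarray(errs) < 0):
                raise ValueError("uncertainties must be non-negative")

    def with_derivatives(self) -> "ThermoResult":
        """Fill α and ΔvapCp by finite differences over the grid."""
        self.alpha, self.alpha_err = thermal_expansivity(
            self.T_grid, self.rho, self.rho_err
        )
        self.dvap_cp, self.dvap_cp_err = heat_capacity_difference(
            self.T_grid, self.dvap_h, self.dvap_h_err
        )
        return self

    def to_table(self) -> str:
        """Columnar text table (TSV) of all derived observables."""
        header = (
            "T_K\trho_gcm3\trho_err\tdvapH_kJmol\tdvapH_err\t"
            "alpha_perK\talpha_err\tdvapCp_kJmolK\tdvapCp_err\n"
        )
        if self.alpha is None:
            self.with_derivatives()
        rows = []
        for k in range(len(self.T_grid)):
            rows.append(
                f"{self.T_grid[k]:.2f}\t{self.rho[k]:.6f}\t{self.rho_err[k]:.6f}\t"
                f"{self.dvap_h[k]:.4f}\t{self.dvap_h_err[k]:.4f}\t"
                f"{self.alpha[k]:.6e}\t{self.alpha_err[k]:.6e}\t"
                f"{self.dvap_cp[k]:.6f}\t{self.dvap_cp_err[k]:.6f}\n"
            )
        return header + "".join(rows)


def running_average(series: ScalarSeries) -> np.ndarray:
    """Cumulative running mean of the production samples."""
    v = series.production
    return np.cumsum(v) / np.arange(1, len(v) + 1)


def block_uncertainty(series: ScalarSeries, plateau_rtol: float = 0.10) -> float:
    """Standard error of the mean by block doubling.

    Block means at sizes 1, 2, 4, … give SEM estimates
    ``sqrt(var(blocks)/(n_blocks−1))``; correlated data inflate the
    estimate as blocks grow until it plateaus.  The reported value is the
    first estimate that changes by less than ``plateau_rtol`` over the two
    following doublings, or the largest-block estimate if no plateau is
    reached.  Requires at least 16 post-burn-in samples.
    """
    v = series.production
    if len(v) < 16:
        raise ValueError(
            f"block analysis needs >= 16 samples, got {len(v)}; "
            "insufficient sampling"
        )
    if np.allclose(v, v[0]):
        return 0.0
    estimates = []
    x = v.copy()
    while len(x) >= 4:
        n = len(x)
        estimates.append(float(np.sqrt(np.var(x, ddof=1) / n)))
        x = 0.5 * (x[: n // 2 * 2 : 2] + x[1 : n // 2 * 2 : 2])
    for k in range(len(estimates) - 2):
        e0, e1, e2 = estimates[k : k + 3]
        if e0 > 0 and abs(e1 - e0) < plateau_rtol * e0 and abs(e2 - e0) < plateau_rtol * e0:
            return max(e0, e1, e2)
    return estimates[-1]


def density(
    config_or_series: Configuration | ScalarSeries,
    templates: dict[str, MoleculeTemplate] | None = None,
) -> float:
    """Bulk mass density in g·cm⁻³.

    For a configuration: ``ρ = Σ_i M_i / (N_A · V)`` with molar masses in
    g·mol⁻¹ and the box volume in Å³.  For a ScalarSeries of densities the
    production mean is returned.
    """
    if isinstance(config_or_series, ScalarSeries):
        return config_or_series.mean
    config = config_or_series
    if templates is None:
        raise ValueError("templates required to compute density of a configuration")
    mass = sum(templates[m.template_id].molar_mass for m in config.molecules)
    return mass / config.box.volume * MASS_PER_A3_TO_G_PER_CM3


def vaporization_enthalpy(
    u_liquid: ScalarSeries,
    v_liquid: ScalarSeries,
    n_molecules: int,
    pressure: float,
    temperature: float,
    u_vapor: ScalarSeries,
    vapor_temperature: float | None = None,
) -> tuple[float, float]:
    """Molar vaporization enthalpy and its propagated uncertainty, kJ·mol⁻¹.

    ``ΔvapH = (⟨U_gas⟩ + R·T) − (⟨U_liq⟩/N + p·⟨V⟩/N)`` with the vapor
    treated as an ideal gas (its pV term is exactly RT); energies in
    kJ·mol⁻¹, volumes in Å³, pressure in bar.  Uncertainties of the three
    sampled means are combined in quadrature.
    """
    if vapor_temperature is not None and abs(vapor_temperature - temperature) > 1e-9:
        raise ValueError(
            f"liquid ({temperature} K) and vapor ({vapor_temperature} K) runs "
            "must be at the same temperature"
        )
    pv_per_mol = pressure * v_liquid.mean * BAR_A3_TO_KJ_PER_MOL / n_molecules
    dvap_h = (u_vapor.mean + R_GAS * temperature) - (
        u_liquid.mean / n_molecules + pv_per_mol
    )
    err = np.sqrt(
        u_vapor.sem ** 2
        + (u_liquid.sem / n_molecules) ** 2
        + (pressure * v_liquid.sem * BAR_A3_TO_KJ_PER_MOL / n_molecules) ** 2
    )
    return float(dvap_h), float(err)


def _central_difference(
    T: np.ndarray, y: np.ndarray, dy: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Derivative dy/dT by central differences (one-sided at the ends),
    with uncertainty from independent-point error propagation."""
    T = np.asarray(T, dtype=float)
    y = np.asarray(y, dtype=float)
    dy = np.asarray(dy, dtype=float)
    if len(T) < 2:
        raise ValueError("need at least 2 temperatures (3 for interior stencils)")
    if np.any(np.diff(T) <= 0):
        raise ValueError("temperature grid must be strictly increasing")
    d = np.empty_like(y)
    err = np.empty_like(y)
    if len(T) > 2:
        d[1:-1] = (y[2:] - y[:-2]) / (T[2:] - T[:-2])
        err[1:-1] = np.sqrt(dy[2:] ** 2 + dy[:-2] ** 2) / (T[2:] - T[:-2])
    d[0] = (y[1] - y[0]) / (T[1] - T[0])
    err[0] = np.sqrt(dy[1] ** 2 + dy[0] ** 2) / (T[1] - T[0])
    d[-1] = (y[-1] - y[-2]) / (T[-1] - T[-2])
    err[-1] = np.sqrt(dy[-1] ** 2 + dy[-2] ** 2) / (T[-1] - T[-2])
    return d, err


def thermal_expansivity(
    T_grid: np.ndarray, rho: np.ndarray, rho_err: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Isobaric thermal expansivity ``α = −(1/ρ)(∂ρ/∂T)_p`` in K⁻¹.

    Finite differences over densities from independent runs on a
    temperature grid; uncertainties propagated from the density errors.
    """
    rho = np.asarray(rho, dtype=float)
    if rho_err is None:
        rho_err = np.zeros_like(rho)
    drho, derr = _central_difference(np.asarray(T_grid, float), rho, np.asarray(rho_err, float))
    return -drho / rho, np.abs(derr / rho)


def heat_capacity_difference(
    T_grid: np.ndarray, dvap_h: np.ndarray, dvap_h_err: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Vapor-minus-liquid heat capacity ``ΔvapCp = ∂ΔvapH/∂T``, kJ·mol⁻¹·K⁻¹."""
    dvap_h = np.asarray(dvap_h, dtype=float)
    if dvap_h_err is None:
        dvap_h_err = np.zeros_like(dvap_h)
    return _central_difference(
        np.asarray(T_grid, float), dvap_h, np.asarray(dvap_h_err, float)
    )


@dataclass
class RdfResult:
    """A site–site radial distribution function with coordination integral."""

    pair: tuple[str, str]
    bin_edges: np.ndarray
    g: np.ndarray
    coordination: np.ndarray
    counts: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def r(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def radial_distribution(
    trajectory: list[Configuration],
    templates: dict[str, MoleculeTemplate],
    pair: tuple[str, str],
    bin_width: float = 0.05,
    r_max: float | None = None,
) -> RdfResult:
    """Intermolecular g(r) between two site labels over a trajectory.

    Pair distances are accumulated under minimum image and normalized per
    frame by the ideal-gas shell expectation ``N_a·(N_b/V)·4πr²Δr`` (with
    the self pair removed for identical labels).  Intramolecular pairs are
    excluded.  The cumulative coordination number ``n(r)`` — average
    number of b-sites within r of an a-site — is reported alongside.
    """
    if not trajectory:
        raise ValueError("empty trajectory")
    la, lb = pair
    box0 = trajectory[0].box
    if r_max is None:
        r_max = 0.5 * float(box0.edge_lengths.min())
    if r_max > 0.5 * min(c.box.edge_lengths.min() for c in trajectory) + 1e-9:
        raise ValueError("r_max must not exceed half the smallest box edge")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max + 1e-12]
    counts = np.zeros(len(edges) - 1)
    norm = np.zeros(len(edges) - 1)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    n_a_total = 0
    for config in trajectory:
        pos_a, mol_a, pos_b, mol_b = [], [], [], []
        for i, mol in enumerate(config.molecules):
            tmpl = templates[mol.template_id]
            coords = instance_coordinates(mol, templates)
            for k, s in enumerate(tmpl.sites):
                if s.site_label == la:
                    pos_a.append(coords[k])
                    mol_a.append(i)
                if s.site_label == lb:
                    pos_b.append(coords[k])
                    mol_b.append(i)
        if not pos_a or not pos_b:
            continue
        pa = np.asarray(pos_a)
        pb = np.asarray(pos_b)
        ma = np.asarray(mol_a)
        mb = np.asarray(mol_b)
        d = minimum_image_displacement(pa[:, None, :], pb[None, :, :], config.box)
        r = np.sqrt((d ** 2).sum(axis=-1))
        inter = ma[:, None] != mb[None, :]
        r = r[inter]
        hist, _ = np.histogram(r, bins=edges)
        counts += hist
        rho_b = len(pb) / config.box.volume if la != lb else (len(pb) - 1) / config.box.volume
        norm += len(pa) * rho_b * shell_vol
        n_a_total += len(pa)
    g = np.divide(counts, norm, out=np.zeros_like(counts), where=norm > 0)
    coordination = (
        np.cumsum(counts) / (n_a_total if n_a_total else 1) * 1.0
    )
    # counts are summed over frames; coordination per a-site averages them
    return RdfResult((la, lb), edges, g, coordination, counts)
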