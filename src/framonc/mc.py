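"""Nested multipotential Metropolis Monte Carlo.

The sampler runs two coupled loops.  The *inner* loop performs ordinary
Metropolis moves (rigid translations, rotations, conformer swaps and — in
NpT — log-volume moves) on a cheap generator potential at *generating*
conditions ``(T_gen, p_gen)``.  After every ``P`` inner attempts the
resulting candidate configuration is assessed in the *outer* loop against
the expensive composite energy at the *target* conditions ``(T, p)``; a
rejected outer proposal discards the whole inner sequence and restores the
previous outer state exactly.  Assuming the inner sequence equilibrates
under the generator potential, the outer acceptance rule

``min{1, exp(−[ΔU_high + p·ΔV]/(R·T) + [ΔU_low + p_gen·ΔV]/(R·T_gen))}``

makes the outer chain's stationary distribution the target-ensemble
distribution of the high-level potential — whatever the generator is.
Because decorrelation is delegated to the inner loop, the outer loop can
and should run at high acceptance; an optional controller adapts ``T_gen``
until the observed outer acceptance sits inside a target window
(0.75–0.90 by default).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .mbe import CompositeEnergyModel, CompositeResult, _MonomerCache, composite_energy
from .potentials import (
    FFParameters,
    OverlapError,
    SiteArrays,
    _molecule_energy,
    _total_energy,
)
from .system import (
    Box,
    Configuration,
    MoleculeTemplate,
    axis_angle_quaternion,
    instance_coordinates,
    quaternion_multiply,
)
from .units import BAR_A3_TO_KJ_PER_MOL, R_GAS

__all__ = [
    "MoveSet",
    "NestedSpec",
    "ChainState",
    "FramoncResult",
    "metropolis_move",
    "run_inner_sequence",
    "outer_accept",
    "outer_acceptance_probability",
    "AdaptationController",
    "run_framonc",
]

MOVE_TYPES = ("translation", "rotation", "volume", "conformer")


@dataclass
class MoveSet:
    """Inner-loop move mixture: maximum step sizes and attempt weights."""

    max_translation: float = 0.25  # Å
    max_rotation: float = 0.25  # rad
    max_ln_volume_step: float = 0.02
    conformer_swap_probability: float = 0.0
    translation_weight: float = 0.5
    rotation_weight: float = 0.5
    volume_weight: float = 0.0

    def __post_init__(self) -> None:
        if min(self.max_translation, self.max_rotation, self.max_ln_volume_step) < 0:
            raise ValueError("move step sizes must be non-negative")
        if min(
            self.translation_weight,
            self.rotation_weight,
            self.volume_weight,
            self.conformer_swap_probability,
        ) < 0:
            raise ValueError("move weights must be non-negative")

    def weights(self, ensemble: str) -> np.ndarray:
        w = np.array(
            [
                self.translation_weight,
                self.rotation_weight,
                self.volume_weight if ensemble == "NpT" else 0.0,
                self.conformer_swap_probability,
            ]
        )
        tot = w.sum()
        if tot <= 0:
            raise ValueError("at least one move type must have positive weight")
        return w / tot


@dataclass
class NestedSpec:
    """Nested-chain schedule: period, target and generating conditions.

    ``T_gen``/``p_gen`` default to the target conditions.  When ``adapt``
    is on, ``T_gen`` is tuned between outer proposals until the outer
    acceptance rate observed over ``adapt_window`` proposals falls inside
    ``acceptance_window`` for two consecutive windows, then frozen.
    """

    period_P: int = 100
    T_target: float = 300.0
    p_target: float = 1.0
    T_gen: float | None = None
    p_gen: float | None = None
    ensemble: str = "NVT"
    adapt: bool = False
    acceptance_window: tuple[float, float] = (0.75, 0.90)
    adapt_window: int = 50
    adapt_kappa: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period_P < 1:
            raise ValueError("period_P must be >= 1")
        if self.T_target <= 0:
            raise ValueError("T_target must be positive")
        if self.ensemble not in ("NVT", "NpT"):
            raise ValueError(f"unknown ensemble {self.ensemble!r}")
        lo, hi = self.acceptance_window
        if not (0 < lo < hi <= 1):
            raise ValueError("acceptance window must satisfy 0 < lo < hi <= 1")
        if self.T_gen is None:
            self.T_gen = self.T_target
        if self.p_gen is None:
            self.p_gen = self.p_target


def _safe_exp(x: float) -> float:
    if x >= 0:
        return 1.0
    if x < -700:
        return 0.0
    return math.exp(x)


def _metropolis_probability(
    dU: float, dV: float, dlnV: float, n_mol: int, T: float, p: float, ensemble: str
) -> float:
    """Acceptance probability for one inner move (kJ·mol⁻¹, Å³, K, bar)."""
    if not np.isfinite(dU):
        return 0.0
    arg = -dU / (R_GAS * T)
    if ensemble == "NpT" and dlnV != 0.0:
        arg += -p * dV * BAR_A3_TO_KJ_PER_MOL / (R_GAS * T) + (n_mol + 1) * dlnV
    return min(1.0, _safe_exp(arg))


# ---------------------------------------------------------------------------
# Low-level sampler with incremental energy updates
# ---------------------------------------------------------------------------

class LowLevelSampler:
    """Metropolis sampler on the generator force field.

    Keeps flattened site arrays in sync with the configuration so that
    single-molecule moves cost one molecule-versus-rest energy evaluation;
    volume moves trigger a full recomputation.  Overlapping or overflowing
    proposals are rejected (infinite energy).
    """

    def __init__(
        self,
        config: Configuration,
        templates: dict[str, MoleculeTemplate],
        params: FFParameters,
        moveset: MoveSet,
        ensemble: str,
        rng_moves: np.random.Generator,
        rng_select: np.random.Generator,
    ) -> None:
        self.config = config
        self.templates = templates
        self.params = params
        self.moveset = moveset
        self.ensemble = ensemble
        self.rng = rng_moves
        self.rng_select = rng_select
        self.sa = SiteArrays.from_configuration(config, templates)
        self.e_total = self._full_energy()
        self.attempts = {m: 0 for m in MOVE_TYPES}
        self.accepts = {m: 0 for m in MOVE_TYPES}

    # -- energies -----------------------------------------------------
    def _full_energy(self) -> float:
        try:
            return _total_energy(self.sa, self.config.box, self.params)
        except OverlapError:
            return math.inf

    def _mol_energy(self, i: int) -> float:
        try:
            return _molecule_energy(self.sa, i, self.config.box, self.params)
        except OverlapError:
            return math.inf

    def refresh(self) -> None:
        self.sa = SiteArrays.from_configuration(self.config, self.templates)
        self.e_total = self._full_energy()

    # -- moves --------------------------------------------------------
    def attempt(self, T: float, p: float) -> bool:
        w = self.moveset.weights(self.ensemble)
        move = MOVE_TYPES[self.rng_select.choice(4, p=w)]
        self.attempts[move] += 1
        if move == "volume":
            ok = self._attempt_volume(T, p)
        else:
            ok = self._attempt_single(move, T)
        if ok:
            self.accepts[move] += 1
        return ok

    def _attempt_single(self, move: str, T: float) -> bool:
        n = self.config.n_molecules
        i = int(self.rng.integers(n))
        mol = self.config.molecules[i]
        old_com = mol.com_position.copy()
        old_q = mol.orientation.copy()
        old_conf = mol.conformer_index
        sl = self.sa.mol_slices[i]
        old_coords = self.sa.positions[sl].copy()

        e_old = self._mol_energy(i)
        if move == "translation":
            mol.com_position = self.config.box.wrap(
                old_com + (self.rng.random(3) - 0.5) * 2 * self.moveset.max_translation
            )
        elif move == "rotation":
            axis = self.rng.normal(size=3)
            angle = (self.rng.random() - 0.5) * 2 * self.moveset.max_rotation
            q = quaternion_multiply(axis_angle_quaternion(axis, angle), old_q)
            mol.orientation = q / np.linalg.norm(q)
        else:  # conformer swap
            n_conf = len(self.templates[mol.template_id].conformers)
            if n_conf < 2:
                return True  # no-op move, trivially accepted
            mol.conformer_index = int(self.rng.integers(n_conf))
        self.sa.positions[sl] = instance_coordinates(mol, self.templates)
        e_new = self._mol_energy(i)
        dU = e_new - e_old
        if self.rng.random() < _metropolis_probability(
            dU, 0.0, 0.0, n, T, 0.0, "NVT"
        ):
            if math.isfinite(dU):
                self.e_total += dU
            else:
                self.e_total = self._full_energy()
            return True
        mol.com_position = old_com
        mol.orientation = old_q
        mol.conformer_index = old_conf
        self.sa.positions[sl] = old_coords
        return False

    def _attempt_volume(self, T: float, p: float) -> bool:
        n = self.config.n_molecules
        box_old = Box(self.config.box.edge_lengths.copy())
        coms_old = [m.com_position.copy() for m in self.config.molecules]
        pos_old = self.sa.positions.copy()
        e_old = self.e_total
        if not math.isfinite(e_old):
            e_old = self._full_energy()
        v_old = box_old.volume
        dlnV = (self.rng.random() - 0.5) * 2 * self.moveset.max_ln_volume_step
        factor = math.exp(dlnV / 3.0)
        self.config.box = box_old.scaled(factor)
        for m in self.config.molecules:
            m.com_position = m.com_position * factor
        for i, m in enumerate(self.config.molecules):
            self.sa.positions[self.sa.mol_slices[i]] = instance_coordinates(
                m, self.templates
            )
        e_new = self._full_energy()
        dV = self.config.box.volume - v_old
        if self.rng.random() < _metropolis_probability(
            e_new - e_old, dV, dlnV, n, T, p, "NpT"
        ):
            self.e_total = e_new
            return True
        self.config.box = box_old
        for m, c in zip(self.config.molecules, coms_old):
            m.com_position = c
        self.sa.positions[:] = pos_old
        self.e_total = e_old
        return False


def metropolis_move(
    config: Configuration,
    templates: dict[str, MoleculeTemplate],
    moveset: MoveSet,
    params: FFParameters,
    T: float,
    p: float,
    ensemble: str,
    rng: np.random.Generator,
) -> tuple[Configuration, bool]:
    """One standard Metropolis move on a configuration (full recompute).

    Convenience wrapper over the incremental sampler for single-shot use;
    mutates and returns ``config``.
    """
    sampler = LowLevelSampler(
        config, templates, params, moveset, ensemble, rng, rng
    )
    accepted = sampler.attempt(T, p)
    config.cached_energy_low = sampler.e_total
    return config, accepted


def run_inner_sequence(
    sampler: LowLevelSampler, spec: NestedSpec
) -> tuple[Configuration, float]:
    """Run exactly ``P`` inner attempts at the generating conditions.

    Returns the (mutated, current) configuration and the generator-level
    energy change relative to the sequence start.
    """
    e_start = sampler.e_total
    for _ in range(spec.period_P):
        sampler.attempt(spec.T_gen, spec.p_gen)
    return sampler.config, sampler.e_total - e_start


def outer_acceptance_probability(
    dU_high: float, dU_low: float, dV: float, spec: NestedSpec
) -> float:
    """Nested outer-loop acceptance probability at target conditions."""
    if not (np.isfinite(dU_high) and np.isfinite(dU_low)):
        return 0.0
    pv_t = spec.p_target * dV * BAR_A3_TO_KJ_PER_MOL if spec.ensemble == "NpT" else 0.0
    pv_g = spec.p_gen * dV * BAR_A3_TO_KJ_PER_MOL if spec.ensemble == "NpT" else 0.0
    arg = -(dU_high + pv_t) / (R_GAS * spec.T_target) + (dU_low + pv_g) / (
        R_GAS * spec.T_gen
    )
    return min(1.0, _safe_exp(arg))


def outer_accept(
    dU_high: float,
    dU_low: float,
    dV: float,
    spec: NestedSpec,
    rng: np.random.Generator,
) -> tuple[float, bool]:
    """Decide one outer proposal; returns (probability, accepted)."""
    prob = outer_acceptance_probability(dU_high, dU_low, dV, spec)
    return prob, bool(rng.random() < prob)


class AdaptationController:
    """Windowed multiplicative tuner for the generating temperature.

    After each window of ``adapt_window`` outer proposals the observed
    acceptance ``a_obs`` is compared with the target window: inside it,
    nothing changes; outside it, ``T_gen ← T_gen·(1 + κ·(a_obs − a_mid))``
    clipped to ``[0.5, 2]·T_target``.  Two consecutive in-window
    observations freeze the controller; estimators treat everything before
    the freeze as burn-in.
    """

    def __init__(self, spec: NestedSpec) -> None:
        self.spec = spec
        self.frozen = not spec.adapt
        self._consecutive_ok = 0
        self._window_accepts = 0
        self._window_count = 0
        self.freeze_step: int | None = 0 if self.frozen else None
        self.history: list[tuple[int, float, float]] = []  # (step, a_obs, T_gen)

    def record(self, accepted: bool, outer_step: int) -> None:
        if self.frozen:
            return
        self._window_accepts += int(accepted)
        self._window_count += 1
        if self._window_count < self.spec.adapt_window:
            return
        a_obs = self._window_accepts / self._window_count
        self._window_accepts = 0
        self._window_count = 0
        lo, hi = self.spec.acceptance_window
        if lo <= a_obs <= hi:
            self._consecutive_ok += 1
            if self._consecutive_ok >= 2:
                self.frozen = True
                self.freeze_step = outer_step + 1
        else:
            self._consecutive_ok = 0
            a_mid = 0.5 * (lo + hi)
            t_new = self.spec.T_gen * (1 + self.spec.adapt_kappa * (a_obs - a_mid))
            t_new = min(max(t_new, 0.5 * self.spec.T_target), 2.0 * self.spec.T_target)
            self.spec.T_gen = t_new
        self.history.append((outer_step, a_obs, self.spec.T_gen))


@dataclass
class ChainState:
    """Snapshot of the outer chain for checkpoint/restart."""

    outer_step: int
    config: Configuration
    t_gen: float
    frozen: bool
    freeze_step: int | None
    rng_states: dict


@dataclass
class FramoncResult:
    """Everything a nested run produces.

    ``series`` values are recorded once per outer proposal (the retained
    state after the accept/reject decision), so they are a faithful sample
    of the outer chain.
    """

    trajectory: list[Configuration] = field(default_factory=list)
    series: dict[str, list[float]] = field(default_factory=dict)
    outer_accepted: list[bool] = field(default_factory=list)
    dimer_records: list = field(default_factory=list)
    t_gen_history: list[float] = field(default_factory=list)
    freeze_step: int | None = None
    inner_attempts: dict[str, int] = field(default_factory=dict)
    inner_accepts: dict[str, int] = field(default_factory=dict)
    final_state: ChainState | None = None

    @property
    def outer_acceptance_rate(self) -> float:
        if not self.outer_accepted:
            return float("nan")
        return float(np.mean(self.outer_accepted))

    def acceptance_rate_tail(self, n: int) -> float:
        tail = self.outer_accepted[-n:]
        return float(np.mean(tail)) if tail else float("nan")


def _spawn_rngs(seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    moves, select, outer = ss.spawn(3)
    return {
        "moves": np.random.default_rng(moves),
        "select": np.random.default_rng(select),
        "outer": np.random.default_rng(outer),
    }


def run_framonc(
    config: Configuration,
    templates: dict[str, MoleculeTemplate],
    low_params: FFParameters,
    model: CompositeEnergyModel,
    spec: NestedSpec,
    moveset: MoveSet,
    n_outer: int,
    record_pairs: bool = True,
    snapshot_stride: int = 1,
    material: str = "",
    log_fn=None,
    checkpoint_every: int = 0,
    checkpoint_path=None,
    tail_after_freeze: int | None = None,
) -> FramoncResult:
    """Run the full nested multipotential chain.

    Alternates inner sequences on the generator force field with composite
    (medium + high-level dimer correction) outer assessments.  Per outer
    proposal the density-relevant observables and, when ``record_pairs``
    is on, the dimer records of accepted composite evaluations are
    streamed into the result.  Fully reproducible for a fixed
    ``spec.seed``; rejected outer proposals restore the previous state
    exactly, energy caches included.

    When ``tail_after_freeze`` is given, the chain stops early once the
    adaptation controller has been frozen for that many further outer
    proposals (``n_outer`` remains a hard cap).
    """
    from .estimators import density  # local import to avoid a cycle

    rngs = _spawn_rngs(spec.seed)
    sampler = LowLevelSampler(
        config, templates, low_params, moveset, spec.ensemble,
        rngs["moves"], rngs["select"],
    )
    controller = AdaptationController(spec)
    cache = _MonomerCache()
    result = FramoncResult(
        series={"density": [], "volume": [], "u_high": [], "u_low": []}
    )

    current = config.copy()
    current_low = sampler.e_total
    current_comp = composite_energy(
        current, model, templates, cache, snapshot_id=-1,
        temperature=spec.T_target, material=material,
    )
    current_high = current_comp.total
    current.cached_energy_low = current_low
    current.cached_energy_high = current_high

    for step in range(n_outer):
        candidate, dU_low = run_inner_sequence(sampler, spec)
        cand_comp = composite_energy(
            candidate, model, templates, cache, snapshot_id=step,
            temperature=spec.T_target, material=material,
        )
        dU_high = cand_comp.total - current_high
        dV = candidate.box.volume - current.box.volume
        prob, accepted = outer_accept(dU_high, dU_low, dV, spec, rngs["outer"])
        if accepted:
            current = candidate.copy()
            sampler.refresh()  # re-sync incremental energy, bounding drift
            current_low = sampler.e_total
            current_high = cand_comp.total
            current.cached_energy_low = current_low
            current.cached_energy_high = current_high
            current_comp = cand_comp
            if record_pairs:
                result.dimer_records.extend(cand_comp.dimers)
        else:
            # discard the inner sequence: restore the pre-sequence state
            sampler.config.box = Box(current.box.edge_lengths.copy())
            sampler.config.molecules = [m.copy() for m in current.molecules]
            sampler.refresh()
            current_low = sampler.e_total
        result.outer_accepted.append(accepted)
        controller.record(accepted, step)
        result.t_gen_history.append(spec.T_gen)
        if step % snapshot_stride == 0:
            result.trajectory.append(current.copy())
        result.series["density"].append(density(current, templates))
        result.series["volume"].append(current.box.volume)
        result.series["u_high"].append(current_high)
        result.series["u_low"].append(current_low)
        if log_fn is not None:
            log_fn(
                {
                    "outer_step": step,
                    "accepted": accepted,
                    "prob": round(prob, 6),
                    "u_high": current_high,
                    "u_low": current_low,
                    "volume": current.box.volume,
                    "T_gen": spec.T_gen,
                }
            )
        if checkpoint_every and checkpoint_path and (step + 1) % checkpoint_every == 0:
            save_checkpoint(
                checkpoint_path,
                ChainState(step + 1, current.copy(), spec.T_gen,
                           controller.frozen, controller.freeze_step, {}),
                templates,
            )
        if (
            tail_after_freeze is not None
            and controller.frozen
            and controller.freeze_step is not None
            and step + 1 >= controller.freeze_step + tail_after_freeze
        ):
            break
    result.freeze_step = controller.freeze_step
    result.inner_attempts = dict(sampler.attempts)
    result.inner_accepts = dict(sampler.accepts)
    result.final_state = ChainState(
        len(result.outer_accepted), current.copy(), spec.T_gen,
        controller.frozen, controller.freeze_step, {},
    )
    return result


def save_checkpoint(path, state: ChainState, templates) -> None:
    """Write a self-contained JSON checkpoint of the outer chain."""
    payload = {
        "outer_step": state.outer_step,
        "t_gen": state.t_gen,
        "frozen": state.frozen,
        "freeze_step": state.freeze_step,
        "box": state.config.box.edge_lengths.tolist(),
        "molecules": [
            {
                "template_id": m.template_id,
                "com": m.com_position.tolist(),
                "quaternion": m.orientation.tolist(),
                "conformer": m.conformer_index,
            }
            for m in state.config.molecules
        ],
        "cached_energy_low": state.config.cached_energy_low,
        "cached_energy_high": state.config.cached_energy_high,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_checkpoint(path) -> ChainState:
    from .system import MoleculeInstance

    with open(path) as fh:
        payload = json.load(fh)
    config = Configuration(
        Box(np.array(payload["box"])),
        [
            MoleculeInstance(
                m["template_id"], np.array(m["com"]),
                np.array(m["quaternion"]), m["conformer"],
            )
            for m in payload["molecules"]
        ],
        payload.get("cached_energy_low"),
        payload.get("cached_energy_high"),
    )
    return ChainState(
        payload["outer_step"], config, payload["t_gen"],
        payload["frozen"], payload["freeze_step"], {},
    )
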