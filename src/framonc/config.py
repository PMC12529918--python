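"""TOML run specification and the end-to-end driver.

A run config declares the system (a preset or explicit templates), the
nested Monte Carlo schedule, the generator force field, the composite
many-body-expansion model (medium/high backends, dimer cutoff) and the
outputs.  :func:`run_from_config` executes generate → sample → analyze →
extract-pairs and writes every declared artifact with the config hash and
seed in its header.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .estimators import ScalarSeries, ThermoResult, radial_distribution
from .mbe import CompositeEnergyModel
from .mc import FramoncResult, MoveSet, NestedSpec, run_framonc
from .engine import EngineAdapterSpec, ExternalEngineBackend
from .pair_library import extract_pair_records, summarize_library, write_library
from .potentials import FFParameters, ForceFieldBackend, ZeroBackend
from .system import Box, Configuration, MoleculeTemplate, SiteSpec, place_molecules
from .toys import PRESETS, ToySystemSpec, generate_toy_system
from .units import MASS_PER_A3_TO_G_PER_CM3
from .xyz import configuration_to_frame, frame_to_string

__all__ = ["ConfigError", "load_config", "run_from_config", "default_config_toml"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """A schema violation, reported with the offending field path."""


def _req(table: dict, key: str, path: str):
    if key not in table:
        raise ConfigError(f"missing required field {path}.{key}")
    return table[key]


def _typed(table: dict, key: str, types, path: str, default=None):
    if key not in table:
        return default
    v = table[key]
    if isinstance(v, bool) and bool not in (types if isinstance(types, tuple) else (types,)):
        raise ConfigError(f"field {path}.{key} has wrong type bool")
    if not isinstance(v, types):
        raise ConfigError(
            f"field {path}.{key} has wrong type {type(v).__name__}"
        )
    return v


@dataclass
class RunConfig:
    """Validated, fully resolved run specification."""

    raw: dict
    preset: str | None
    templates: dict[str, MoleculeTemplate]
    counts: dict[str, int]
    density: float | None
    min_separation: float
    temperatures: list[float]
    pressure: float
    ensemble: str
    n_outer: int
    nested_kwargs: dict
    moveset: MoveSet
    ff_params: FFParameters
    model_factory: object  # callable () -> CompositeEnergyModel
    output_dir: Path
    record_pairs: bool
    snapshot_stride: int
    checkpoint_every: int
    vapor_run: bool
    rdf_pairs: list[tuple[str, str]]
    seed: int

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _parse_templates(raw_templates: list, path: str) -> dict[str, MoleculeTemplate]:
    templates = {}
    for ti, traw in enumerate(raw_templates):
        tpath = f"{path}[{ti}]"
        name = _req(traw, "name", tpath)
        sites_raw = _req(traw, "site", tpath)
        sites = []
        for si, sraw in enumerate(sites_raw):
            spath = f"{tpath}.site[{si}]"
            sites.append(
                SiteSpec(
                    _req(sraw, "element", spath),
                    _typed(sraw, "label", str, spath, _req(sraw, "element", spath)),
                    float(_typed(sraw, "charge", (int, float), spath, 0.0)),
                    float(_typed(sraw, "sigma", (int, float), spath, 0.0)),
                    float(_typed(sraw, "epsilon", (int, float), spath, 0.0)),
                    tuple(_req(sraw, "position", spath)),
                )
            )
        bonds = [tuple(b) for b in traw.get("bonds", [])]
        try:
            templates[name] = MoleculeTemplate(name, sites, bonds)
        except ValueError as exc:
            raise ConfigError(f"{tpath}: {exc}") from exc
    return templates


def _backend_factory(braw: dict, ff_params: FFParameters, path: str):
    btype = _typed(braw, "type", str, path, "ff")
    if btype == "ff":
        return ForceFieldBackend(ff_params, name=_typed(braw, "name", str, path, "ff"))
    if btype == "scaled_ff":
        return ForceFieldBackend(
            ff_params,
            epsilon_scale=float(_typed(braw, "epsilon_scale", (int, float), path, 1.0)),
            charge_scale=float(_typed(braw, "charge_scale", (int, float), path, 1.0)),
            name=_typed(braw, "name", str, path, None),
        )
    if btype == "zero":
        return ZeroBackend()
    if btype == "external":
        spec = EngineAdapterSpec(
            command_template=_req(braw, "command_template", path),
            energy_parse_pattern=_typed(
                braw, "energy_parse_pattern", str, path,
                EngineAdapterSpec.__dataclass_fields__["energy_parse_pattern"].default,
            ),
            workdir=_typed(braw, "workdir", str, path, None),
            timeout=float(_typed(braw, "timeout", (int, float), path, 60.0)),
        )
        return ExternalEngineBackend(spec, name=_typed(braw, "name", str, path, "external"))
    raise ConfigError(f"field {path}.type: unknown backend type {btype!r}")


def load_config(path) -> RunConfig:
    """Parse and validate a TOML run config; errors name the field path."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    version = raw.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"schema_version {version} unsupported (expected {SCHEMA_VERSION})")

    sys_raw = raw.get("system", {})
    preset = _typed(sys_raw, "preset", str, "system", None)
    if preset is not None and preset not in PRESETS:
        raise ConfigError(
            f"field system.preset: unknown preset {preset!r}; choose from {PRESETS}"
        )
    if preset is None:
        templates = _parse_templates(raw.get("template", []), "template")
        if not templates:
            raise ConfigError("either system.preset or [[template]] tables required")
        counts_raw = _req(sys_raw, "counts", "system")
        counts = {str(k): int(v) for k, v in counts_raw.items()}
    else:
        from .toys import toy_template

        tmpl = toy_template(preset)
        templates = {tmpl.name: tmpl}
        counts = {tmpl.name: int(_typed(sys_raw, "n_molecules", int, "system", 30))}

    mc_raw = raw.get("mc", {})
    ensemble = _typed(mc_raw, "ensemble", str, "mc", "NVT")
    if ensemble not in ("NVT", "NpT"):
        raise ConfigError(f"field mc.ensemble: must be 'NVT' or 'NpT', got {ensemble!r}")
    temps = mc_raw.get("temperature", 300.0)
    temperatures = [float(t) for t in (temps if isinstance(temps, list) else [temps])]
    seed = int(_typed(mc_raw, "seed", int, "mc", 0))
    window = mc_raw.get("acceptance_window", [0.75, 0.90])
    nested_kwargs = dict(
        period_P=int(_typed(mc_raw, "period_P", int, "mc", 100)),
        p_target=float(_typed(mc_raw, "pressure", (int, float), "mc", 1.0)),
        T_gen=mc_raw.get("T_gen"),
        p_gen=mc_raw.get("p_gen"),
        ensemble=ensemble,
        adapt=bool(mc_raw.get("adapt", False)),
        acceptance_window=(float(window[0]), float(window[1])),
        adapt_window=int(_typed(mc_raw, "adapt_window", int, "mc", 50)),
    )
    moveset = MoveSet(
        max_translation=float(_typed(mc_raw, "max_translation", (int, float), "mc", 0.25)),
        max_rotation=float(_typed(mc_raw, "max_rotation", (int, float), "mc", 0.25)),
        max_ln_volume_step=float(
            _typed(mc_raw, "max_ln_volume_step", (int, float), "mc", 0.02)
        ),
        conformer_swap_probability=float(
            _typed(mc_raw, "conformer_swap_probability", (int, float), "mc", 0.0)
        ),
        volume_weight=float(
            _typed(mc_raw, "volume_weight", (int, float), "mc",
                   0.1 if ensemble == "NpT" else 0.0)
        ),
    )

    ff_raw = raw.get("forcefield", {})
    try:
        ff_params = FFParameters(
            combining_rule=_typed(ff_raw, "combining_rule", str, "forcefield",
                                  "lorentz_berthelot"),
            r_cut=ff_raw.get("r_cut"),
            coulomb_damping=float(
                _typed(ff_raw, "coulomb_damping", (int, float), "forcefield", 0.2)
            ),
            tail_correction=bool(ff_raw.get("tail_correction", False)),
        )
    except ValueError as exc:
        raise ConfigError(f"forcefield: {exc}") from exc

    mbe_raw = raw.get("mbe", {})
    dimer_cutoff = float(_typed(mbe_raw, "dimer_cutoff", (int, float), "mbe", 4.0))
    medium_raw = mbe_raw.get("medium", {"type": "ff"})
    high_raw = mbe_raw.get("high", {"type": "ff"})

    def model_factory() -> CompositeEnergyModel:
        return CompositeEnergyModel(
            _backend_factory(medium_raw, ff_params, "mbe.medium"),
            _backend_factory(high_raw, ff_params, "mbe.high"),
            dimer_cutoff,
        )

    out_raw = raw.get("output", {})
    rdf_raw = out_raw.get("rdf_pairs", [])
    return RunConfig(
        raw=raw,
        preset=preset,
        templates=templates,
        counts=counts,
        density=sys_raw.get("density"),
        min_separation=float(
            _typed(sys_raw, "min_separation", (int, float), "system", 1.5)
        ),
        temperatures=temperatures,
        pressure=float(_typed(mc_raw, "pressure", (int, float), "mc", 1.0)),
        ensemble=ensemble,
        n_outer=int(_typed(mc_raw, "n_outer", int, "mc", 100)),
        nested_kwargs=nested_kwargs,
        moveset=moveset,
        ff_params=ff_params,
        model_factory=model_factory,
        output_dir=Path(_typed(out_raw, "directory", str, "output", "framonc_out")),
        record_pairs=bool(out_raw.get("record_pairs", True)),
        snapshot_stride=int(_typed(out_raw, "snapshot_stride", int, "output", 1)),
        checkpoint_every=int(_typed(out_raw, "checkpoint_every", int, "output", 0)),
        vapor_run=bool(out_raw.get("vapor_run", False)),
        rdf_pairs=[(str(p[0]), str(p[1])) for p in rdf_raw],
        seed=seed,
    )


def _build_initial_configuration(cfg: RunConfig, seed: int) -> Configuration:
    if cfg.preset is not None:
        spec = ToySystemSpec(
            cfg.preset,
            n_molecules=sum(cfg.counts.values()),
            density=cfg.density,
            seed=seed,
        )
        config, _ = generate_toy_system(spec, cfg.min_separation)
        return config
    mass = sum(
        cfg.templates[t].molar_mass * n for t, n in cfg.counts.items()
    )
    density = cfg.density or 0.8
    edge = (mass * MASS_PER_A3_TO_G_PER_CM3 / density) ** (1 / 3)
    return place_molecules(
        cfg.templates, cfg.counts, Box(np.full(3, edge)), cfg.min_separation, seed
    )


def _vapor_configuration(cfg: RunConfig, seed: int) -> Configuration:
    """Single molecule surrounded by void space (ideal-gas vapor box)."""
    tid = next(iter(cfg.counts))
    box = Box(np.full(3, 60.0))
    return place_molecules(cfg.templates, {tid: 1}, box, 0.0, seed)


def run_from_config(path, overrides: dict | None = None) -> dict:
    """Execute the full pipeline declared in a TOML config.

    Per temperature on the grid: build the box, run the nested chain,
    stream observables, optionally run the companion single-molecule vapor
    box, then derive the thermodynamic table and extract the
    pair-interaction library.  Returns a manifest of written artifacts.
    """
    cfg = load_config(path)
    if overrides:
        for k, v in overrides.items():
            setattr(cfg, k, v)
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    header = {"config_hash": cfg.config_hash, "seed": cfg.seed}
    manifest: dict[str, object] = {"outputs": [], "temperatures": cfg.temperatures}

    restart_from = getattr(cfg, "restart_from", None)
    rho_means, rho_errs, dh_means, dh_errs = [], [], [], []
    all_entries = []
    for ti, T in enumerate(cfg.temperatures):
        run_seed = cfg.seed + 1000 * ti
        nested_kwargs = dict(cfg.nested_kwargs)
        if restart_from is not None and ti == 0:
            from .mc import load_checkpoint

            state = load_checkpoint(restart_from)
            config = state.config
            nested_kwargs["T_gen"] = state.t_gen
            if state.frozen:
                nested_kwargs["adapt"] = False
        else:
            config = _build_initial_configuration(cfg, run_seed)
        spec = NestedSpec(T_target=T, seed=run_seed, **nested_kwargs)
        model = cfg.model_factory()
        log_path = out / f"run_T{T:g}.log.jsonl"
        with open(log_path, "w") as log_fh:
            log_fh.write(json.dumps(header) + "\n")
            result = run_framonc(
                config, cfg.templates, cfg.ff_params, model, spec, cfg.moveset,
                cfg.n_outer, record_pairs=cfg.record_pairs,
                snapshot_stride=cfg.snapshot_stride,
                material=cfg.preset or "custom",
                log_fn=lambda rec: log_fh.write(json.dumps(rec) + "\n"),
                checkpoint_every=cfg.checkpoint_every,
                checkpoint_path=out / f"checkpoint_T{T:g}.json",
            )
        manifest["outputs"].append(str(log_path))
        from .mc import save_checkpoint

        chk_path = out / f"checkpoint_T{T:g}.json"
        save_checkpoint(chk_path, result.final_state, cfg.templates)
        manifest["outputs"].append(str(chk_path))

        burn = _default_burn_in(result)
        rho = ScalarSeries(result.series["density"], "g/cm^3", burn)
        u_high = ScalarSeries(result.series["u_high"], "kJ/mol", burn)
        vol = ScalarSeries(result.series["volume"], "A^3", burn)
        rho_means.append(rho.mean)
        rho_errs.append(_safe_sem(rho))

        traj_path = out / f"trajectory_T{T:g}.extxyz"
        with open(traj_path, "w") as fh:
            for k, snap in enumerate(result.trajectory):
                fh.write(
                    frame_to_string(
                        configuration_to_frame(
                            snap, cfg.templates,
                            {"snapshot": k, **header},
                        )
                    )
                )
        manifest["outputs"].append(str(traj_path))

        series_path = out / f"series_T{T:g}.tsv"
        with open(series_path, "w") as fh:
            fh.write(f"# config_hash={cfg.config_hash} seed={cfg.seed} burn_in={burn}\n")
            fh.write("outer_step\taccepted\tdensity\tvolume\tu_high\tu_low\n")
            for k in range(len(result.series["density"])):
                fh.write(
                    f"{k}\t{int(result.outer_accepted[k])}\t"
                    f"{result.series['density'][k]:.8f}\t"
                    f"{result.series['volume'][k]:.6f}\t"
                    f"{result.series['u_high'][k]:.8f}\t"
                    f"{result.series['u_low'][k]:.8f}\n"
                )
        manifest["outputs"].append(str(series_path))

        if cfg.vapor_run:
            vconfig = _vapor_configuration(cfg, run_seed + 1)
            vspec = NestedSpec(
                T_target=T, seed=run_seed + 1,
                **{**cfg.nested_kwargs, "ensemble": "NVT", "adapt": False},
            )
            vresult = run_framonc(
                vconfig, cfg.templates, cfg.ff_params, cfg.model_factory(), vspec,
                cfg.moveset, max(cfg.n_outer // 2, 20), record_pairs=False,
            )
            u_gas = ScalarSeries(vresult.series["u_high"], "kJ/mol",
                                 _default_burn_in(vresult))
            from .estimators import vaporization_enthalpy

            dh, dh_err = vaporization_enthalpy(
                u_high, vol, sum(cfg.counts.values()), cfg.pressure, T, u_gas
            )
            dh_means.append(dh)
            dh_errs.append(dh_err)

        if cfg.record_pairs:
            entries = extract_pair_records(
                result.trajectory, model, cfg.templates,
                temperature=T, pressure=cfg.pressure,
                material=cfg.preset or "custom",
            )
            all_entries.extend(entries)

        for pair in cfg.rdf_pairs:
            rdf = radial_distribution(result.trajectory[burn:] or result.trajectory,
                                      cfg.templates, pair)
            rdf_path = out / f"rdf_{pair[0]}_{pair[1]}_T{T:g}.tsv"
            with open(rdf_path, "w") as fh:
                fh.write(f"# config_hash={cfg.config_hash} seed={cfg.seed}\n")
                fh.write("r_A\tg\tcoordination\n")
                for r, g, c in zip(rdf.r, rdf.g, rdf.coordination):
                    fh.write(f"{r:.4f}\t{g:.6f}\t{c:.6f}\n")
            manifest["outputs"].append(str(rdf_path))

    if len(cfg.temperatures) >= 2:
        thermo = ThermoResult(
            np.array(cfg.temperatures),
            np.array(rho_means), np.array(rho_errs),
            np.array(dh_means) if dh_means else np.zeros(len(cfg.temperatures)),
            np.array(dh_errs) if dh_errs else np.zeros(len(cfg.temperatures)),
        ).with_derivatives()
        results_path = out / "results.tsv"
        with open(results_path, "w") as fh:
            fh.write(f"# config_hash={cfg.config_hash} seed={cfg.seed}\n")
            fh.write(thermo.to_table())
        manifest["outputs"].append(str(results_path))
        manifest["thermo"] = {
            "T": list(map(float, thermo.T_grid)),
            "rho": list(map(float, thermo.rho)),
            "alpha": list(map(float, thermo.alpha)),
        }
    else:
        manifest["thermo"] = {"T": cfg.temperatures, "rho": rho_means}

    if all_entries:
        lib_path = out / "pair_library.extxyz"
        write_library(all_entries, lib_path)
        summary = summarize_library(all_entries)
        summary_path = out / "pair_library_summary.tsv"
        with open(summary_path, "w") as fh:
            fh.write(f"# config_hash={cfg.config_hash} seed={cfg.seed}\n")
            fh.write(summary.to_tsv())
        manifest["outputs"] += [str(lib_path), str(summary_path)]
    manifest["n_pair_entries"] = len(all_entries)
    manifest["rho_mean"] = rho_means
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _safe_sem(series: ScalarSeries) -> float:
    """Block-doubling SEM, or the naive estimate for very short series."""
    try:
        return series.sem
    except ValueError:
        v = series.production
        return float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0


def _default_burn_in(result: FramoncResult) -> int:
    """Pre-freeze samples plus 10% of the remainder, capped below n−16."""
    n = len(result.series["density"])
    freeze = result.freeze_step or 0
    burn = freeze + int(0.1 * max(n - freeze, 0))
    return min(burn, max(n - 16, 0))


def default_config_toml(preset: str = "toy_water") -> str:
    """A commented starter config for ``framonc init``."""
    return f"""\
schema_version = 1

[system]
preset = "{preset}"      # {", ".join(PRESETS)}
n_molecules = 30
# density = 1.0          # g/cm^3; omit for the preset default

[mc]
ensemble = "NpT"         # NVT | NpT
temperature = 300.0      # K; may be a list for a temperature grid
pressure = 1.0           # bar
period_P = 20            # inner attempts per outer proposal
n_outer = 200            # outer proposals
seed = 1
adapt = true             # tune T_gen toward the acceptance window
acceptance_window = [0.75, 0.90]
max_translation = 0.25   # Angstrom
max_rotation = 0.25      # rad
max_ln_volume_step = 0.02
volume_weight = 0.1

[forcefield]
combining_rule = "lorentz_berthelot"
coulomb_damping = 0.2    # 1/Angstrom
tail_correction = false

[mbe]
dimer_cutoff = 4.0       # Angstrom, closest-contact cutoff for dimers

[mbe.medium]
type = "ff"

[mbe.high]
type = "scaled_ff"
epsilon_scale = 1.05

[output]
directory = "framonc_out"
record_pairs = true
vapor_run = false
rdf_pairs = [["O", "O"]]
"""
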