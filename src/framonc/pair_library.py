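"""Pair-interaction energy libraries.

Every composite-energy evaluation of an accepted configuration yields one
interaction energy per proximate dimer at both the high and the medium
level.  Collected over a run, these form a library of two-level dimer
interaction energies with full geometries — a data set suitable for later
fitting of pair potentials.  Libraries are stored as multi-frame
extended-XYZ: one frame per dimer, energies and contact metadata in the
comment line.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .mbe import CompositeEnergyModel, DimerRecord, classify_contact, enumerate_proximate_dimers
from .potentials import fragment_from_molecules
from .system import Configuration, MoleculeTemplate
from .xyz import XYZFrame, read_frames, write_frames

__all__ = [
    "PairLibraryEntry",
    "LibrarySummary",
    "extract_pair_records",
    "write_library",
    "read_library",
    "summarize_library",
]


@dataclass
class PairLibraryEntry:
    """One dimer: record + contiguous free-space geometry + provenance."""

    record: DimerRecord
    elements: list[str]
    labels: list[str]
    positions: np.ndarray  # (n, 3) Å, minimum-image reassembled
    mol_split: int  # first site index of the second molecule
    template_ids: tuple[str, str]
    pressure: float = float("nan")
    backend_high: str = ""
    backend_medium: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if not np.isfinite(self.record.e_int_high) or not np.isfinite(
            self.record.e_int_medium
        ):
            raise ValueError("interaction energies must be finite")


@dataclass
class LibrarySummary:
    """Per-contact-class counts and (distance, energy) 2D histograms."""

    class_counts: dict[str, int]
    class_median_e_high: dict[str, float]
    histograms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    total: int

    def to_tsv(self) -> str:
        lines = ["contact_class\tcount\tmedian_e_int_high_kJmol\n"]
        for cls in sorted(self.class_counts, key=lambda c: -self.class_counts[c]):
            lines.append(
                f"{cls}\t{self.class_counts[cls]}\t"
                f"{self.class_median_e_high[cls]:.4f}\n"
            )
        return "".join(lines)


def extract_pair_records(
    trajectory: list[Configuration],
    model: CompositeEnergyModel,
    templates: dict[str, MoleculeTemplate],
    temperature: float = float("nan"),
    pressure: float = float("nan"),
    material: str = "",
) -> list[PairLibraryEntry]:
    """Build library entries for every (snapshot, proximate dimer).

    Fragment backends are pure functions of geometry, so replaying the
    stored trajectory through the composite-energy breakdown reproduces
    the energies computed during the run.  One entry per (snapshot,
    dimer), no duplicates; the entry count equals the total
    proximate-dimer count over the trajectory.
    """
    from .mbe import _MonomerCache, composite_energy

    if trajectory is None:
        raise ValueError("run was not recorded: no trajectory available")
    entries: list[PairLibraryEntry] = []
    cache = _MonomerCache()
    for snap_id, config in enumerate(trajectory):
        records = composite_energy(
            config, model, templates, cache, snapshot_id=snap_id,
            temperature=temperature, material=material,
        ).dimers
        for rec in records:
            i, j = rec.mol_ids
            mi, mj = config.molecules[i], config.molecules[j]
            frag = fragment_from_molecules([mi, mj], templates, config.box)
            n_i = templates[mi.template_id].n_sites
            entries.append(
                PairLibraryEntry(
                    DimerRecord(
                        rec.mol_ids, rec.contact_distance, rec.contact_labels,
                        rec.contact_class, rec.e_int_high, rec.e_int_medium,
                        snap_id,
                        rec.temperature if np.isfinite(rec.temperature) else temperature,
                        rec.material or material,
                    ),
                    frag.elements,
                    frag.labels,
                    frag.positions,
                    n_i,
                    (mi.template_id, mj.template_id),
                    pressure,
                    model.high.name,
                    model.medium.name,
                )
            )
    return entries


def _entry_to_frame(e: PairLibraryEntry) -> XYZFrame:
    info = {
        "e_int_high": float(e.record.e_int_high),
        "e_int_medium": float(e.record.e_int_medium),
        "contact_distance": float(e.record.contact_distance),
        "contact_class": e.record.contact_class,
        "contact_labels": ",".join(e.record.contact_labels),
        "mol_ids": f"{e.record.mol_ids[0]},{e.record.mol_ids[1]}",
        "snapshot_id": int(e.record.snapshot_id),
        "T": float(e.record.temperature),
        "p": float(e.pressure),
        "material": e.record.material or "-",
        "mol_split": e.mol_split,
        "template_ids": ",".join(e.template_ids),
        "backend_high": e.backend_high or "-",
        "backend_medium": e.backend_medium or "-",
    }
    return XYZFrame(
        list(e.elements),
        e.positions,
        info,
        {"site_label": list(e.labels)},
    )


def _frame_to_entry(fr: XYZFrame, index: int) -> PairLibraryEntry:
    try:
        info = fr.info
        mol_ids = tuple(int(x) for x in str(info["mol_ids"]).split(","))
        labels = str(info["contact_labels"]).split(",")
        tids = tuple(str(info["template_ids"]).split(","))
        rec = DimerRecord(
            (mol_ids[0], mol_ids[1]),
            float(info["contact_distance"]),
            (labels[0], labels[1]),
            str(info["contact_class"]),
            float(info["e_int_high"]),
            float(info["e_int_medium"]),
            int(info["snapshot_id"]),
            float(info["T"]),
            "" if info.get("material") in ("-", None) else str(info["material"]),
        )
        return PairLibraryEntry(
            rec,
            fr.symbols,
            list(fr.arrays.get("site_label", fr.symbols)),
            fr.positions,
            int(info["mol_split"]),
            (tids[0], tids[1]),
            float(info["p"]),
            "" if info.get("backend_high") in ("-", None) else str(info["backend_high"]),
            "" if info.get("backend_medium") in ("-", None) else str(info["backend_medium"]),
        )
    except (KeyError, ValueError, IndexError) as exc:
        raise ValueError(f"malformed library frame {index}: {exc}") from exc


def write_library(entries: list[PairLibraryEntry], path) -> None:
    """Write a library as multi-frame extended-XYZ (canonical formatting)."""
    write_frames([_entry_to_frame(e) for e in entries], path)


def read_library(path) -> list[PairLibraryEntry]:
    """Read a library file back; refuses partially parseable files."""
    frames = read_frames(path)
    return [_frame_to_entry(fr, i) for i, fr in enumerate(frames)]


def summarize_library(
    entries: list[PairLibraryEntry],
    distance_bins: np.ndarray | None = None,
    energy_bins: np.ndarray | None = None,
) -> LibrarySummary:
    """Per-contact-class counts, median energies and 2D histograms.

    The histograms bin (contact distance, high-level interaction energy)
    per class — the data behind a distance–energy scatter colored by
    contact type.
    """
    counts = Counter(e.record.contact_class for e in entries)
    medians: dict[str, float] = {}
    hists: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    if entries:
        all_d = np.array([e.record.contact_distance for e in entries])
        all_e = np.array([e.record.e_int_high for e in entries])
        if distance_bins is None:
            distance_bins = np.linspace(all_d.min() - 1e-9, all_d.max() + 1e-9, 25)
        if energy_bins is None:
            energy_bins = np.linspace(all_e.min() - 1e-9, all_e.max() + 1e-9, 25)
        for cls in counts:
            sel = [e for e in entries if e.record.contact_class == cls]
            d = np.array([e.record.contact_distance for e in sel])
            en = np.array([e.record.e_int_high for e in sel])
            medians[cls] = float(np.median(en))
            h, xe, ye = np.histogram2d(d, en, bins=[distance_bins, energy_bins])
            hists[cls] = (h, xe, ye)
    return LibrarySummary(dict(counts), medians, hists, len(entries))


def plot_summary(entries: list[PairLibraryEntry], path) -> None:
    """Contact-distance vs interaction-energy scatter colored by class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    classes = sorted({e.record.contact_class for e in entries})
    fig, ax = plt.subplots(figsize=(5, 4))
    for cls in classes:
        sel = [e for e in entries if e.record.contact_class == cls]
        ax.scatter(
            [e.record.contact_distance for e in sel],
            [e.record.e_int_high for e in sel],
            s=4, alpha=0.5, label=cls,
        )
    ax.set_xlabel("closest contact distance (Å)")
    ax.set_ylabel("pair interaction energy (kJ·mol⁻¹)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
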