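"""File I/O and validated domain containers for the amphidinol pipeline.

Amphidinols (AMs) ionize almost exclusively as singly charged sodium
adducts, and all mass arithmetic downstream operates directly on the
observed adduct m/z; nothing in this package converts to neutral masses.
Retention times are stored in minutes (MGF ``RTINSECONDS`` is converted
on read). The instrument is unit-resolution, so masses are kept as
decimals but matched elsewhere with an absolute tolerance (default
0.5 Da).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "TransitionEntry",
    "TransitionTable",
    "PeakAreaRecord",
    "WellCount",
    "CountTables",
    "SpectrumError",
    "ValidationError",
    "read_mgf",
    "write_mgf",
    "read_transition_table",
    "write_transition_table",
    "default_transition_table",
    "read_peak_areas",
    "read_count_tables",
]


class SpectrumError(ValueError):
    """A spectrum violates its structural invariants."""


class ValidationError(ValueError):
    """A tabular input violates its documented contract."""


@dataclass(frozen=True)
class Spectrum:
    """One CID product-ion scan of a sodium-adduct precursor.

    ``fragments`` is an ascending-m/z list of ``(mz, intensity)`` pairs;
    the low-abundance precursor ion itself is usually present as the
    last fragment.
    """

    spectrum_id: str
    precursor_mz: float
    rt_min: float
    fragments: tuple[tuple[float, float], ...]
    strain_id: str = ""

    def __post_init__(self) -> None:
        if not self.precursor_mz > 0:
            raise SpectrumError(
                f"{self.spectrum_id}: precursor_mz must be > 0, got {self.precursor_mz}"
            )
        frags = tuple((float(m), float(i)) for m, i in self.fragments)
        mzs = [m for m, _ in frags]
        if any(i < 0 for _, i in frags):
            raise SpectrumError(f"{self.spectrum_id}: negative fragment intensity")
        if any(m >= self.precursor_mz + 1.0 for m in mzs):
            raise SpectrumError(
                f"{self.spectrum_id}: fragment m/z above precursor {self.precursor_mz}"
            )
        if mzs != sorted(mzs):
            frags = tuple(sorted(frags))
        object.__setattr__(self, "fragments", frags)

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([m for m, _ in self.fragments], dtype=float)

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([i for _, i in self.fragments], dtype=float)

    def base_peak_mz(self) -> float:
        """m/z of the most intense fragment."""
        if not self.fragments:
            raise SpectrumError(f"{self.spectrum_id}: empty fragment list")
        return max(self.fragments, key=lambda f: f[1])[0]


@dataclass(frozen=True)
class TransitionEntry:
    """One SRM transition: AM variant name, Q1/Q3 masses and retention time."""

    variant_name: str
    q1_mz: float
    q3_mz: float
    rt_min: float
    sulfated: bool

    def __post_init__(self) -> None:
        if not self.q3_mz < self.q1_mz:
            raise ValidationError(
                f"{self.variant_name}: q3 ({self.q3_mz}) must be < q1 ({self.q1_mz})"
            )
        if not self.rt_min > 0:
            raise ValidationError(f"{self.variant_name}: rt_min must be > 0")


@dataclass
class TransitionTable:
    """Library of known AM variants used for SRM detection and matching."""

    entries: list[TransitionEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.variant_name for e in self.entries]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValidationError(f"duplicate variant names: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def names(self) -> list[str]:
        return [e.variant_name for e in self.entries]

    def without(self, names: Iterable[str]) -> "TransitionTable":
        drop = set(names)
        return TransitionTable([e for e in self.entries if e.variant_name not in drop])


@dataclass(frozen=True)
class PeakAreaRecord:
    """One integrated chromatographic peak for a (strain, variant) pair."""

    strain_id: str
    variant_name: str
    peak_area: float
    snr: float = math.inf

    def __post_init__(self) -> None:
        if self.peak_area < 0:
            raise ValidationError(
                f"{self.strain_id}/{self.variant_name}: peak_area must be >= 0"
            )
        if self.snr < 0:
            raise ValidationError(
                f"{self.strain_id}/{self.variant_name}: snr must be >= 0"
            )


@dataclass(frozen=True)
class WellCount:
    """Dead-individual counts for one well of a 24-well brine-shrimp plate."""

    well_type: str  # treatment | dmso_control | seawater_control
    initial_dead: int
    dead_24h: int
    dead_48h: int
    total: int

    def __post_init__(self) -> None:
        if self.well_type not in ("treatment", "dmso_control", "seawater_control"):
            raise ValidationError(f"unknown well_type {self.well_type!r}")
        for name in ("initial_dead", "dead_24h", "dead_48h"):
            v = getattr(self, name)
            if v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")
            if v > self.total:
                raise ValidationError(
                    f"{name}={v} exceeds total={self.total} individuals in well"
                )


@dataclass
class CountTables:
    """Cell counts and brine-shrimp assay well counts, keyed by strain.

    ``cell_counts`` maps strain_id -> (n_cells, sample_volume_ul);
    ``assay_counts`` maps strain_id -> list of :class:`WellCount`.
    """

    cell_counts: dict[str, tuple[int, float]]
    assay_counts: dict[str, list[WellCount]]

    def __post_init__(self) -> None:
        for strain, (n, vol) in self.cell_counts.items():
            if n <= 0:
                raise ValidationError(f"{strain}: n_cells must be > 0")
            if vol <= 0:
                raise ValidationError(f"{strain}: sample_volume_ul must be > 0")
        for strain, wells in self.assay_counts.items():
            n_treat = sum(1 for w in wells if w.well_type == "treatment")
            if n_treat != 3:
                logger.warning(
                    "strain %s has %d treatment wells (expected 3)", strain, n_treat
                )
            if strain not in self.cell_counts:
                logger.warning(
                    "strain %s present in assay counts but missing from cell counts; "
                    "excluded from cell-quota computation",
                    strain,
                )


# ---------------------------------------------------------------------------
# MGF I/O


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read CID spectra from an MGF file (BEGIN IONS blocks).

    PEPMASS is taken as the sodium-adduct precursor m/z, RTINSECONDS is
    converted to minutes, TITLE becomes the spectrum id and an optional
    STRAIN parameter is carried through. Blocks lacking PEPMASS are
    rejected with a warning; malformed blocks raise a parse error that
    names the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra: list[Spectrum] = []
    try:
        with _mgf.read(str(path), use_index=False) as reader:
            for k, raw in enumerate(reader):
                params = raw.get("params", {})
                title = str(params.get("title", f"scan_{k}"))
                if "pepmass" not in params:
                    logger.warning(
                        "%s: block %r has no PEPMASS; rejected", path.name, title
                    )
                    continue
                pepmass = params["pepmass"]
                precursor = float(pepmass[0] if isinstance(pepmass, tuple) else pepmass)
                rt_min = float(params.get("rtinseconds", 0.0)) / 60.0
                frags = tuple(
                    zip(
                        (float(m) for m in raw["m/z array"]),
                        (float(i) for i in raw["intensity array"]),
                    )
                )
                spectra.append(
                    Spectrum(
                        spectrum_id=title,
                        precursor_mz=precursor,
                        rt_min=rt_min,
                        fragments=frags,
                        strain_id=str(params.get("strain", "")),
                    )
                )
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        if isinstance(exc, (SpectrumError, FileNotFoundError)):
            raise
        raise ValidationError(f"malformed MGF {path}: {exc}") from exc
    if not spectra:
        logger.warning("%s: no spectra read", path.name)
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path: str | Path) -> Path:
    """Write spectra as MGF; m/z at 4 decimals, intensity at 2.

    ``read_mgf(write_mgf(x))`` reproduces ``x`` at that precision.
    """
    path = Path(path)
    blocks = []
    for s in spectra:
        params = {
            "title": s.spectrum_id,
            "pepmass": round(s.precursor_mz, 4),
            "rtinseconds": round(s.rt_min * 60.0, 4),
        }
        if s.strain_id:
            params["strain"] = s.strain_id
        blocks.append(
            {
                "m/z array": s.mz_array,
                "intensity array": s.intensity_array,
                "params": params,
            }
        )
    with open(path, "w") as fh:
        _mgf.write(blocks, fh, fragment_format="{:.4f} {:.2f}")
    return path


# ---------------------------------------------------------------------------
# CSV tables

_TRANSITION_COLS = ["variant_name", "q1_mz", "q3_mz", "rt_min", "sulfated"]


def read_transition_table(path: str | Path) -> TransitionTable:
    """Read an SRM transition library CSV.

    Header: ``variant_name,q1_mz,q3_mz,rt_min,sulfated``. Rows with
    q3 >= q1 or duplicate variant names are rejected, naming the row.
    """
    df = pd.read_csv(path, comment="#")
    missing = set(_TRANSITION_COLS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    entries = []
    for idx, row in df.iterrows():
        try:
            entries.append(
                TransitionEntry(
                    variant_name=str(row["variant_name"]),
                    q1_mz=float(row["q1_mz"]),
                    q3_mz=float(row["q3_mz"]),
                    rt_min=float(row["rt_min"]),
                    sulfated=_parse_bool(row["sulfated"]),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {idx + 2}: {exc}") from exc
    return TransitionTable(entries)


def write_transition_table(table: TransitionTable, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "variant_name": e.variant_name,
                "q1_mz": e.q1_mz,
                "q3_mz": e.q3_mz,
                "rt_min": e.rt_min,
                "sulfated": e.sulfated,
            }
            for e in table
        ],
        columns=_TRANSITION_COLS,
    ).to_csv(path, index=False)
    return path


def default_transition_table() -> TransitionTable:
    """The shipped transition library.

    Contains only the eight ARC variants, whose Q1 masses, retention
    times and C1/C1' cleavage fragments (used as Q3) are recoverable
    from the published description; the full known-AM transition list
    is instrument-method metadata and is supplied by the user as an
    editable CSV with the same header.
    """
    ref = resources.files("amphiscan").joinpath("data/transitions.csv")
    with resources.as_file(ref) as p:
        return read_transition_table(p)


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "yes", "t"):
        return True
    if s in ("false", "0", "no", "f"):
        return False
    raise ValidationError(f"cannot parse boolean {v!r}")


def read_peak_areas(path: str | Path) -> list[PeakAreaRecord]:
    """Read a chromatographic peak-area table CSV.

    Header: ``strain_id,variant_name,peak_area[,snr]``.
    """
    df = pd.read_csv(path, comment="#")
    required = {"strain_id", "variant_name", "peak_area"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                PeakAreaRecord(
                    strain_id=str(row["strain_id"]),
                    variant_name=str(row["variant_name"]),
                    peak_area=float(row["peak_area"]),
                    snr=float(row["snr"]) if "snr" in df.columns else math.inf,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {idx + 2}: {exc}") from exc
    return records


def read_count_tables(path_cells: str | Path, path_assay: str | Path) -> CountTables:
    """Read cell-count and brine-shrimp assay CSVs into a :class:`CountTables`.

    ``path_cells`` header: ``strain_id,n_cells,sample_volume_ul``.
    ``path_assay`` header:
    ``strain_id,well_type,initial_dead,dead_24h,dead_48h,total``
    with one row per well (three treatment and six control wells per
    strain in the standard plate layout).
    """
    cells_df = pd.read_csv(path_cells, comment="#")
    assay_df = pd.read_csv(path_assay, comment="#")
    for df, cols, p in (
        (cells_df, ["strain_id", "n_cells", "sample_volume_ul"], path_cells),
        (
            assay_df,
            ["strain_id", "well_type", "initial_dead", "dead_24h", "dead_48h", "total"],
            path_assay,
        ),
    ):
        missing = set(cols) - set(df.columns)
        if missing:
            raise ValidationError(f"{p}: missing columns {sorted(missing)}")
    cell_counts = {
        str(r["strain_id"]): (int(r["n_cells"]), float(r["sample_volume_ul"]))
        for _, r in cells_df.iterrows()
    }
    assay_counts: dict[str, list[WellCount]] = {}
    for idx, r in assay_df.iterrows():
        try:
            well = WellCount(
                well_type=str(r["well_type"]),
                initial_dead=int(r["initial_dead"]),
                dead_24h=int(r["dead_24h"]),
                dead_48h=int(r["dead_48h"]),
                total=int(r["total"]),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path_assay}: row {idx + 2}: {exc}") from exc
        assay_counts.setdefault(str(r["strain_id"]), []).append(well)
    return CountTables(cell_counts=cell_counts, assay_counts=assay_counts)


def write_count_tables(
    counts: CountTables, path_cells: str | Path, path_assay: str | Path
) -> None:
    pd.DataFrame(
        [
            {"strain_id": s, "n_cells": n, "sample_volume_ul": v}
            for s, (n, v) in counts.cell_counts.items()
        ]
    ).to_csv(path_cells, index=False)
    rows = []
    for s, wells in counts.assay_counts.items():
        for w in wells:
            rows.append(
                {
                    "strain_id": s,
                    "well_type": w.well_type,
                    "initial_dead": w.initial_dead,
                    "dead_24h": w.dead_24h,
                    "dead_48h": w.dead_48h,
                    "total": w.total,
                }
            )
    pd.DataFrame(rows).to_csv(path_assay, index=False)
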