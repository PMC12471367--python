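"""Semi-quantification of amphidinols as luteophanol-D equivalents.

No certified standards exist for most AM variants, so detected AMs are
calibrated against a single external luteophanol-D (LPD) standard and
reported as LPD equivalents — explicitly semi-quantitative. The three
reductions are:

* concentration (ng/uL) = peak_area_toxin x c(LPD) / peak_area(LPD)
* cell quota (fg/cell)  = concentration x sample_volume_uL x 1e6 / n_cells
* LoD (fg/cell)         = c(LPD) x 3/(S/N of LPD) x sample_volume_uL
                          x 1e6 / n_cells

The default standard concentration is 12.5 ng/uL (10 ug of LPD in
800 uL methanol); per-strain totals exclude below-LoD variants by
default (configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .spectra_io import CountTables, PeakAreaRecord, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "LpdStandard",
    "QuantRecord",
    "concentration",
    "cell_quota",
    "lod",
    "quantify_panel",
]

NG_TO_FG = 1_000_000.0


@dataclass(frozen=True)
class LpdStandard:
    """External luteophanol-D calibration standard."""

    conc_ng_per_ul: float = 12.5
    peak_area: float = 1.0
    snr: float = 30.0

    def __post_init__(self) -> None:
        if self.conc_ng_per_ul <= 0:
            raise ValidationError("standard concentration must be > 0")
        if self.peak_area <= 0:
            raise ValidationError("standard peak area must be > 0")


@dataclass(frozen=True)
class QuantRecord:
    """LPD-equivalent quantification of one (strain, variant) pair."""

    strain_id: str
    variant_name: str
    conc_ng_per_ul: float
    cell_quota_fg_per_cell: float
    lod_fg_per_cell: float
    below_lod: bool


def concentration(peak_area_toxin: float, std: LpdStandard) -> float:
    """Toxin concentration (ng/uL, LPD equivalents) from its peak area."""
    if peak_area_toxin < 0:
        raise ValidationError("peak area must be >= 0")
    return peak_area_toxin * std.conc_ng_per_ul / std.peak_area


def cell_quota(conc_ng_per_ul: float, sample_volume_ul: float, n_cells: float) -> float:
    """Toxin cell quota (fg/cell) from concentration, volume and cell count."""
    if n_cells <= 0:
        raise ValidationError("n_cells must be > 0")
    return conc_ng_per_ul * sample_volume_ul * NG_TO_FG / n_cells


def lod(std: LpdStandard, sample_volume_ul: float, n_cells: float) -> float:
    """Limit of detection (fg/cell) from the LPD standard's S/N.

    Defined as the concentration at which the toxin would reach S/N = 3,
    scaled to a cell quota for the given sample.
    """
    if std.snr <= 0:
        raise ValidationError("standard S/N must be > 0")
    if n_cells <= 0:
        raise ValidationError("n_cells must be > 0")
    return std.conc_ng_per_ul * (3.0 / std.snr) * sample_volume_ul * NG_TO_FG / n_cells


def quantify_panel(
    areas: Sequence[PeakAreaRecord],
    std: LpdStandard,
    counts: CountTables,
    include_below_lod_in_total: bool = False,
) -> tuple[list[QuantRecord], dict[str, float]]:
    """Quantify a panel of peak areas into per-variant cell quotas.

    Returns ``(records, totals)`` where ``totals`` maps strain_id to the
    summed cell quota of its variants; below-LoD variants are flagged
    and excluded from the total unless ``include_below_lod_in_total``.
    Strains absent from the cell-count table are skipped with a warning.
    Strains with cell counts but no detected variants get a total of 0
    (reported as not detected).
    """
    records: list[QuantRecord] = []
    totals: dict[str, float] = {s: 0.0 for s in counts.cell_counts}
    for rec in areas:
        if rec.strain_id not in counts.cell_counts:
            logger.warning(
                "strain %s has peak areas but no cell counts; skipped", rec.strain_id
            )
            continue
        n_cells, volume = counts.cell_counts[rec.strain_id]
        conc = concentration(rec.peak_area, std)
        quota = cell_quota(conc, volume, n_cells)
        limit = lod(std, volume, n_cells)
        below = quota < limit
        records.append(
            QuantRecord(
                strain_id=rec.strain_id,
                variant_name=rec.variant_name,
                conc_ng_per_ul=conc,
                cell_quota_fg_per_cell=quota,
                lod_fg_per_cell=limit,
                below_lod=below,
            )
        )
        if not below or include_below_lod_in_total:
            totals[rec.strain_id] += quota
    return records, totals
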