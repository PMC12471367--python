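"""Brine-shrimp (Artemia salina) assay reduction.

Each strain's crude methanol extract is tested in three treatment wells
of a 24-well plate (~60 nauplii per well) alongside six control wells
(three DMSO, three seawater). Dead counts at 24 h and 48 h are adjusted
by subtracting the initial (inoculation) mortality and the mean control
mortality, and the mortality rate is

    rate (per day) = ln(adjusted dead at 48 h) / 48 h x 24 h

i.e. the log of a count, not of a proportion — the published rate range
(up to ~2 per day for 60-individual wells) matches this form. A
proportion-based alternative (``mode="hazard"``) is available but never
the default. Adjusted counts of 0 or 1 map to a rate of 0 (the log is
undefined or zero).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .spectra_io import CountTables, ValidationError, WellCount

logger = logging.getLogger(__name__)

__all__ = ["ToxicityRecord", "adjust_deaths", "mortality_rate", "assay_reduce"]

ASSAY_HOURS = 48.0


@dataclass(frozen=True)
class ToxicityRecord:
    """Control-adjusted assay outcome for one strain."""

    strain_id: str
    adjusted_dead_24h: float
    adjusted_dead_48h: float
    mortality_rate_per_day: float
    per_well_rates: tuple[float, ...] = ()


def adjust_deaths(
    treatment_dead: float, initial_dead: float, control_dead_mean: float
) -> float:
    """Control-adjusted death count, floored at zero."""
    if treatment_dead < 0 or initial_dead < 0 or control_dead_mean < 0:
        raise ValidationError("counts must be >= 0")
    return max(0.0, treatment_dead - initial_dead - control_dead_mean)


def mortality_rate(dead_48h: float, mode: str = "count") -> float:
    """Mortality rate (per day) from the adjusted 48 h death count.

    ``count`` mode (default): ln(dead)/48 x 24 for dead >= 1, else 0.
    ``hazard`` mode: -ln(1 - dead/60)/2, a proportion-based alternative
    assuming ~60 individuals per well.
    """
    if dead_48h < 0:
        raise ValidationError("death count must be >= 0")
    if mode == "hazard":
        frac = min(dead_48h / 60.0, 1.0 - 1e-9)
        return -math.log(1.0 - frac) / (ASSAY_HOURS / 24.0)
    if mode != "count":
        raise ValidationError(f"unknown mortality-rate mode {mode!r}")
    if dead_48h == 0:
        logger.warning("zero adjusted deaths at 48 h; rate set to 0")
        return 0.0
    if dead_48h < 1.0:
        return 0.0
    return math.log(dead_48h) / ASSAY_HOURS * 24.0


def _control_mean(wells: list[WellCount], attr: str) -> float:
    controls = [w for w in wells if w.well_type != "treatment"]
    if not controls:
        return 0.0
    # DMSO and seawater controls are pooled (six wells in the standard layout).
    return sum(getattr(w, attr) for w in controls) / len(controls)


def assay_reduce(counts: CountTables, mode: str = "count") -> list[ToxicityRecord]:
    """Reduce per-well assay counts to one toxicity record per strain.

    Per strain the three treatment wells are adjusted (initial mortality
    and pooled control mean subtracted, floored at zero) and averaged;
    the rate is computed from the mean adjusted 48 h deaths. Per-well
    rates are also emitted for dispersion reporting. Strains with no
    treatment wells are skipped with a warning.
    """
    records: list[ToxicityRecord] = []
    for strain, wells in counts.assay_counts.items():
        treatment = [w for w in wells if w.well_type == "treatment"]
        if not treatment:
            logger.warning("strain %s has no treatment wells; skipped", strain)
            continue
        c24 = _control_mean(wells, "dead_24h")
        c48 = _control_mean(wells, "dead_48h")
        adj24 = [adjust_deaths(w.dead_24h, w.initial_dead, c24) for w in treatment]
        adj48 = [adjust_deaths(w.dead_48h, w.initial_dead, c48) for w in treatment]
        mean24 = sum(adj24) / len(adj24)
        mean48 = sum(adj48) / len(adj48)
        records.append(
            ToxicityRecord(
                strain_id=strain,
                adjusted_dead_24h=mean24,
                adjusted_dead_48h=mean48,
                mortality_rate_per_day=mortality_rate(mean48, mode=mode),
                per_well_rates=tuple(mortality_rate(a, mode=mode) for a in adj48),
            )
        )
    return records
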