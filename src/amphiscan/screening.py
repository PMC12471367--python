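"""Three-mode search strategy for amphidinol candidates.

The discovery workflow combines three triple-quadrupole operation modes:

* **SRM** — targeted detection of known variants via (Q1, Q3) transition
  pairs at their expected retention time;
* **NL** — neutral-loss screening for the characteristic lipophilic-arm
  fragments released by the preferred C1/C1' cleavage (fourteen channels:
  seven non-sulfated losses and their seven sulfated counterparts);
* **FS** — untargeted full scan over the typical AM mass range
  (m/z 1000-1800) within the retention-time window of the known AMs
  (2.0-4.2 min), as a safety net for variants forming none of the known
  neutral losses.

A signal-to-noise ratio of three is the minimum threshold for retained
peaks throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .spectra_io import PeakAreaRecord, Spectrum, TransitionTable, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "NLChannel",
    "ScreenHit",
    "SrmPeak",
    "build_nl_library",
    "nl_screen",
    "fs_screen",
    "srm_detect",
    "estimate_snr",
    "fragment_snr",
    "DEFAULT_NL_LOSSES",
    "PLACEHOLDER_NL_LOSSES",
]

# Lipophilic-arm neutral losses printed in the variant descriptions.
DEFAULT_NL_LOSSES = (392.0, 398.0, 426.0)
# The remaining four non-sulfated channels of the fourteen-channel method
# are instrument-method metadata not recoverable from the published text;
# these placeholders keep the default library at full cardinality and are
# expected to be replaced by the user's method values.
PLACEHOLDER_NL_LOSSES = (380.0, 410.0, 440.0, 454.0)
# Mass added to a loss for its sulfated counterpart: the neutral fragment
# retains NaHSO4 (120 Da) when the sulfate sits on the lipophilic arm.
SULFATE_SHIFT = 120.0


@dataclass(frozen=True)
class NLChannel:
    """One neutral-loss scan channel."""

    loss_da: float
    sulfated: bool
    label: str
    provenance: str = "main_text"  # main_text | derived | placeholder | user

    def __post_init__(self) -> None:
        if not self.loss_da > 0:
            raise ValidationError(f"channel {self.label}: loss_da must be > 0")


@dataclass(frozen=True)
class ScreenHit:
    """A retained candidate precursor from any of the three search modes."""

    spectrum_id: str
    q1_mz: float
    channel_label: str  # NL channel label, transition name, or "full-scan"
    rt_min: float
    snr: float
    mode: str  # "nl" | "fs" | "srm"


@dataclass(frozen=True)
class SrmPeak:
    """A chromatographic peak observed in SRM mode."""

    strain_id: str
    q1_mz: float
    q3_mz: float
    rt_min: float
    peak_area: float
    snr: float = math.inf


def build_nl_library(config: Mapping | str = "default") -> list[NLChannel]:
    """Build the neutral-loss channel library.

    With ``config="default"`` the library has exactly 14 channels: the
    seven non-sulfated arm losses (three published, four placeholders)
    plus their seven sulfated counterparts. A mapping with key
    ``non_sulfated`` (list of losses in Da) builds a custom library;
    optional key ``sulfated`` overrides the derived counterparts.
    Duplicate masses within a sulfation class are a config error.
    """
    if config == "default":
        non_sulf = list(DEFAULT_NL_LOSSES) + list(PLACEHOLDER_NL_LOSSES)
        sulf = [m + SULFATE_SHIFT for m in non_sulf]
        provenance = {m: "main_text" for m in DEFAULT_NL_LOSSES}
        provenance.update({m: "placeholder" for m in PLACEHOLDER_NL_LOSSES})
        sulf_prov = {m + SULFATE_SHIFT: "derived" for m in non_sulf}
    elif isinstance(config, Mapping):
        non_sulf = [float(m) for m in config["non_sulfated"]]
        sulf = [float(m) for m in config.get("sulfated", [])]
        provenance = {m: "user" for m in non_sulf}
        sulf_prov = {m: "user" for m in sulf}
    else:
        raise ValidationError(f"unrecognized NL config {config!r}")

    for cls_name, masses in (("non-sulfated", non_sulf), ("sulfated", sulf)):
        seen = set()
        for m in masses:
            if m in seen:
                raise ValidationError(
                    f"duplicate {cls_name} neutral-loss mass {m} in NL config"
                )
            seen.add(m)

    channels = [
        NLChannel(m, False, f"arm-{m:g}", provenance[m]) for m in non_sulf
    ] + [NLChannel(m, True, f"arm-{m:g}-sulf", sulf_prov[m]) for m in sulf]
    return channels


def estimate_snr(
    trace: Sequence[float], peak_index_range: tuple[int, int]
) -> float:
    """Robust signal-to-noise ratio of a peak within an intensity trace.

    ``peak_index_range`` is a half-open ``(start, stop)`` index range
    covering the peak. S/N = (peak max - baseline median) / noise with
    noise = 1.4826 x median absolute deviation of the off-peak samples
    (the Gaussian-consistent MAD scale). If the noise is exactly zero
    the result is 0 for a flat trace and +inf when the peak rises above
    the baseline (treated as passing any threshold).
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 8:
        raise ValidationError(f"trace too short for S/N estimation ({trace.size} < 8)")
    start, stop = peak_index_range
    if not (0 <= start < stop <= trace.size):
        raise ValidationError(f"peak index range {peak_index_range} outside trace")
    mask = np.zeros(trace.size, dtype=bool)
    mask[start:stop] = True
    off = trace[~mask]
    if off.size == 0:
        raise ValidationError("peak range covers the whole trace")
    baseline = float(np.median(off))
    noise = 1.4826 * float(np.median(np.abs(off - baseline)))
    signal = float(trace[mask].max()) - baseline
    if noise == 0.0:
        return math.inf if signal > 0 else 0.0
    return signal / noise


def fragment_snr(spectrum: Spectrum, fragment_index: int) -> float:
    """S/N of one fragment against the rest of the peak list.

    Peak lists are not continuous traces, so the noise floor is taken
    from the low-intensity half of the other fragments (the population
    dominated by noise peaks rather than structural ions): baseline =
    its median, noise = 1.4826 x its MAD. Sparse spectra (fewer than 8
    fragments) carry no measurable noise floor, so no fragment can be
    rejected: the sentinel +inf is returned for any nonzero fragment.
    """
    intens = spectrum.intensity_array
    others = np.delete(intens, fragment_index)
    value = float(intens[fragment_index])
    if intens.size < 8:
        return math.inf if value > 0 else 0.0
    floor_pop = others[others <= np.median(others)]
    baseline = float(np.median(floor_pop))
    noise = 1.4826 * float(np.median(np.abs(floor_pop - baseline)))
    if noise == 0.0:
        return math.inf if value > baseline else 0.0
    return (value - baseline) / noise


def nl_screen(
    spectrum: Spectrum,
    channels: Sequence[NLChannel],
    mz_tol: float = 0.5,
    snr_min: float = 3.0,
) -> list[ScreenHit]:
    """Neutral-loss screen of one spectrum against a channel library.

    A hit on channel L is emitted when some fragment f satisfies
    ``|precursor_mz - L - f.mz| <= mz_tol`` and its S/N passes
    ``snr_min``. The hit carries the precursor as Q1 mass.
    """
    if mz_tol <= 0:
        raise ValidationError("mz_tol must be > 0")
    hits: list[ScreenHit] = []
    for ch in channels:
        target = spectrum.precursor_mz - ch.loss_da
        best = None
        for idx, (mz, _inten) in enumerate(spectrum.fragments):
            if abs(mz - target) <= mz_tol:
                snr = fragment_snr(spectrum, idx)
                if snr >= snr_min and (best is None or snr > best):
                    best = snr
        if best is not None:
            hits.append(
                ScreenHit(
                    spectrum_id=spectrum.spectrum_id,
                    q1_mz=spectrum.precursor_mz,
                    channel_label=ch.label,
                    rt_min=spectrum.rt_min,
                    snr=best,
                    mode="nl",
                )
            )
    return hits


def fs_screen(
    spectra: Sequence[Spectrum],
    rt_window: tuple[float, float] = (2.0, 4.2),
    mz_range: tuple[float, float] = (1000.0, 1800.0),
    snr_min: float = 3.0,
    exclude_hits: Sequence[ScreenHit] = (),
    mz_tol: float = 0.5,
    rt_tol: float = 0.1,
    boundary_margin: float = 0.25,
) -> list[ScreenHit]:
    """Full-scan candidate selection.

    Returns precursors inside both the retention-time window and the
    mass range with base-peak S/N >= ``snr_min``, excluding Q1 masses
    already found by NL or SRM (dedup within ``mz_tol`` and ``rt_tol``).
    Windows are inclusive; precursors falling just outside the RT window
    (within ``boundary_margin`` minutes) are logged, since printed AM
    retention times can sit on or past the nominal window edge.
    """
    if rt_window[0] >= rt_window[1] or mz_range[0] >= mz_range[1]:
        raise ValidationError("inverted rt_window or mz_range")
    hits: list[ScreenHit] = []
    for s in spectra:
        if not (mz_range[0] <= s.precursor_mz <= mz_range[1]):
            continue
        if not (rt_window[0] <= s.rt_min <= rt_window[1]):
            if (
                rt_window[0] - boundary_margin
                <= s.rt_min
                <= rt_window[1] + boundary_margin
            ):
                logger.warning(
                    "%s (m/z %.1f): RT %.2f min just outside FS window %s; "
                    "excluded but flagged for manual review",
                    s.spectrum_id,
                    s.precursor_mz,
                    s.rt_min,
                    rt_window,
                )
            continue
        already = any(
            abs(h.q1_mz - s.precursor_mz) <= mz_tol and abs(h.rt_min - s.rt_min) <= rt_tol
            for h in exclude_hits
        )
        if already:
            continue
        if not s.fragments:
            continue
        base_idx = int(np.argmax(s.intensity_array))
        snr = fragment_snr(s, base_idx)
        if snr >= snr_min:
            hits.append(
                ScreenHit(
                    spectrum_id=s.spectrum_id,
                    q1_mz=s.precursor_mz,
                    channel_label="full-scan",
                    rt_min=s.rt_min,
                    snr=snr,
                    mode="fs",
                )
            )
    return hits


def srm_detect(
    peaks: Sequence[SrmPeak],
    table: TransitionTable,
    mz_tol: float = 0.5,
    rt_tol: float = 0.1,
    snr_min: float = 3.0,
) -> list[ScreenHit]:
    """Targeted SRM hit detection against a transition library.

    A hit requires both Q1 and Q3 to match a transition within
    ``mz_tol`` and the retention time within ``rt_tol``.
    """
    if len(table) == 0:
        raise ValidationError("transition table is empty")
    hits: list[ScreenHit] = []
    for p in peaks:
        for entry in table:
            if (
                abs(p.q1_mz - entry.q1_mz) <= mz_tol
                and abs(p.q3_mz - entry.q3_mz) <= mz_tol
                and abs(p.rt_min - entry.rt_min) <= rt_tol
                and p.snr >= snr_min
            ):
                hits.append(
                    ScreenHit(
                        spectrum_id=p.strain_id,
                        q1_mz=p.q1_mz,
                        channel_label=entry.variant_name,
                        rt_min=p.rt_min,
                        snr=p.snr,
                        mode="srm",
                    )
                )
    return hits
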