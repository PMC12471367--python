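"""Rule-based interpretation of amphidinol CID spectra.

Sodium adducts of amphidinols fragment sparsely, but the few fragments
they do produce are highly diagnostic:

* **Sulfation** — a 120 Da neutral loss (NaHSO4) from the precursor
  distinguishes sulfated from non-sulfated variants.
* **C1/C1' cleavage** — the weakest bond in every known AM sits between
  two vicinal hydroxyl groups in the conserved central region. Cleavage
  releases the lipophilic arm (C1'-Cn') as a neutral of characteristic
  mass (392, 398 or 426 Da among the published arms) and leaves the
  charged hydrophilic-arm fragment (C1-Cn). The arm mass identifies the
  arm type shared between analogs (392: lingshuiol-A; 398: AM-B).
* **Di-gamma-hydroxy-carbonyl signature** — a 29,33-di-hydroxy-
  31-carbonyl motif cleaves on either side of the carbonyl through a
  six-membered transition state, yielding fragment pairs separated by
  exactly 58 Da.
* **Terminus loss** — a 218 Da neutral loss from the pseudo-molecular
  ion (or 200 Da from the desulfated ion of a sulfated variant) marks a
  conserved hydrophilic-arm terminus; the 218 -> 200 shift is the
  signature of a sulfated counterpart of a 218-type variant.

``annotate`` composes the detectors into a per-spectrum structural call
(known variant / novel AM candidate / non-AM). Unit-resolution masses
are matched with an absolute tolerance (default 0.5 Da).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .spectra_io import Spectrum, TransitionTable

logger = logging.getLogger(__name__)

__all__ = [
    "SULFATE_LOSS",
    "TERMINUS_LOSS_PRECURSOR",
    "TERMINUS_LOSS_DESULFATED",
    "CARBONYL_PAIR_DELTA",
    "DEFAULT_ARM_LIBRARY",
    "ARM_ANALOGY",
    "SulfationResult",
    "AnnotationRecord",
    "detect_sulfation",
    "assign_arm",
    "detect_carbonyl_pairs",
    "detect_terminus_loss",
    "classify_hydrophilic_type",
    "match_known",
    "annotate",
]

SULFATE_LOSS = 120.0  # NaHSO4 eliminated from the sodium-adduct precursor
TERMINUS_LOSS_PRECURSOR = 218.0  # hydrophilic-terminus loss from [M+Na]+
TERMINUS_LOSS_DESULFATED = 200.0  # same loss measured from [M+Na-120]+
CARBONYL_PAIR_DELTA = 58.0  # di-gamma-hydroxy-carbonyl pair spacing
DEFAULT_ARM_LIBRARY = (392.0, 398.0, 426.0)

# Known analogs sharing each published lipophilic arm.
ARM_ANALOGY = {
    392.0: "same lipophilic arm as LS-A",
    398.0: "same lipophilic arm as AM-B",
    426.0: "same lipophilic arm as ARC-3/ARC-7",
}


@dataclass(frozen=True)
class SulfationResult:
    sulfated: bool
    desulfated_mz: Optional[float] = None


@dataclass
class AnnotationRecord:
    """Per-spectrum structural call produced by :func:`annotate`."""

    spectrum_id: str
    precursor_mz: float
    sulfated: bool = False
    desulfated_mz: Optional[float] = None
    arm_mass: Optional[float] = None
    cleavage_fragment_mz: Optional[float] = None
    carbonyl_pairs: list[tuple[float, float]] = field(default_factory=list)
    terminus_loss: Optional[float] = None  # 218.0, 200.0 or None
    hydrophilic_type: frozenset[str] = frozenset()
    verdict: str = "non-AM"  # "known:<variant>" | "novel" | "non-AM"
    evidence: list[str] = field(default_factory=list)


def _find_fragment(
    s: Spectrum, target_mz: float, mz_tol: float
) -> Optional[tuple[float, float]]:
    """Closest fragment to ``target_mz`` within tolerance, or None.

    Ties on |delta| are broken by larger intensity, then smaller m/z,
    making downstream assignments deterministic.
    """
    candidates = [
        (abs(mz - target_mz), -inten, mz, inten)
        for mz, inten in s.fragments
        if abs(mz - target_mz) <= mz_tol
    ]
    if not candidates:
        return None
    _, _, mz, inten = min(candidates)
    return (mz, inten)


def detect_sulfation(s: Spectrum, mz_tol: float = 0.5) -> SulfationResult:
    """Detect the 120 Da NaHSO4 loss marking a sulfated variant.

    Returns ``(sulfated, desulfated_mz)`` where ``desulfated_mz`` is
    the observed m/z of the [M+Na-120]+ fragment.
    """
    hit = _find_fragment(s, s.precursor_mz - SULFATE_LOSS, mz_tol)
    if hit is None:
        return SulfationResult(False, None)
    return SulfationResult(True, hit[0])


def assign_arm(
    s: Spectrum,
    sulfation: SulfationResult,
    arm_library: Sequence[float] = DEFAULT_ARM_LIBRARY,
    mz_tol: float = 0.5,
) -> Optional[tuple[float, float]]:
    """Assign the lipophilic-arm neutral loss and the C1/C1' fragment.

    Searches for a fragment at ``base - arm`` for every arm mass in the
    library, where ``base`` is the desulfated ion for sulfated variants
    and the precursor otherwise. Ties are broken by smallest mass error,
    then largest fragment intensity, then smallest arm mass. Returns
    ``(arm_mass, cleavage_fragment_mz)`` or None.
    """
    if not arm_library:
        raise ValueError("arm_library must be non-empty")
    base = (
        sulfation.desulfated_mz
        if sulfation.sulfated and sulfation.desulfated_mz is not None
        else s.precursor_mz
    )
    candidates = []
    for arm in arm_library:
        hit = _find_fragment(s, base - arm, mz_tol)
        if hit is not None:
            mz, inten = hit
            candidates.append((abs(base - arm - mz), -inten, arm, mz))
    if not candidates:
        return None
    _, _, arm, mz = min(candidates)
    return (float(arm), float(mz))


def detect_carbonyl_pairs(
    fragments: Sequence[tuple[float, float]],
    mz_tol: float = 0.5,
    precursor_mz: Optional[float] = None,
) -> list[tuple[float, float]]:
    """Find all fragment pairs separated by the 58 Da carbonyl spacing.

    Returns ``(hi_mz, lo_mz)`` pairs sorted descending by the high-mass
    member. The precursor ion itself, when present in the peak list, is
    excluded from pairing.
    """
    mzs = [mz for mz, _ in fragments]
    if precursor_mz is not None:
        mzs = [m for m in mzs if abs(m - precursor_mz) > mz_tol]
    pairs = [
        (hi, lo)
        for i, hi in enumerate(mzs)
        for lo in mzs[:i] + mzs[i + 1 :]
        if 0 < hi - lo and abs(hi - lo - CARBONYL_PAIR_DELTA) <= mz_tol
    ]
    return sorted(set(pairs), key=lambda p: -p[0])


def detect_terminus_loss(
    s: Spectrum, sulfation: SulfationResult, mz_tol: float = 0.5
) -> Optional[float]:
    """Detect the conserved hydrophilic-terminus neutral loss.

    218 if a fragment sits at ``precursor - 218``; 200 if the variant is
    sulfated and a fragment sits at ``desulfated - 200``. When both
    match, 218 takes precedence. Returns 218.0, 200.0 or None.
    """
    if _find_fragment(s, s.precursor_mz - TERMINUS_LOSS_PRECURSOR, mz_tol):
        return TERMINUS_LOSS_PRECURSOR
    if sulfation.sulfated and sulfation.desulfated_mz is not None:
        if _find_fragment(
            s, sulfation.desulfated_mz - TERMINUS_LOSS_DESULFATED, mz_tol
        ):
            return TERMINUS_LOSS_DESULFATED
    return None


def classify_hydrophilic_type(
    s: Spectrum,
    cleavage_fragment_mz: Optional[float],
    carbonyl_pairs: Sequence[tuple[float, float]] = (),
    terminus_loss: Optional[float] = None,
) -> frozenset[str]:
    """Label the hydrophilic-arm type from the fragmentation evidence.

    ``LP-D-type`` when the C1/C1' cleavage fragment is the base peak of
    the spectrum (luteophanol-D-like hydrophilic arm); ``AM-18-type``
    when at least one 58 Da carbonyl pair co-occurs with a terminus
    loss. The labels can co-occur.
    """
    labels = set()
    if cleavage_fragment_mz is not None and s.fragments:
        if cleavage_fragment_mz == s.base_peak_mz():
            labels.add("LP-D-type")
    if carbonyl_pairs and terminus_loss in (
        TERMINUS_LOSS_PRECURSOR,
        TERMINUS_LOSS_DESULFATED,
    ):
        labels.add("AM-18-type")
    return frozenset(labels)


def match_known(
    s: Spectrum,
    table: TransitionTable,
    mz_tol: float = 0.5,
    rt_tol: float = 0.1,
) -> Optional[str]:
    """Match a spectrum against the known-variant transition library.

    A match requires |Q1 - precursor| <= mz_tol, |RT difference| <=
    rt_tol and a fragment at Q3 +- mz_tol. Multiple matches resolve to
    the closest Q1, then closest RT; the ambiguity is logged.
    """
    matches = []
    for entry in table:
        if (
            abs(entry.q1_mz - s.precursor_mz) <= mz_tol
            and abs(entry.rt_min - s.rt_min) <= rt_tol
            and _find_fragment(s, entry.q3_mz, mz_tol) is not None
        ):
            matches.append(
                (
                    abs(entry.q1_mz - s.precursor_mz),
                    abs(entry.rt_min - s.rt_min),
                    entry.variant_name,
                )
            )
    if not matches:
        return None
    if len(matches) > 1:
        logger.info(
            "%s: ambiguous known-variant match (%s); choosing closest",
            s.spectrum_id,
            [m[2] for m in sorted(matches)],
        )
    return min(matches)[2]


def annotate(
    s: Spectrum,
    arm_library: Sequence[float] = DEFAULT_ARM_LIBRARY,
    transition_table: Optional[TransitionTable] = None,
    mz_tol: float = 0.5,
    rt_tol: float = 0.1,
) -> AnnotationRecord:
    """Full structural call for one CID spectrum.

    Composes the four detectors and classifies the spectrum as a known
    variant (transition-library match), a novel AM candidate (no known
    match but positive structural evidence: an assigned arm, or carbonyl
    pairs together with a terminus loss), or non-AM. The ``evidence``
    list records every fired rule.
    """
    rec = AnnotationRecord(spectrum_id=s.spectrum_id, precursor_mz=s.precursor_mz)

    sulf = detect_sulfation(s, mz_tol)
    rec.sulfated = sulf.sulfated
    rec.desulfated_mz = sulf.desulfated_mz
    if sulf.sulfated:
        rec.evidence.append(
            f"sulfation: 120 Da loss to m/z {sulf.desulfated_mz:g}"
        )

    arm = assign_arm(s, sulf, arm_library, mz_tol)
    if arm is not None:
        rec.arm_mass, rec.cleavage_fragment_mz = arm
        tag = ARM_ANALOGY.get(rec.arm_mass, "lipophilic arm")
        rec.evidence.append(
            f"C1/C1' cleavage: {rec.arm_mass:g} Da arm loss to m/z "
            f"{rec.cleavage_fragment_mz:g} ({tag})"
        )

    rec.carbonyl_pairs = detect_carbonyl_pairs(
        s.fragments, mz_tol, precursor_mz=s.precursor_mz
    )
    if rec.carbonyl_pairs:
        rec.evidence.append(
            f"di-gamma-hydroxy-carbonyl: {len(rec.carbonyl_pairs)} x 58 Da pair(s)"
        )

    rec.terminus_loss = detect_terminus_loss(s, sulf, mz_tol)
    if rec.terminus_loss == TERMINUS_LOSS_PRECURSOR:
        rec.evidence.append("terminus: 218 Da loss from precursor")
    elif rec.terminus_loss == TERMINUS_LOSS_DESULFATED:
        rec.evidence.append(
            "terminus: 200 Da loss from desulfated ion "
            "(sulfated variant of the 218-type; AM-18/AM-19 analogy)"
        )

    rec.hydrophilic_type = classify_hydrophilic_type(
        s, rec.cleavage_fragment_mz, rec.carbonyl_pairs, rec.terminus_loss
    )

    known = None
    if transition_table is not None and len(transition_table) > 0:
        known = match_known(s, transition_table, mz_tol, rt_tol)
    if known is not None:
        rec.verdict = f"known:{known}"
    elif rec.arm_mass is not None or (
        rec.carbonyl_pairs and rec.terminus_loss is not None
    ):
        rec.verdict = "novel"
    else:
        rec.verdict = "non-AM"
    return rec
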