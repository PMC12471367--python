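"""Synthetic instrument output for the amphidinol pipeline.

No raw data accompany the study conditions this package reproduces, so
every pipeline input can be generated here: CID spectra built from the
diagnostic fragmentation grammar, SRM peak areas proportional to
planted cell quotas, cell counts, binomially sampled brine-shrimp well
counts, and whole strain panels with planted cluster structure. A truth
manifest accompanies every panel so that downstream estimates can be
checked against the planted values.

Fragmentation grammar (all masses are sodium-adduct m/z):

* precursor ion at low intensity;
* sulfated variants: fragment at ``precursor - 120`` (NaHSO4 loss);
* C1/C1' cleavage fragment at ``base - arm`` where ``base`` is the
  desulfated ion for sulfated variants, the precursor otherwise;
* terminus fragment at ``precursor - 218`` or, for sulfated variants
  of the 218-type, ``desulfated - 200``;
* di-gamma-hydroxy-carbonyl variants: a high-mass 58 Da pair anchored
  at the terminus fragment (``anchor`` and ``anchor - 58``) and a
  low-mass pair shifted down by the arm mass (``anchor - arm`` and
  ``anchor - arm - 58``) — the canonical layout that reproduces the
  ARC-7 series 1288/1230 and 862/804 from precursor 1506;
* optional uniform decoy peaks kept >= 2 Da away from every
  rule-consistent position, so decoys can never satisfy a rule at the
  0.5 Da matching tolerance.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .spectra_io import (
    CountTables,
    PeakAreaRecord,
    Spectrum,
    TransitionEntry,
    TransitionTable,
    WellCount,
)

__all__ = [
    "VariantSpec",
    "PanelConfig",
    "Panel",
    "ARC_VARIANT_SPECS",
    "make_spectrum",
    "make_fixture_table1",
    "known_am_table",
    "make_panel",
    "random_variant_spec",
]

SULFATE_LOSS = 120.0
PAIR_DELTA = 58.0
TERMINUS_PRECURSOR = 218.0
TERMINUS_DESULFATED = 200.0
# structural offset anchoring carbonyl pairs when no terminus loss is
# emitted; chosen clear (>2 Da) of every rule-consistent position
NO_TERMINUS_ANCHOR_OFFSET = 170.0
DECOY_EXCLUSION_DA = 2.0
MIN_FRAGMENT_MZ = 100.0


@dataclass(frozen=True)
class VariantSpec:
    """Generative description of one AM variant's CID behaviour."""

    name: str
    precursor_mz: float
    sulfated: bool
    arm_mass: float
    has_carbonyl: bool = False
    terminus: Optional[float] = None  # 218.0, 200.0 or None
    rt_min: float = 3.0
    base_peak: str = "cleavage"  # which fragment is most intense
    extra_fragments: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.terminus == TERMINUS_DESULFATED and not self.sulfated:
            raise ValueError(
                f"{self.name}: a 200 Da terminus loss implies a sulfated variant"
            )
        if self.terminus not in (None, TERMINUS_PRECURSOR, TERMINUS_DESULFATED):
            raise ValueError(f"{self.name}: terminus must be 218, 200 or None")
        if self.base_peak not in ("cleavage", "precursor", "desulfated", "terminus"):
            raise ValueError(f"{self.name}: unknown base_peak {self.base_peak!r}")


def _grammar_positions(spec: VariantSpec) -> dict[str, float]:
    """Rule-implied fragment m/z values for a variant spec."""
    pos: dict[str, float] = {}
    base = spec.precursor_mz
    if spec.sulfated:
        pos["desulfated"] = spec.precursor_mz - SULFATE_LOSS
        base = pos["desulfated"]
    pos["cleavage"] = base - spec.arm_mass
    if spec.terminus == TERMINUS_PRECURSOR:
        pos["terminus"] = spec.precursor_mz - TERMINUS_PRECURSOR
    elif spec.terminus == TERMINUS_DESULFATED:
        pos["terminus"] = pos["desulfated"] - TERMINUS_DESULFATED
    if spec.has_carbonyl:
        anchor = pos.get("terminus", base - NO_TERMINUS_ANCHOR_OFFSET)
        pos["pair_hi_a"] = anchor
        pos["pair_hi_b"] = anchor - PAIR_DELTA
        pos["pair_lo_a"] = anchor - spec.arm_mass
        pos["pair_lo_b"] = anchor - spec.arm_mass - PAIR_DELTA
    return pos


def make_spectrum(
    spec: VariantSpec,
    n_decoys: int = 0,
    seed: int | np.random.Generator = 0,
    strain_id: str = "",
) -> Spectrum:
    """Build one CID spectrum from a variant spec.

    Emits exactly the rule-implied fragments plus the low-intensity
    precursor ion and ``n_decoys`` uniform decoy peaks placed at least
    2 Da from any rule-consistent position (including 58 Da offsets from
    real fragments and other decoys, so decoys never create spurious
    carbonyl pairs). Raises if any implied fragment falls below m/z 100.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = _grammar_positions(spec)
    low = min(pos.values())
    if low < MIN_FRAGMENT_MZ:
        raise ValueError(
            f"{spec.name}: implied fragment at m/z {low:.1f} below {MIN_FRAGMENT_MZ}"
        )

    intensities: dict[str, float] = {}
    for key, mz in pos.items():
        intensities[key] = float(rng.uniform(300.0, 800.0))
    if spec.base_peak == "precursor":
        # precursor intensity handled below; damp everything else
        pass
    elif spec.base_peak in pos:
        intensities[spec.base_peak] = 1000.0
    else:  # requested base peak not implied (e.g. cleavage absent) - use max
        intensities[max(intensities, key=intensities.get)] = 1000.0
    precursor_intensity = 1000.0 if spec.base_peak == "precursor" else float(
        rng.uniform(30.0, 80.0)
    )

    # the terminus fragment and the high-pair anchor share one m/z;
    # emit each position once, keeping the strongest assigned intensity
    by_mz: dict[float, float] = {}
    for key, mz in pos.items():
        by_mz[mz] = max(by_mz.get(mz, 0.0), intensities[key])
    fragments = list(by_mz.items())
    fragments.append((spec.precursor_mz, precursor_intensity))
    for mz in spec.extra_fragments:
        fragments.append((mz, float(rng.uniform(300.0, 450.0))))

    # rule-consistent positions a decoy must avoid: real fragments plus
    # every location where a detector would look for evidence
    guard = {mz for mz, _ in fragments}
    guard.add(spec.precursor_mz - SULFATE_LOSS)
    guard.add(spec.precursor_mz - TERMINUS_PRECURSOR)
    base = pos.get("desulfated", spec.precursor_mz)
    guard.add(base - TERMINUS_DESULFATED)
    for arm in (392.0, 398.0, 426.0):
        guard.add(base - arm)
        guard.add(spec.precursor_mz - arm)

    placed: list[float] = []
    attempts = 0
    while len(placed) < n_decoys:
        attempts += 1
        if attempts > 10000:
            raise RuntimeError("could not place decoys clear of rule positions")
        mz = float(rng.uniform(150.0, spec.precursor_mz - 5.0))
        occupied = guard | set(placed)
        if any(abs(mz - g) < DECOY_EXCLUSION_DA for g in occupied):
            continue
        # no spurious 58 Da pairs with real fragments or other decoys
        if any(
            abs(abs(mz - g) - PAIR_DELTA) < DECOY_EXCLUSION_DA for g in occupied
        ):
            continue
        placed.append(mz)
    for mz in placed:
        fragments.append((mz, float(rng.uniform(10.0, 100.0))))

    return Spectrum(
        spectrum_id=spec.name,
        precursor_mz=spec.precursor_mz,
        rt_min=spec.rt_min,
        fragments=tuple(sorted(fragments)),
        strain_id=strain_id,
    )


# ---------------------------------------------------------------------------
# The eight published novel variants

ARC_VARIANT_SPECS: tuple[VariantSpec, ...] = (
    VariantSpec("ARC-1", 1226.0, False, 392.0, rt_min=3.89, base_peak="cleavage"),
    # three published 392 Da losses: from the precursor (-> 874), the
    # desulfated ion (-> 754) and a hydrophilic-arm fragment 1022 (-> 630)
    VariantSpec(
        "ARC-2",
        1266.0,
        True,
        392.0,
        rt_min=3.03,
        base_peak="desulfated",
        extra_fragments=(874.0, 1022.0, 630.0),
    ),
    VariantSpec("ARC-3", 1358.0, False, 426.0, rt_min=2.90, base_peak="cleavage"),
    VariantSpec("ARC-4", 1398.0, True, 392.0, rt_min=2.93, base_peak="cleavage"),
    VariantSpec(
        "ARC-5",
        1426.0,
        False,
        392.0,
        has_carbonyl=True,
        terminus=TERMINUS_PRECURSOR,
        rt_min=3.87,
        base_peak="terminus",
    ),
    VariantSpec("ARC-6", 1446.0, True, 398.0, rt_min=3.20, base_peak="cleavage"),
    VariantSpec(
        "ARC-7",
        1506.0,
        False,
        426.0,
        has_carbonyl=True,
        terminus=TERMINUS_PRECURSOR,
        rt_min=4.35,
        base_peak="terminus",
    ),
    VariantSpec(
        "ARC-8",
        1608.0,
        True,
        426.0,
        has_carbonyl=True,
        terminus=TERMINUS_DESULFATED,
        rt_min=3.26,
        base_peak="desulfated",
    ),
)


def known_am_table() -> TransitionTable:
    """Synthetic stand-in transition table of pre-existing known AMs.

    The real known-AM transition list is instrument-method metadata not
    published with the study conditions this package reproduces; these
    entries carry synthetic Q1/Q3/RT values chosen not to collide with
    any ARC variant, and exist so that the "novel vs known" logic can be
    exercised.
    """
    return TransitionTable(
        [
            TransitionEntry("LS-A", 1312.0, 920.0, 3.50, False),
            TransitionEntry("AM-B", 1380.0, 982.0, 3.60, False),
            TransitionEntry("AM-18", 1381.0, 963.0, 3.10, False),
        ]
    )


def make_fixture_table1(
    seed: int = 0, n_decoys: int = 0
) -> tuple[list[Spectrum], TransitionTable]:
    """The packaged eight-variant fixture set.

    One spectrum per ARC-1..ARC-8 built from the published per-variant
    fragmentation descriptions, carrying the published retention times
    and Q1 masses, paired with a known-AM transition table that excludes
    the ARC variants (so all eight annotate as novel).
    """
    rng = np.random.default_rng(seed)
    spectra = [make_spectrum(spec, n_decoys=n_decoys, seed=rng) for spec in ARC_VARIANT_SPECS]
    return spectra, known_am_table()


def random_variant_spec(
    rng: np.random.Generator,
    name: str = "synthetic",
    arm_library: Sequence[float] = (392.0, 398.0, 426.0),
) -> VariantSpec:
    """Draw a random variant spec from the fragmentation grammar."""
    sulfated = bool(rng.integers(0, 2))
    has_carbonyl = bool(rng.integers(0, 2))
    terminus_choices: list[Optional[float]] = [None, TERMINUS_PRECURSOR]
    if sulfated:
        terminus_choices.append(TERMINUS_DESULFATED)
    terminus = terminus_choices[int(rng.integers(0, len(terminus_choices)))]
    return VariantSpec(
        name=name,
        precursor_mz=float(rng.integers(1005, 1796)),
        sulfated=sulfated,
        arm_mass=float(arm_library[int(rng.integers(0, len(arm_library)))]),
        has_carbonyl=has_carbonyl,
        terminus=terminus,
        rt_min=float(rng.uniform(2.0, 4.2)),
        base_peak="cleavage" if rng.integers(0, 2) else "precursor",
    )


# ---------------------------------------------------------------------------
# Strain panels with planted cluster structure


@dataclass(frozen=True)
class PanelConfig:
    """Study conditions for a synthetic strain panel.

    Defaults mirror the published panel: 54 strains in three chemotype
    archetypes — a majority archetype with low/variable AM quotas and
    low toxicity, and two high-AM archetypes with distinct variant
    profiles and moderate vs. high toxicity. Quota means are in fg/cell;
    ``area_cv`` is the lognormal coefficient of variation of the
    simulated peak areas (0 disables all sampling noise, including the
    binomial assay sampling, producing a fully deterministic panel).
    """

    n_strains: int = 54
    mixture: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    area_cv: float = 0.25
    decoys_per_spectrum: int = 3
    death_probability: tuple[float, float, float] = (0.02, 0.12, 0.25)
    n_cells_range: tuple[int, int] = (1_000_000, 5_000_000)
    sample_volume_ul: float = 500.0
    individuals_per_well: int = 60
    seed: int = 0


# per-archetype mean quotas (fg/cell); variant -> mean
_ARCHETYPE_QUOTAS: tuple[dict[str, float], ...] = (
    # archetype 1: low quotas, the common background chemotype
    {"AM20(S)": 40.0, "KAR-A": 10.0, "KAR-B": 20.0},
    # archetype 2: high quotas of the ARC-2/ARC-4 chemotype
    {
        "AM20(M)": 800.0,
        "LP-A": 1200.0,
        "LS-B/SP": 1500.0,
        "ARC-2": 1100.0,
        "ARC-4": 900.0,
    },
    # archetype 3: high quotas of the ARC-3/5/7/8 chemotype
    {
        "AM-A": 700.0,
        "AM-B": 900.0,
        "ARC-3": 1300.0,
        "ARC-5": 1000.0,
        "ARC-7": 1600.0,
        "ARC-8": 800.0,
    },
)


@dataclass
class Panel:
    """A generated strain panel plus its truth manifest."""

    spectra: list[Spectrum]
    peak_areas: list[PeakAreaRecord]
    counts: CountTables
    truth: dict


def make_panel(cfg: PanelConfig, std_conc_ng_per_ul: float = 12.5,
               std_peak_area: float = 1.0e6) -> Panel:
    """Generate a full synthetic strain panel.

    Peak areas are proportional to the planted cell quotas through the
    same calibration the quantifier inverts (area = quota x n_cells /
    (volume x 1e6) x std_area / std_conc), multiplied by mean-preserving
    lognormal noise of the configured CV. Brine-shrimp deaths are
    binomial per well with the archetype death probability (expected
    counts when ``area_cv == 0``). All randomness flows from
    ``cfg.seed``; the truth manifest records planted quotas, cluster
    labels, death probabilities and the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    if not math.isclose(sum(cfg.mixture), 1.0, abs_tol=1e-9):
        raise ValueError("mixture weights must sum to 1")

    # deterministic archetype assignment honoring the exact mixture
    sizes = [int(round(w * cfg.n_strains)) for w in cfg.mixture]
    while sum(sizes) < cfg.n_strains:
        sizes[0] += 1
    while sum(sizes) > cfg.n_strains:
        sizes[int(np.argmax(sizes))] -= 1
    labels = np.concatenate([np.full(n, i) for i, n in enumerate(sizes)])
    rng.shuffle(labels)

    sigma = math.sqrt(math.log(1.0 + cfg.area_cv**2)) if cfg.area_cv > 0 else 0.0

    spectra: list[Spectrum] = []
    peak_areas: list[PeakAreaRecord] = []
    cell_counts: dict[str, tuple[int, float]] = {}
    assay_counts: dict[str, list[WellCount]] = {}
    truth_quotas: dict[str, dict[str, float]] = {}

    variant_specs = {s.name: s for s in ARC_VARIANT_SPECS}

    for idx in range(cfg.n_strains):
        strain = f"SYN{idx + 1:03d}"
        arch = int(labels[idx])
        n_cells = int(rng.integers(cfg.n_cells_range[0], cfg.n_cells_range[1] + 1))
        cell_counts[strain] = (n_cells, cfg.sample_volume_ul)

        quotas: dict[str, float] = {}
        for variant, mean in _ARCHETYPE_QUOTAS[arch].items():
            quotas[variant] = mean
            conc = mean * n_cells / (cfg.sample_volume_ul * 1.0e6)
            area = conc * std_peak_area / std_conc_ng_per_ul
            if sigma > 0:
                # mean-preserving lognormal noise on the measured area
                area *= float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))
            peak_areas.append(
                PeakAreaRecord(
                    strain_id=strain, variant_name=variant, peak_area=area, snr=math.inf
                )
            )
            if variant in variant_specs:
                spec = dataclasses.replace(variant_specs[variant], name=f"{strain}:{variant}")
                spectra.append(
                    make_spectrum(
                        spec, n_decoys=cfg.decoys_per_spectrum, seed=rng, strain_id=strain
                    )
                )
        truth_quotas[strain] = quotas

        p = cfg.death_probability[arch]
        n_ind = cfg.individuals_per_well
        wells: list[WellCount] = []
        for _ in range(3):  # treatment wells
            if cfg.area_cv > 0:
                dead48 = int(rng.binomial(n_ind, p))
                dead24 = int(rng.binomial(dead48, 0.6))
                initial = int(rng.binomial(n_ind, 0.01))
            else:
                dead48 = int(round(n_ind * p))
                dead24 = int(round(dead48 * 0.6))
                initial = 0
            dead24 = min(dead24 + initial, n_ind)
            dead48 = min(dead48 + initial, n_ind)
            wells.append(WellCount("treatment", initial, dead24, dead48, n_ind))
        for well_type in ("dmso_control",) * 3 + ("seawater_control",) * 3:
            if cfg.area_cv > 0:
                cdead = int(rng.binomial(n_ind, 0.005))
            else:
                cdead = 0
            wells.append(WellCount(well_type, 0, cdead, cdead, n_ind))
        assay_counts[strain] = wells

    counts = CountTables(cell_counts=cell_counts, assay_counts=assay_counts)
    truth = {
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "cluster_labels": {f"SYN{i + 1:03d}": int(labels[i]) for i in range(cfg.n_strains)},
        "death_probability": {
            f"SYN{i + 1:03d}": cfg.death_probability[int(labels[i])]
            for i in range(cfg.n_strains)
        },
        "quotas_fg_per_cell": truth_quotas,
        "std_conc_ng_per_ul": std_conc_ng_per_ul,
        "std_peak_area": std_peak_area,
    }
    return Panel(spectra=spectra, peak_areas=peak_areas, counts=counts, truth=truth)


def write_panel(panel: Panel, out_dir: str | Path) -> Path:
    """Write a panel to disk: MGF spectra, CSV tables and truth JSON."""
    from . import spectra_io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spectra_io.write_mgf(panel.spectra, out / "spectra.mgf")
    import pandas as pd

    pd.DataFrame(
        [
            {
                "strain_id": r.strain_id,
                "variant_name": r.variant_name,
                "peak_area": r.peak_area,
                "snr": r.snr,
            }
            for r in panel.peak_areas
        ]
    ).to_csv(out / "peak_areas.csv", index=False)
    spectra_io.write_count_tables(
        panel.counts, out / "cell_counts.csv", out / "assay_counts.csv"
    )
    with open(out / "truth.json", "w") as fh:
        json.dump(panel.truth, fh, indent=2)
    return out
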