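"""End-to-end orchestration: simulate -> screen -> annotate -> quantify
-> toxicity -> profile.

Every stage writes plain CSV/TSV/JSON so any stage can be inspected or
replaced, and a run manifest records the seed, the config hash and
per-stage counts. A failure in one strain never aborts the panel.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cid_annotator import DEFAULT_ARM_LIBRARY, annotate
from .multivariate import (
    build_strain_profile,
    cluster_scores,
    pcoa,
    plot_ordination,
    scale_transform,
)
from .quantify import LpdStandard, quantify_panel
from .screening import SrmPeak, build_nl_library, fs_screen, nl_screen, srm_detect
from .spectra_io import default_transition_table
from .synthetic_data import PanelConfig, make_panel, write_panel
from .toxicity import assay_reduce

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    Tolerances and windows default to the published method settings:
    unit-resolution mass matching (0.5 Da), 0.1 min retention-time
    tolerance, minimum S/N of 3, full-scan window m/z 1000-1800 over
    2.0-4.2 min.
    """

    seed: int = 0
    mz_tol: float = 0.5
    rt_tol: float = 0.1
    snr_min: float = 3.0
    rt_window: tuple[float, float] = (2.0, 4.2)
    mz_range: tuple[float, float] = (1000.0, 1800.0)
    std_conc_ng_per_ul: float = 12.5
    std_peak_area: float = 1.0e6
    std_snr: float = 30.0
    k_clusters: int = 3
    distance: str = "euclidean"
    linkage: str = "complete"
    panel: PanelConfig = field(default_factory=PanelConfig)

    def __post_init__(self) -> None:
        if min(self.mz_tol, self.rt_tol) <= 0:
            raise ValueError("tolerances must be > 0")
        if isinstance(self.panel, dict):
            self.panel = PanelConfig(**self.panel)
        if isinstance(self.rt_window, list):
            self.rt_window = tuple(self.rt_window)
        if isinstance(self.mz_range, list):
            self.mz_range = tuple(self.mz_range)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)
        return path

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rt_window"] = list(self.rt_window)
        d["mz_range"] = list(self.mz_range)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_all(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Run the full synthetic pipeline, writing all stage outputs.

    Stages: panel simulation, three-mode screening, CID annotation,
    LPD-equivalent quantification, brine-shrimp toxicity reduction, and
    strain-profile ordination + clustering. Returns the output
    directory; ``manifest.json`` records seed, config hash, package
    version and per-stage counts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts_log: dict[str, int] = {}

    # simulate ------------------------------------------------------------
    panel_cfg = dataclasses.replace(cfg.panel, seed=cfg.seed)
    panel = make_panel(
        panel_cfg,
        std_conc_ng_per_ul=cfg.std_conc_ng_per_ul,
        std_peak_area=cfg.std_peak_area,
    )
    write_panel(panel, out / "panel")
    counts_log["spectra_simulated"] = len(panel.spectra)
    logger.info("simulate: %d spectra, %d strains", len(panel.spectra),
                len(panel.counts.cell_counts))

    # screen --------------------------------------------------------------
    table = default_transition_table()
    channels = build_nl_library("default")
    srm_peaks = [
        SrmPeak(
            strain_id=r.strain_id,
            q1_mz=e.q1_mz,
            q3_mz=e.q3_mz,
            rt_min=e.rt_min,
            peak_area=r.peak_area,
            snr=r.snr,
        )
        for r in panel.peak_areas
        for e in table
        if e.variant_name == r.variant_name
    ]
    srm_hits = srm_detect(srm_peaks, table, cfg.mz_tol, cfg.rt_tol, cfg.snr_min)
    nl_hits = [
        h
        for s in panel.spectra
        for h in nl_screen(s, channels, cfg.mz_tol, cfg.snr_min)
    ]
    fs_hits = fs_screen(
        panel.spectra,
        rt_window=cfg.rt_window,
        mz_range=cfg.mz_range,
        snr_min=cfg.snr_min,
        exclude_hits=srm_hits + nl_hits,
        mz_tol=cfg.mz_tol,
        rt_tol=cfg.rt_tol,
    )
    all_hits = srm_hits + nl_hits + fs_hits
    pd.DataFrame(
        [
            {
                "spectrum_id": h.spectrum_id,
                "mode": h.mode,
                "q1_mz": h.q1_mz,
                "channel": h.channel_label,
                "rt_min": h.rt_min,
                "snr": h.snr,
            }
            for h in all_hits
        ]
    ).to_csv(out / "screen_hits.tsv", sep="\t", index=False)
    counts_log.update(
        srm_hits=len(srm_hits), nl_hits=len(nl_hits), fs_hits=len(fs_hits)
    )
    logger.info("screen: %d SRM, %d NL, %d FS hits", len(srm_hits), len(nl_hits),
                len(fs_hits))

    # annotate ------------------------------------------------------------
    records = []
    for s in panel.spectra:
        try:
            records.append(
                annotate(s, DEFAULT_ARM_LIBRARY, table, cfg.mz_tol, cfg.rt_tol)
            )
        except Exception:  # pragma: no cover - per-strain failure containment
            logger.exception("annotation failed for %s; continuing", s.spectrum_id)
    with open(out / "annotations.json", "w") as fh:
        json.dump(
            [
                {
                    **dataclasses.asdict(r),
                    "hydrophilic_type": sorted(r.hydrophilic_type),
                }
                for r in records
            ],
            fh,
            indent=2,
        )
    pd.DataFrame(
        [
            {
                "spectrum_id": r.spectrum_id,
                "verdict": r.verdict,
                "sulfated": r.sulfated,
                "arm_mass": r.arm_mass,
                "n_pairs": len(r.carbonyl_pairs),
                "terminus": r.terminus_loss,
                "hydrophilic_type": ";".join(sorted(r.hydrophilic_type)),
            }
            for r in records
        ]
    ).to_csv(out / "annotations.tsv", sep="\t", index=False)
    counts_log["novel_calls"] = sum(r.verdict == "novel" for r in records)
    counts_log["known_calls"] = sum(r.verdict.startswith("known") for r in records)
    logger.info("annotate: %d records, %d novel", len(records),
                counts_log["novel_calls"])

    # quantify ------------------------------------------------------------
    std = LpdStandard(cfg.std_conc_ng_per_ul, cfg.std_peak_area, cfg.std_snr)
    quant_records, totals = quantify_panel(panel.peak_areas, std, panel.counts)
    quant_df = pd.DataFrame(
        [
            {
                "strain_id": r.strain_id,
                "variant": r.variant_name,
                "conc_ng_ul": r.conc_ng_per_ul,
                "quota_fg_cell": r.cell_quota_fg_per_cell,
                "lod_fg_cell": r.lod_fg_per_cell,
                "below_lod": r.below_lod,
            }
            for r in quant_records
        ]
    )
    quant_df.to_csv(out / "quant.csv", index=False)
    wide = quant_df.pivot_table(
        index="strain_id", columns="variant", values="quota_fg_cell", fill_value=0.0
    )
    wide.to_csv(out / "quota_matrix.csv")
    counts_log["strains_quantified"] = wide.shape[0]

    # toxicity ------------------------------------------------------------
    tox_records = assay_reduce(panel.counts)
    tox_df = pd.DataFrame(
        [
            {
                "strain_id": r.strain_id,
                "rate_per_day": r.mortality_rate_per_day,
                "adjusted_dead_24h": r.adjusted_dead_24h,
                "adjusted_dead_48h": r.adjusted_dead_48h,
            }
            for r in tox_records
        ]
    )
    tox_df.to_csv(out / "toxicity.csv", index=False)
    counts_log["strains_toxicity"] = len(tox_records)

    # profile -------------------------------------------------------------
    mortality = tox_df.set_index("strain_id")["rate_per_day"]
    profile = build_strain_profile(wide, mortality)
    scaled = scale_transform(profile)
    ordination = pcoa(scaled, distance=cfg.distance)
    labels = cluster_scores(
        ordination.scores,
        k=cfg.k_clusters,
        linkage=cfg.linkage,
        positive_axes=ordination.eigenvalues,
    )
    ordination.cluster_labels = labels
    ordination.scores.to_csv(out / "pcoa_scores.csv")
    pd.DataFrame(
        {
            "eigenvalue": ordination.eigenvalues,
            "pct_variability": ordination.pct_variability,
        }
    ).to_csv(out / "pcoa_eigenvalues.csv", index=False)
    labels.to_csv(out / "clusters.csv")
    plot_ordination(ordination, str(out / "ordination.png"), color_by=labels)
    counts_log["clusters"] = int(labels.nunique())

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": cfg.as_dict(),
        "stage_counts": counts_log,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
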