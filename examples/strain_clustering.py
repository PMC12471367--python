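"""Ordinate and cluster strain chemotype profiles.

Builds a 54-strain panel with three planted chemotype archetypes,
quantifies it, joins the quotas with mortality rates, scales the
features (min-max then ln(x+1)), runs PCoA and clusters the scores.
"""

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from amphiscan import (
    LpdStandard,
    PanelConfig,
    build_strain_profile,
    cluster_scores,
    make_panel,
    pcoa,
    quantify_panel,
    scale_transform,
)
from amphiscan.toxicity import assay_reduce

panel = make_panel(PanelConfig(n_strains=54, area_cv=0.25, seed=1))
std = LpdStandard(panel.truth["std_conc_ng_per_ul"], panel.truth["std_peak_area"], 30.0)
records, _ = quantify_panel(panel.peak_areas, std, panel.counts)

wide = pd.DataFrame(
    [
        {"strain_id": r.strain_id, "variant": r.variant_name,
         "quota": r.cell_quota_fg_per_cell}
        for r in records
    ]
).pivot_table(index="strain_id", columns="variant", values="quota", fill_value=0.0)
mortality = pd.Series(
    {r.strain_id: r.mortality_rate_per_day for r in assay_reduce(panel.counts)}
)

scaled = scale_transform(build_strain_profile(wide, mortality))
result = pcoa(scaled, distance="euclidean")
labels = cluster_scores(result.scores, k=3, positive_axes=result.eigenvalues)

truth = pd.Series(panel.truth["cluster_labels"])
print(f"axes 1+2 explain {result.pct_variability[:2].sum():.2f}% of variability")
print(f"cluster sizes: {labels.value_counts().sort_index().to_dict()}")
print(f"adjusted Rand index vs planted archetypes: "
      f"{adjusted_rand_score(truth[labels.index], labels):.3f}")

# The two leading principal coordinates separate the three planted
# chemotypes; an ARI of 1.0 means the hierarchical clustering of the
# PCoA scores recovered the planted archetype of every strain despite
# the 25% lognormal noise on the simulated peak areas.
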