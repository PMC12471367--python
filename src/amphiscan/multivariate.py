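"""Ordination and clustering of strain chemotype profiles.

Strain profiles (per-variant cell quotas, total AM quota and brine-
shrimp mortality rate) span several orders of magnitude, so each
feature is min-max scaled to [0, 1] and then log transformed
(ln(x + 1)) before ordination. Principal coordinate analysis (classical
multidimensional scaling of the pairwise distance matrix; Euclidean by
default, Bray-Curtis available) summarizes between-strain structure,
and the PCoA scores feed an agglomerative hierarchical clustering
(complete linkage by default) to delimit chemotype groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .spectra_io import ValidationError

__all__ = [
    "StrainProfile",
    "OrdinationResult",
    "build_strain_profile",
    "scale_transform",
    "pcoa",
    "cluster_scores",
    "plot_ordination",
]


@dataclass
class StrainProfile:
    """Strains x features matrix with optional species/region labels.

    Features are per-variant cell quotas (fg/cell), the total AM quota
    and the brine-shrimp mortality rate (per day); all non-negative.
    """

    data: pd.DataFrame
    species: dict[str, str] | None = None
    region: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            raise ValidationError("duplicate feature names in strain profile")
        if (self.data.values < 0).any():
            raise ValidationError("strain profile has negative entries")


@dataclass
class OrdinationResult:
    """PCoA scores with eigenvalues and optional cluster labels."""

    scores: pd.DataFrame  # strains x axes
    eigenvalues: np.ndarray  # nonincreasing, negative values truncated to 0
    pct_variability: np.ndarray  # percent of total positive-eigenvalue variance
    cluster_labels: pd.Series | None = None


def build_strain_profile(
    quota_wide: pd.DataFrame,
    mortality: pd.Series,
    species: dict[str, str] | None = None,
    region: dict[str, str] | None = None,
) -> StrainProfile:
    """Join a strain x variant quota matrix with mortality rates.

    Adds a ``total_AM`` column (row sum of the variant quotas) and a
    ``mortality_rate`` column; strains missing a mortality value get 0.
    """
    df = quota_wide.copy()
    df["total_AM"] = df.sum(axis=1)
    df["mortality_rate"] = mortality.reindex(df.index).fillna(0.0)
    return StrainProfile(df, species=species, region=region)


def scale_transform(profile: StrainProfile) -> StrainProfile:
    """Min-max scale each feature to [0, 1], then apply ln(x + 1).

    Constant features map to 0. Output values lie in [0, ln 2].
    """
    X = profile.data
    if X.empty:
        raise ValidationError("empty strain profile")
    mins, maxs = X.min(axis=0), X.max(axis=0)
    span = maxs - mins
    scaled = (X - mins).div(span.replace(0.0, np.inf), axis=1)
    return StrainProfile(
        np.log1p(scaled), species=profile.species, region=profile.region
    )


def pcoa(profile: StrainProfile, distance: str = "euclidean") -> OrdinationResult:
    """Principal coordinate analysis of the between-strain distance matrix.

    Classical scaling (cmdscale) of pairwise distances. Negative
    eigenvalues — possible for non-Euclidean metrics such as
    Bray-Curtis — are truncated to 0 for the percent-variability
    computation; axes are ordered by decreasing eigenvalue. Under the
    Euclidean metric the scores equal centered principal-component
    scores.
    """
    X = profile.data
    if len(X) < 3:
        raise ValidationError("PCoA needs at least 3 strains")
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        strains = X.index[X.isna().any(axis=1)].tolist()
        raise ValidationError(f"NaN in strain profile: strains {strains}, features {bad}")
    dm = DistanceMatrix(
        squareform(pdist(X.values, metric=distance)), ids=[str(i) for i in X.index]
    )
    with warnings.catch_warnings():
        # negative eigenvalues from non-Euclidean metrics are handled below
        warnings.simplefilter("ignore")
        res = _skbio_pcoa(dm)
    eig = np.clip(res.eigvals.values, 0.0, None)
    order = np.argsort(-eig)
    eig = eig[order]
    scores = res.samples.values[:, order]
    total = eig.sum()
    pct = 100.0 * eig / total if total > 0 else np.zeros_like(eig)
    scores_df = pd.DataFrame(
        scores,
        index=X.index,
        columns=[f"PCo{i + 1}" for i in range(scores.shape[1])],
    )
    return OrdinationResult(scores=scores_df, eigenvalues=eig, pct_variability=pct)


def cluster_scores(
    scores: pd.DataFrame,
    k: int = 3,
    linkage: str = "complete",
    positive_axes: np.ndarray | None = None,
) -> pd.Series:
    """Agglomerative clustering of PCoA score rows into k groups.

    Euclidean distances between score rows, hierarchical clustering with
    the chosen linkage, cut at k clusters. If ``positive_axes``
    (eigenvalues) is given, only axes with positive eigenvalues are
    used. Labels are 1..k ordered by decreasing cluster size (ties
    broken by first occurrence), so label 1 is always the largest
    cluster.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > len(scores):
        raise ValidationError(f"k={k} exceeds number of strains ({len(scores)})")
    X = scores.values
    if positive_axes is not None:
        X = X[:, positive_axes > 0]
    Z = hierarchy.linkage(X, method=linkage, metric="euclidean")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # relabel by decreasing size; first-occurrence order breaks ties
    sizes = {}
    for lbl in raw:
        sizes[lbl] = sizes.get(lbl, 0) + 1
    first_seen = {lbl: int(np.argmax(raw == lbl)) for lbl in sizes}
    ordered = sorted(sizes, key=lambda l: (-sizes[l], first_seen[l]))
    remap = {old: new + 1 for new, old in enumerate(ordered)}
    return pd.Series([remap[l] for l in raw], index=scores.index, name="cluster")


def plot_ordination(
    result: OrdinationResult,
    path: str,
    color_by: pd.Series | None = None,
) -> str:
    """Scatter plot of the first two PCoA axes, saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    scores = result.scores
    labels = (
        color_by
        if color_by is not None
        else (result.cluster_labels if result.cluster_labels is not None else None)
    )
    if labels is not None:
        for value in sorted(labels.unique()):
            sel = labels == value
            ax.scatter(
                scores.loc[sel, scores.columns[0]],
                scores.loc[sel, scores.columns[1]],
                label=str(value),
                s=30,
            )
        ax.legend(title=labels.name or "group", fontsize=8)
    else:
        ax.scatter(scores.iloc[:, 0], scores.iloc[:, 1], s=30)
    ax.set_xlabel(f"PCo1 ({result.pct_variability[0]:.1f}%)")
    ax.set_ylabel(f"PCo2 ({result.pct_variability[1]:.1f}%)")
    ax.set_title("Strain chemotype ordination")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
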