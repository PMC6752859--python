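"""k-means clustering of family flanking-methylation profiles into H/M/L.

Feature vectors are the 20 CG + 20 CHG flank bins of each family metaprofile
(body bins excluded).  Families are clustered with k-means (k = 3,
k-means++ initialisation, fixed seed) separately for LTR and TIR orders;
clusters are labelled High / Moderate / Low by descending centroid mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .config import ProfileConfig

log = logging.getLogger(__name__)

LABELS = ("H", "M", "L")


@dataclass
class ClusterAssignment:
    """Result of clustering family flank profiles."""

    labels: pd.Series          # family -> cluster index (or H/M/L after labelling)
    centroids: np.ndarray      # k x n_features
    inertia: float
    seed: int
    feature_names: list[str]

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


def family_feature_vectors(
    profiles: pd.DataFrame,
    order: str | None = None,
    config: ProfileConfig = ProfileConfig(),
) -> pd.DataFrame:
    """Build the 40-feature flank matrix from a long family-profile table.

    Rows are families, columns ``cg_flank_00..19`` then ``chg_flank_00..19``
    (left flank bins then right flank bins, oriented).  ``order`` restricts
    to LTR or TIR families.
    """
    fb, bb = config.flank_bins, config.body_bins
    flank_bins = list(range(fb)) + list(range(fb + bb, config.n_bins))
    sub = profiles[profiles["signal"].isin(["cg_ratio", "chg_ratio"])]
    if order is not None:
        sub = sub[sub["order"] == order]
    sub = sub[sub["bin"].isin(flank_bins)]
    wide = sub.pivot_table(
        index="family", columns=["signal", "bin"], values="mean", dropna=False
    )
    cols = []
    names = []
    for sig, tag in (("cg_ratio", "cg"), ("chg_ratio", "chg")):
        for i, b in enumerate(flank_bins):
            cols.append((sig, b))
            names.append(f"{tag}_flank_{i:02d}")
    wide = wide.reindex(columns=pd.MultiIndex.from_tuples(cols))
    wide.columns = names
    return wide


def cluster_family_profiles(
    vectors: pd.DataFrame,
    k: int = 3,
    seed: int = 0,
    n_init: int = 10,
    max_missing: float = 0.5,
    standardize: bool = False,
) -> ClusterAssignment:
    """k-means over family flank feature vectors.

    Families with more than ``max_missing`` missing features are excluded;
    remaining missing values are mean-imputed per feature (logged).  Raw
    [0, 1] ratios are clustered by default; ``standardize`` z-scores the
    features first.
    """
    if len(vectors) < k:
        raise ValueError(f"need at least {k} families, got {len(vectors)}")
    X = vectors.to_numpy(dtype=float)
    frac_missing = np.isnan(X).mean(axis=1)
    keep = frac_missing <= max_missing
    if not np.all(keep):
        log.info("excluding %d families with >%.0f%% missing features",
                 int((~keep).sum()), 100 * max_missing)
    X = X[keep]
    families = vectors.index[keep]
    if np.isnan(X).all(axis=0).any():
        raise ValueError("feature with no observed values")
    n_imputed = int(np.isnan(X).sum())
    if n_imputed:
        col_means = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_means[None, :], X)
        log.info("mean-imputed %d missing feature values", n_imputed)
    km = KMeans(n_clusters=k, n_init=n_init, init="k-means++",
                random_state=seed)
    if standardize:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        fit_X = (X - mu) / sd
    else:
        fit_X = X
    km.fit(fit_X)
    centroids = km.cluster_centers_
    if standardize:
        centroids = centroids * sd[None, :] + mu[None, :]
    return ClusterAssignment(
        labels=pd.Series(km.labels_, index=families, name="cluster"),
        centroids=centroids,
        inertia=float(km.inertia_),
        seed=seed,
        feature_names=list(vectors.columns),
    )


def label_clusters(assignment: ClusterAssignment) -> ClusterAssignment:
    """Label the three clusters H/M/L by descending centroid mean.

    Ranking uses the mean over all 40 flank features; exact ties are broken
    by the CG-feature mean (logged).  The resulting family -> label map is
    invariant to cluster index permutation.
    """
    if assignment.k != len(LABELS):
        raise ValueError("H/M/L labelling requires exactly 3 clusters")
    overall = assignment.centroids.mean(axis=1)
    is_cg = np.array(
        [n.startswith("cg") for n in assignment.feature_names]
    )
    cg_mean = assignment.centroids[:, is_cg].mean(axis=1)
    if len(np.unique(overall)) < len(overall):
        log.warning("duplicate centroid means; tie-broken by CG mean")
    order = np.lexsort((-cg_mean, -overall))
    label_of = {int(ci): LABELS[rank] for rank, ci in enumerate(order)}
    return ClusterAssignment(
        labels=assignment.labels.map(label_of).rename("group"),
        centroids=assignment.centroids[order],
        inertia=assignment.inertia,
        seed=assignment.seed,
        feature_names=assignment.feature_names,
    )


def cluster_and_label(
    vectors: pd.DataFrame, seed: int = 0, n_init: int = 10, **kwargs
) -> ClusterAssignment:
    """Convenience: cluster into 3 groups and label them H/M/L."""
    return label_clusters(
        cluster_family_profiles(vectors, k=3, seed=seed, n_init=n_init, **kwargs)
    )


def k_sweep(
    vectors: pd.DataFrame, k_range=range(2, 6), seed: int = 0, n_init: int = 10
) -> pd.DataFrame:
    """Inertia diagnostic over a range of cluster counts."""
    rows = []
    for k in k_range:
        a = cluster_family_profiles(vectors, k=k, seed=seed, n_init=n_init)
        rows.append(dict(k=k, inertia=a.inertia))
    return pd.DataFrame(rows)
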