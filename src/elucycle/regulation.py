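"""Detection and clustering of cell-cycle-regulated protein profiles.

A protein is regulated when its per-cell 6-fraction profile varies by at
least the fold cutoff (default 2, boundary inclusive). Regulated profiles
are max-scaled, clustered by Ward linkage into 16 clusters, and then
reassigned by the fraction of maximum expression — except for the single
bimodal (two-peak) cluster, which is retained unchanged as the G2&M+G1
class (cluster 7).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .config import FRACTION_BROAD_CLASS, FRACTIONS

logger = logging.getLogger(__name__)

#: argmax fraction -> final cluster number (1..6); cluster 7 is bimodal
FRACTION_CLUSTER = {f: i + 1 for i, f in enumerate(FRACTIONS)}
CLUSTER_BROAD_CLASS = {**{i + 1: FRACTION_BROAD_CLASS[f] for i, f in enumerate(FRACTIONS)},
                       7: "G2M+G1"}


def scale_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Divide each 6-fraction profile by its maximum (heatmap semantics:
    the brightest entry is 1)."""
    mat = profiles[list(FRACTIONS)]
    return mat.div(mat.max(axis=1), axis=0)


def profile_folds(profiles: pd.DataFrame) -> pd.Series:
    mat = profiles[list(FRACTIONS)]
    if (mat <= 0).to_numpy().any():
        raise ValueError("profiles must be strictly positive to compute folds")
    return mat.max(axis=1) / mat.min(axis=1)


def detect_regulated(profiles: pd.DataFrame, cutoff: float = 2.0) -> pd.DataFrame:
    """Regulated iff max/min across the six fractions >= cutoff (inclusive).

    Returns a frame with fold, argmax fraction and the regulated flag;
    classification is invariant to global profile scaling.
    """
    folds = profile_folds(profiles)
    mat = profiles[list(FRACTIONS)]
    argmax = mat.columns[np.argmax(mat.to_numpy(), axis=1)]
    return pd.DataFrame(
        {"fold": folds, "argmax_fraction": argmax, "regulated": folds >= cutoff},
        index=profiles.index,
    )


def _is_bimodal(centroid: np.ndarray, end_frac: float = 0.8,
                dip_frac: float = 0.6) -> bool:
    """Two-peak rule: F1 and F6 entries each >= ``end_frac`` of the centroid
    maximum, with some interior entry <= ``dip_frac`` of the maximum."""
    m = centroid.max()
    return (
        centroid[0] >= end_frac * m
        and centroid[-1] >= end_frac * m
        and centroid[1:-1].min() <= dip_frac * m
    )


@dataclass
class ClusterResult:
    assignments: pd.DataFrame  # cluster (1-7), broad_class, argmax, fold
    centroids: pd.DataFrame
    bimodal_clusters: tuple[int, ...]

    @property
    def bimodal_cluster(self) -> int | None:
        """Largest retained bimodal cluster (None when there is none)."""
        return self.bimodal_clusters[0] if self.bimodal_clusters else None


def cluster_profiles(
    profiles: pd.DataFrame,
    n_clusters: int = 16,
    cutoff: float = 2.0,
) -> ClusterResult:
    """Ward-linkage clustering of max-scaled regulated profiles.

    The initial 16-way cut serves only to isolate the bimodal cluster: its
    members are retained as cluster 7 (G2M+G1) while every other profile is
    reassigned to clusters 1-6 by its fraction of maximum expression, making
    the assignment idempotent and (except for cluster 7) independent of the
    initial cut.
    """
    if len(profiles) < n_clusters + 1:
        raise ValueError(
            f"need at least {n_clusters + 1} regulated profiles, got {len(profiles)}"
        )
    scaled = scale_profiles(profiles)
    Z = linkage(scaled.to_numpy(), method="ward", metric="euclidean")
    raw_labels = fcluster(Z, t=n_clusters, criterion="maxclust")

    centroids = scaled.groupby(raw_labels).mean()
    # every cluster whose centroid is two-peaked is retained as cluster 7;
    # with a single such cluster (the paper's situation) this coincides
    # with keeping "the final cluster" unchanged
    bimodal_candidates = sorted(
        (
            (int((raw_labels == lab).sum()), int(lab))
            for lab in centroids.index
            if _is_bimodal(centroids.loc[lab].to_numpy())
        ),
        key=lambda t: (-t[0], t[1]),
    )
    bimodal = tuple(lab for _, lab in bimodal_candidates)
    if not bimodal:
        logger.info("no bimodal cluster found; cluster 7 left empty")

    det = detect_regulated(profiles, cutoff)
    cluster = det["argmax_fraction"].map(FRACTION_CLUSTER).to_numpy()
    if bimodal:
        cluster = np.where(np.isin(raw_labels, bimodal), 7, cluster)
    assignments = pd.DataFrame(
        {
            "cluster": cluster,
            "broad_class": [CLUSTER_BROAD_CLASS[c] for c in cluster],
            "argmax_fraction": det["argmax_fraction"],
            "fold": det["fold"],
        },
        index=profiles.index,
    )
    return ClusterResult(assignments, centroids, bimodal)


def summarize_regulation(assignments: pd.DataFrame, filtered_size: int) -> dict:
    """Counts and percentages per cluster and broad class, plus the
    regulated share of the quality-filtered data set (percent, one
    decimal)."""
    n_reg = len(assignments)
    per_cluster = assignments["cluster"].value_counts().sort_index()
    per_class = assignments["broad_class"].value_counts()
    summary = {
        "n_regulated": int(n_reg),
        "n_filtered": int(filtered_size),
        "regulated_percent": regulated_percent(n_reg, filtered_size),
        "cluster_counts": {int(k): int(v) for k, v in per_cluster.items()},
        "broad_class_counts": {str(k): int(v) for k, v in per_class.items()},
        "broad_class_percent": {
            str(k): (100.0 * int(v) / n_reg if n_reg else 0.0)
            for k, v in per_class.items()
        },
    }
    return summary


def regulated_percent(n_regulated: int, n_filtered: int) -> float:
    """Regulated / filtered as a percent rounded to one decimal."""
    if n_filtered == 0:
        return 0.0
    return round(100.0 * n_regulated / n_filtered, 1)
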