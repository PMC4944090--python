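"""Animal-level clustering on RLE descriptor profiles.

Animals are clustered with k-means on their (min-max scaled) descriptor
vectors; cluster composition is reported per experimental group as two
ratio families: each cell gives the share of a cluster contributed by a
group, the parenthesized companion the share of a group falling in that
cluster.  A stability score (mean pairwise adjusted Rand index across
seeds and matrix variants) quantifies how reproducible the grouping is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .descriptors import DESCRIPTOR_NAMES
from .exceptions import InputError, ParameterError

__all__ = [
    "WormClustering",
    "CompositionReport",
    "cluster_worms",
    "composition_table",
    "stability_report",
]


@dataclass
class WormClustering:
    """k-means assignment of animals to clusters 1..k."""

    k: int
    assignment: pd.Series  # index animal_id -> cluster id (1-based)
    seed: int
    features: tuple[str, ...]


@dataclass
class CompositionReport:
    """Cluster-by-group composition ratios.

    ``cluster_share``: rows = groups, columns = clusters; each column sums
    to 1 (share of that cluster made up by each group).  ``group_share``:
    same layout, each row sums to 1 (share of that group falling in each
    cluster).  ``counts`` holds the underlying contingency table.
    """

    counts: pd.DataFrame
    cluster_share: pd.DataFrame
    group_share: pd.DataFrame


def _feature_matrix(
    table: pd.DataFrame, features: list[str] | None
) -> tuple[np.ndarray, tuple[str, ...]]:
    if features is None:
        features = [n for n in DESCRIPTOR_NAMES if n in table.columns]
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise InputError(f"features not in table: {missing}")
    X = table[list(features)].to_numpy(dtype=float)
    # min-max scale per feature: descriptors span orders of magnitude
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = hi - lo
    scaled = np.where(span > 0, (X - lo) / np.where(span > 0, span, 1.0), 0.0)
    return scaled, tuple(features)


def cluster_worms(
    table: pd.DataFrame,
    features: list[str] | None = None,
    k: int = 5,
    seed: int = 0,
    restarts: int = 10,
) -> WormClustering:
    """k-means over animals on min-max scaled descriptor features.

    ``table`` is a per-animal descriptor table (index animal_id); by
    default all eleven descriptors present are used.
    """
    if k < 1:
        raise InputError("k must be >= 1")
    if k > len(table):
        raise InputError(f"k={k} exceeds the {len(table)} animals")
    X, feats = _feature_matrix(table, features)
    km = KMeans(
        n_clusters=k, n_init=restarts, random_state=seed, tol=1e-6,
        max_iter=300,
    ).fit(X)
    assignment = pd.Series(
        km.labels_ + 1, index=table.index, name="cluster"
    )
    return WormClustering(k=k, assignment=assignment, seed=seed,
                          features=feats)


def composition_table(
    clustering: WormClustering, groups: pd.Series
) -> CompositionReport:
    """Cluster composition per group (both ratio families).

    ``groups`` maps animal_id → group label and must cover every clustered
    animal.
    """
    idx = clustering.assignment.index
    missing = [a for a in idx if a not in groups.index]
    if missing or groups.reindex(idx).isna().any():
        raise InputError("every clustered animal needs a group label")
    g = groups.reindex(idx)
    counts = pd.crosstab(g, clustering.assignment)
    counts = counts.reindex(
        columns=range(1, clustering.k + 1), fill_value=0
    )
    counts.index.name = "group"
    counts.columns.name = "cluster"
    cluster_tot = counts.sum(axis=0)
    cluster_share = counts / cluster_tot.replace(0, np.nan)
    group_share = counts.div(counts.sum(axis=1), axis=0)
    return CompositionReport(
        counts=counts,
        cluster_share=cluster_share,
        group_share=group_share,
    )


def stability_report(
    tables: pd.DataFrame | dict[str, pd.DataFrame],
    features: list[str] | dict[str, list[str]] | None = None,
    k: int = 5,
    n_seeds: int = 5,
    seed: int = 0,
) -> float:
    """Mean pairwise adjusted Rand index of clusterings across seeds
    (and, when several matrix variants are given, across variants).

    ``tables`` is one descriptor table or a mapping variant → table (all
    tables must share the same animals); ``features`` may be per-variant.
    Returns a score in [−1, 1], 1.0 meaning identical groupings throughout.
    """
    if n_seeds < 2:
        raise ParameterError("n_seeds must be >= 2")
    if isinstance(tables, pd.DataFrame):
        tables = {"default": tables}
    if not tables:
        raise InputError("no descriptor tables")

    ref_index = None
    assignments = []
    for kind, table in tables.items():
        if ref_index is None:
            ref_index = table.index
        elif not table.index.equals(ref_index):
            raise InputError("descriptor tables must share the same animals")
        if isinstance(features, dict):
            feats = features.get(kind)
        else:
            feats = features
        for s in range(n_seeds):
            c = cluster_worms(table, feats, k=k, seed=seed + s)
            assignments.append(c.assignment.to_numpy())

    scores = []
    for a in range(len(assignments)):
        for b in range(a + 1, len(assignments)):
            scores.append(adjusted_rand_score(assignments[a], assignments[b]))
    return float(np.mean(scores))
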