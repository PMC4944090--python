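"""Symbolization of steps by k-means clustering.

All angle-bearing steps of a cohort are pooled and clustered with k-means
(Euclidean distance on the min-max-normalized length/angle/speed features,
k = 2..5).  Raw cluster ids are relabeled to symbols 1..k by ascending mean
raw angle, which fixes the symbol semantics independently of k-means
initialization: for k = 2, symbol 1 is the *sharp turn* cluster (angles
mostly < 90°) and symbol 2 the *shallow turn* cluster (angles mostly ≥ 90°).
Each animal's ordered angle-bearing steps then become a symbol string.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .exceptions import (
    DegenerateClusteringError,
    EmptyResultWarning,
    InputError,
    UnsupportedConfigurationError,
)
from .features import StepTable, _NORM_COLUMNS

__all__ = [
    "StepClusterModel",
    "SymbolString",
    "fit_step_clusters",
    "symbolize",
    "angle_rule_agreement",
]


@dataclass
class StepClusterModel:
    """Fitted k-means model over normalized step features.

    ``centroids`` row s−1 is the centroid of symbol s (symbols ordered by
    ascending mean raw angle); ``per_cluster_ranges`` is the per-symbol
    min/max of the raw angle, length and speed.
    """

    k: int
    centroids: np.ndarray  # (k, 3) over (length_norm, angle_norm, speed_norm)
    symbol_of_cluster: dict[int, int]  # raw k-means label -> symbol 1..k
    per_cluster_ranges: pd.DataFrame
    seed: int
    feature_names: tuple[str, ...] = _NORM_COLUMNS


@dataclass
class SymbolString:
    """Ordered symbol sequence for one animal (alphabet {1..k})."""

    animal_id: str
    group_label: str
    symbols: np.ndarray

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=int)

    def __len__(self) -> int:
        return int(self.symbols.size)

    def as_text(self) -> str:
        return "".join(str(s) for s in self.symbols)


def _pooled_features(tables: list[StepTable]) -> pd.DataFrame:
    missing = [
        c
        for t in tables
        if len(t.steps)
        for c in _NORM_COLUMNS
        if c not in t.steps.columns
    ]
    if missing:
        raise InputError(
            "step tables are not normalized (run normalize_features first)"
        )
    frames = [t.angle_bearing() for t in tables]
    frames = [f for f in frames if len(f)]
    if not frames:
        raise InputError("no angle-bearing steps in the cohort")
    return pd.concat(frames, ignore_index=True)


def fit_step_clusters(
    tables: list[StepTable],
    k: int = 2,
    seed: int = 0,
    restarts: int = 10,
) -> StepClusterModel:
    """Fit pooled k-means (k in [2, 5]) on angle-bearing steps.

    Uses Euclidean distance on the normalized features with ``restarts``
    deterministic restarts; clusters are relabeled to symbols by ascending
    mean raw angle and the per-symbol raw feature ranges are reported.
    """
    if not 2 <= k <= 5:
        raise InputError("k must be in [2, 5]")
    pooled = _pooled_features(tables)
    X = pooled[list(_NORM_COLUMNS)].to_numpy()
    if len(X) < k:
        raise DegenerateClusteringError(
            f"only {len(X)} angle-bearing steps for k={k}"
        )
    if np.unique(X, axis=0).shape[0] < k:
        raise DegenerateClusteringError(
            f"fewer than k={k} distinct step-feature points"
        )

    km = KMeans(
        n_clusters=k,
        n_init=restarts,
        random_state=seed,
        tol=1e-6,
        max_iter=300,
    ).fit(X)
    labels = km.labels_

    mean_angle = np.array(
        [pooled["angle_deg"].to_numpy()[labels == c].mean() for c in range(k)]
    )
    order = np.argsort(mean_angle, kind="stable")
    symbol_of_cluster = {int(c): int(s + 1) for s, c in enumerate(order)}
    centroids = km.cluster_centers_[order]

    rows = []
    for s, c in enumerate(order, start=1):
        sub = pooled[labels == c]
        rows.append(
            {
                "symbol": s,
                "angle_min": sub["angle_deg"].min(),
                "angle_max": sub["angle_deg"].max(),
                "length_min": sub["length_mm"].min(),
                "length_max": sub["length_mm"].max(),
                "speed_min": sub["speed_mm_s"].min(),
                "speed_max": sub["speed_mm_s"].max(),
            }
        )
    ranges = pd.DataFrame(rows).set_index("symbol")
    return StepClusterModel(
        k=k,
        centroids=centroids,
        symbol_of_cluster=symbol_of_cluster,
        per_cluster_ranges=ranges,
        seed=seed,
    )


def symbolize(
    tables: list[StepTable], model: StepClusterModel
) -> list[SymbolString]:
    """Assign each angle-bearing step to its nearest centroid's symbol.

    Step order is preserved; an equidistant tie goes to the lowest symbol
    id.  A table with no angle-bearing steps yields an empty string (with a
    warning).
    """
    out = []
    for t in tables:
        ab = t.angle_bearing()
        if not len(ab):
            warnings.warn(
                f"no angle-bearing steps for {t.animal_id!r}; empty symbol "
                "string",
                EmptyResultWarning,
                stacklevel=2,
            )
            out.append(SymbolString(t.animal_id, t.group_label, np.array([])))
            continue
        for c in _NORM_COLUMNS:
            if c not in ab.columns:
                raise InputError("step table is not normalized")
        X = ab[list(model.feature_names)].to_numpy()
        # centroids are ordered by symbol, so argmin resolves ties to the
        # lowest symbol id
        d2 = ((X[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
        symbols = d2.argmin(axis=1) + 1
        out.append(SymbolString(t.animal_id, t.group_label, symbols))
    return out


def angle_rule_agreement(
    strings: list[SymbolString], tables: list[StepTable]
) -> float:
    """Fraction of steps whose symbol matches the 90° angle rule.

    The rule assigns symbol 1 (sharp) to angles < 90° and symbol 2 (shallow)
    to angles ≥ 90°; defined for two-symbol strings only.
    """
    if len(strings) != len(tables):
        raise InputError("strings and tables must pair up one-to-one")
    total = 0
    agree = 0
    for s, t in zip(strings, tables):
        if s.symbols.size and s.symbols.max() > 2:
            raise UnsupportedConfigurationError(
                "angle_rule_agreement is defined for k=2 only"
            )
        angles = t.angle_bearing()["angle_deg"].to_numpy()
        if angles.size != s.symbols.size:
            raise InputError(
                f"string/table length mismatch for {s.animal_id!r}"
            )
        rule = np.where(angles < 90.0, 1, 2)
        agree += int((rule == s.symbols).sum())
        total += int(angles.size)
    if total == 0:
        raise InputError("no steps to score")
    return agree / total
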