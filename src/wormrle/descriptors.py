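"""The eleven RLE path descriptors and the correlation filter.

Each RLE matrix P(i, j) is summarized by eleven scalars (j taken from the
matrix's column values, i the symbol index, n_r the number of runs, n_p the
number of symbols):

========  =====================================================
SRE       (1/n_r) ΣΣ P(i,j)/j²        short-run emphasis
LRE       (1/n_r) ΣΣ P(i,j)·j²        long-run emphasis
LARE      (1/n_r) ΣΣ P(i,j)/i²        low-angle (sharp-turn) emphasis
HARE      (1/n_r) ΣΣ P(i,j)·i²        high-angle (shallow-turn) emphasis
SRLAE     (1/n_r) ΣΣ P(i,j)/(i²·j²)   short-run, low-angle
SRHAE     (1/n_r) ΣΣ P(i,j)·i²/j²     short-run, high-angle
LRLAE     (1/n_r) ΣΣ P(i,j)·j²/i²     long-run, low-angle
LRHAE     (1/n_r) ΣΣ P(i,j)·i²·j²     long-run, high-angle
ALN       (1/n_r) Σ_i (Σ_j P(i,j))²   angle-level nonuniformity
RLN       (1/n_r) Σ_j (Σ_i P(i,j))²   run-length nonuniformity
RP        n_r / n_p                    run percentage
========  =====================================================

ALN and RLN square the marginal sums (the standard run-length
nonuniformity definitions).  The low/high *angle* wording reflects the
two-symbol alphabet, where symbol 1 is the sharp-turn cluster and symbol 2
the shallow-turn cluster; matrices over more symbols are supported
structurally.

Because several descriptors are strongly redundant, a greedy correlation
filter (Pearson, threshold 0.9, fixed scan order as listed above) reduces
the per-matrix descriptor set before the animal-level clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateFeatureWarning,
    InsufficientDataError,
    InputError,
    UndefinedDescriptorError,
)
from .rle import RLEMatrix

__all__ = [
    "DESCRIPTOR_NAMES",
    "DescriptorVector",
    "compute_descriptors",
    "descriptor_table",
    "select_descriptors",
]

DESCRIPTOR_NAMES = (
    "SRE",
    "LRE",
    "LARE",
    "HARE",
    "SRLAE",
    "SRHAE",
    "LRLAE",
    "LRHAE",
    "ALN",
    "RLN",
    "RP",
)


@dataclass
class DescriptorVector:
    """The eleven descriptors of one animal under one matrix variant."""

    animal_id: str
    group_label: str
    matrix_kind: str
    SRE: float
    LRE: float
    LARE: float
    HARE: float
    SRLAE: float
    SRHAE: float
    LRLAE: float
    LRHAE: float
    ALN: float
    RLN: float
    RP: float

    def values(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in DESCRIPTOR_NAMES])

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in DESCRIPTOR_NAMES}


def compute_descriptors(m: RLEMatrix) -> DescriptorVector:
    """Evaluate the eleven descriptor formulas on one RLE matrix."""
    if m.n_r < 1:
        raise UndefinedDescriptorError(
            f"descriptors undefined for {m.animal_id!r}: no runs (n_r=0)"
        )
    P = m.P
    i2 = (m.symbols.astype(float) ** 2)[:, None]
    j2 = (m.col_values.astype(float) ** 2)[None, :]
    n_r = float(m.n_r)

    row_sums = P.sum(axis=1)
    col_sums = P.sum(axis=0)

    vals = {
        "SRE": (P / j2).sum() / n_r,
        "LRE": (P * j2).sum() / n_r,
        "LARE": (P / i2).sum() / n_r,
        "HARE": (P * i2).sum() / n_r,
        "SRLAE": (P / (i2 * j2)).sum() / n_r,
        "SRHAE": (P * i2 / j2).sum() / n_r,
        "LRLAE": (P * j2 / i2).sum() / n_r,
        "LRHAE": (P * i2 * j2).sum() / n_r,
        "ALN": (row_sums**2).sum() / n_r,
        "RLN": (col_sums**2).sum() / n_r,
        "RP": m.n_r / m.n_p,
    }
    return DescriptorVector(
        animal_id=m.animal_id,
        group_label=m.group_label,
        matrix_kind=m.kind,
        **{k: float(v) for k, v in vals.items()},
    )


def descriptor_table(vectors: list[DescriptorVector]) -> pd.DataFrame:
    """Stack descriptor vectors into a DataFrame (index animal_id)."""
    if not vectors:
        raise InputError("no descriptor vectors")
    kinds = {v.matrix_kind for v in vectors}
    if len(kinds) > 1:
        raise InputError(
            f"descriptor table mixes matrix kinds: {sorted(kinds)}"
        )
    rows = []
    for v in vectors:
        row = {"animal_id": v.animal_id, "group": v.group_label,
               "matrix_kind": v.matrix_kind}
        row.update(v.as_dict())
        rows.append(row)
    return pd.DataFrame(rows).set_index("animal_id")


def select_descriptors(
    table: pd.DataFrame, threshold: float = 0.9
) -> list[str]:
    """Greedy correlation filter over a per-animal descriptor table.

    Scanning the descriptors in their fixed listing order, a descriptor is
    kept iff its absolute Pearson correlation (over animals) with every
    already-kept descriptor is below ``threshold``.  Zero-variance
    descriptors are dropped with a warning.  By construction the kept set
    is pairwise below the threshold.
    """
    if not 0.0 < threshold <= 1.0:
        raise InputError("threshold must be in (0, 1]")
    present = [n for n in DESCRIPTOR_NAMES if n in table.columns]
    if len(present) < 2:
        raise InputError("need at least 2 descriptor columns")
    df = table[present].astype(float)
    if len(df) < 3:
        raise InsufficientDataError(
            f"need >= 3 animals for correlation filtering, got {len(df)}"
        )

    variable = []
    for n in present:
        vals = df[n].to_numpy()
        if vals.max() == vals.min():
            warnings.warn(
                f"descriptor {n!r} is constant across animals; dropped",
                DegenerateFeatureWarning,
                stacklevel=2,
            )
        else:
            variable.append(n)

    corr = df[variable].corr(method="pearson").abs()
    kept: list[str] = []
    for n in variable:
        if all(corr.loc[n, k] < threshold for k in kept):
            kept.append(n)
    return kept
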