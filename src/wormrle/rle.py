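"""Run-length encoding of symbol strings and the RLE matrix variants.

A symbol string like ``"22122221222"`` is compressed into maximal runs
``(2,2)(1,1)(2,4)(1,1)(2,3)``.  From the runs of one animal a count matrix
P(i, j) is built — the number of maximal runs of symbol i with run length j
— in four variants that differ in the column range and binning:

IMF
    columns 1..max run of *this* animal (Individual Maximum Frequency);
AMF
    columns 1..max run across *all* animals (All Maximum Frequency), so
    matrices of different animals are directly comparable;
BAMF
    AMF columns aggregated into bins {1},{2},{3},{4–8},{9–16},{17–32},…
    (dyadic spans, final bin truncated at the global maximum); the column
    value used in descriptor formulas is the bin index;
BAAMF
    same binned counts as BAMF, but each column value is the average of the
    observed run lengths falling in that bin for this animal (empty bins
    take the bin midpoint).

IMFL and AMFL are elementwise ln(1 + count) transforms of IMF and AMF
(zeros are pervasive in these sparse matrices, hence log1p).  All variants
carry the raw totals n_r (number of runs) and n_p (number of symbols).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .exceptions import InputError
from .symbolize import SymbolString

__all__ = [
    "MATRIX_KINDS",
    "RunLengthSequence",
    "BinScheme",
    "RLEMatrix",
    "run_length_encode",
    "run_length_decode",
    "make_bin_scheme",
    "build_matrix",
    "log_transform",
]

MATRIX_KINDS = ("IMF", "AMF", "BAMF", "BAAMF", "IMFL", "AMFL")
_BUILD_KINDS = ("IMF", "AMF", "BAMF", "BAAMF")


@dataclass
class RunLengthSequence:
    """Maximal runs ``(symbol, run_length)`` of one symbol string."""

    runs: list[tuple[int, int]]
    animal_id: str = ""
    group_label: str = ""

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def n_symbols(self) -> int:
        """Total number of symbols in the source string (Σ run lengths)."""
        return sum(j for _, j in self.runs)

    @property
    def max_run(self) -> int:
        return max((j for _, j in self.runs), default=0)


@dataclass(frozen=True)
class BinScheme:
    """Run-length bins {1},{2},{3} then dyadic spans, truncated at max_run."""

    edges: tuple[tuple[int, int], ...]
    max_run: int

    @property
    def n_bins(self) -> int:
        return len(self.edges)

    def bin_index(self, run_length: int) -> int:
        """1-based bin index of a run length."""
        if not 1 <= run_length <= self.max_run:
            raise InputError(
                f"run length {run_length} outside [1, {self.max_run}]"
            )
        his = [hi for _, hi in self.edges]
        return int(np.searchsorted(his, run_length)) + 1

    def midpoint(self, bin_idx: int) -> float:
        lo, hi = self.edges[bin_idx - 1]
        return (lo + hi) / 2.0


@dataclass
class RLEMatrix:
    """Run-count grid P(i, j) with the column values used in descriptors.

    ``P[i-1, c]`` counts runs of symbol i whose (possibly binned) length
    falls in column c; ``col_values[c]`` is the j value that column
    contributes to descriptor formulas.  ``n_r``/``n_p`` are the raw run and
    symbol totals of the source string (carried unchanged through binning
    and log transforms).
    """

    kind: str
    P: np.ndarray
    col_values: np.ndarray
    n_r: int
    n_p: int
    bins: BinScheme | None = None
    empty_bins: tuple[int, ...] = ()
    animal_id: str = ""
    group_label: str = ""

    @property
    def M(self) -> int:
        """Number of symbols (rows)."""
        return int(self.P.shape[0])

    @property
    def n_cols(self) -> int:
        return int(self.P.shape[1])

    @property
    def symbols(self) -> np.ndarray:
        """Row symbol values i = 1..M."""
        return np.arange(1, self.M + 1)


def _symbols_of(s) -> np.ndarray:
    """Accept a SymbolString, a digit string, or an int sequence."""
    if isinstance(s, SymbolString):
        return s.symbols
    if isinstance(s, str):
        return np.array([int(ch) for ch in s], dtype=int)
    return np.asarray(list(s), dtype=int)


def run_length_encode(s) -> RunLengthSequence:
    """Compress a symbol string into maximal ``(symbol, run_length)`` runs.

    ``decode(encode(s)) == s`` for every string; the empty string encodes to
    the empty sequence.
    """
    symbols = _symbols_of(s)
    animal_id = s.animal_id if isinstance(s, SymbolString) else ""
    group_label = s.group_label if isinstance(s, SymbolString) else ""
    if symbols.size == 0:
        return RunLengthSequence([], animal_id, group_label)
    change = np.flatnonzero(np.diff(symbols) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [symbols.size]))
    runs = [
        (int(symbols[a]), int(b - a)) for a, b in zip(starts, ends)
    ]
    return RunLengthSequence(runs, animal_id, group_label)


def run_length_decode(r: RunLengthSequence) -> SymbolString:
    """Exact inverse of :func:`run_length_encode`."""
    out = []
    for sym, length in r.runs:
        if length < 1:
            raise InputError(f"run length must be >= 1, got {length}")
        out.extend([sym] * length)
    return SymbolString(r.animal_id, r.group_label, np.array(out, dtype=int))


def make_bin_scheme(max_run: int) -> BinScheme:
    """Bins {1},{2},{3} then dyadic spans [4,8],[9,16],[17,32],[33,64],…

    The final bin is truncated at ``max_run`` (e.g. max_run=37 gives seven
    bins ending in [33, 37]).
    """
    max_run = int(max_run)
    if max_run < 1:
        raise InputError("max_run must be >= 1")
    edges: list[tuple[int, int]] = []
    for unit in (1, 2, 3):
        if unit <= max_run:
            edges.append((unit, unit))
    lo, hi = 4, 8
    while lo <= max_run:
        edges.append((lo, min(hi, max_run)))
        lo, hi = hi + 1, hi * 2
    return BinScheme(tuple(edges), max_run)


def _infer_n_symbols(runs: RunLengthSequence) -> int:
    return max((sym for sym, _ in runs.runs), default=2)


def build_matrix(
    runs: RunLengthSequence,
    kind: str,
    global_max_run: int | None = None,
    bins: BinScheme | None = None,
    n_symbols: int | None = None,
) -> RLEMatrix:
    """Build one RLE matrix variant from an animal's run sequence.

    ``global_max_run`` (the maximum run length across the cohort) is
    required for AMF and, when ``bins`` is not supplied, for BAMF/BAAMF
    (the bin scheme is then derived from it).  ``n_symbols`` fixes the row
    count M; by default it is inferred from the runs (min 2).
    """
    if kind not in _BUILD_KINDS:
        raise InputError(
            f"kind must be one of {_BUILD_KINDS}, got {kind!r} "
            "(log variants come from log_transform)"
        )
    for sym, length in runs.runs:
        if sym < 1:
            raise InputError(f"symbols must be >= 1, got {sym}")
        if length < 1:
            raise InputError(f"run lengths must be >= 1, got {length}")

    M = int(n_symbols) if n_symbols is not None else _infer_n_symbols(runs)
    if any(sym > M for sym, _ in runs.runs):
        raise InputError("a run's symbol exceeds n_symbols")
    n_r = runs.n_runs
    n_p = runs.n_symbols
    local_max = runs.max_run

    if kind == "IMF":
        N = local_max
        P = np.zeros((M, N))
        for sym, length in runs.runs:
            P[sym - 1, length - 1] += 1
        col_values = np.arange(1, N + 1, dtype=float)
        return RLEMatrix(
            "IMF", P, col_values, n_r, n_p,
            animal_id=runs.animal_id, group_label=runs.group_label,
        )

    if kind == "AMF":
        if global_max_run is None:
            raise InputError("AMF requires global_max_run")
        if local_max > global_max_run:
            bad = next(
                (sym, length)
                for sym, length in runs.runs
                if length > global_max_run
            )
            raise InputError(
                f"run {bad} exceeds global_max_run={global_max_run}"
            )
        P = np.zeros((M, int(global_max_run)))
        for sym, length in runs.runs:
            P[sym - 1, length - 1] += 1
        col_values = np.arange(1, int(global_max_run) + 1, dtype=float)
        return RLEMatrix(
            "AMF", P, col_values, n_r, n_p,
            animal_id=runs.animal_id, group_label=runs.group_label,
        )

    # binned variants
    if bins is None:
        if global_max_run is None:
            raise InputError(f"{kind} requires bins or global_max_run")
        bins = make_bin_scheme(global_max_run)
    if local_max > bins.max_run:
        raise InputError(
            f"run length {local_max} exceeds bin scheme max {bins.max_run}"
        )
    B = bins.n_bins
    P = np.zeros((M, B))
    length_sum = np.zeros(B)
    for sym, length in runs.runs:
        b = bins.bin_index(length)
        P[sym - 1, b - 1] += 1
        length_sum[b - 1] += length

    if kind == "BAMF":
        col_values = np.arange(1, B + 1, dtype=float)
        empty = ()
    else:  # BAAMF
        counts = P.sum(axis=0)
        col_values = np.empty(B)
        empty_list = []
        for b in range(B):
            if counts[b] > 0:
                col_values[b] = length_sum[b] / counts[b]
            else:
                col_values[b] = bins.midpoint(b + 1)
                empty_list.append(b + 1)
        empty = tuple(empty_list)
    return RLEMatrix(
        kind, P, col_values, n_r, n_p, bins=bins, empty_bins=empty,
        animal_id=runs.animal_id, group_label=runs.group_label,
    )


def log_transform(m: RLEMatrix) -> RLEMatrix:
    """Elementwise ln(1 + P) of an IMF or AMF matrix (→ IMFL/AMFL).

    ``n_r`` and ``n_p`` are carried over unchanged; applying the transform
    to an already-transformed or binned matrix is an error.
    """
    if m.kind not in ("IMF", "AMF"):
        raise InputError(
            f"log_transform applies to IMF/AMF only, got {m.kind!r}"
        )
    return RLEMatrix(
        kind=m.kind + "L",
        P=np.log1p(m.P),
        col_values=m.col_values.copy(),
        n_r=m.n_r,
        n_p=m.n_p,
        bins=m.bins,
        empty_bins=m.empty_bins,
        animal_id=m.animal_id,
        group_label=m.group_label,
    )
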