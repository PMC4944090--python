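"""Independent brute-force oracles for the RLE matrix and descriptors.

These deliberately avoid the package's vectorized code paths: runs are
found with a character-by-character scan, the matrix is filled by explicit
loops, and every descriptor formula is evaluated with plain Python loops.
"""

from __future__ import annotations

import math


def runs_by_scan(symbols) -> list[tuple[int, int]]:
    """Maximal runs via a plain left-to-right scan."""
    symbols = list(symbols)
    runs = []
    pos = 0
    while pos < len(symbols):
        sym = symbols[pos]
        length = 0
        while pos < len(symbols) and symbols[pos] == sym:
            length += 1
            pos += 1
        runs.append((int(sym), length))
    return runs


def imf_matrix_bruteforce(symbols, n_symbols: int):
    """IMF count grid as nested lists, plus (col_values, n_r, n_p)."""
    runs = runs_by_scan(symbols)
    max_run = 0
    for _, length in runs:
        if length > max_run:
            max_run = length
    P = [[0.0] * max_run for _ in range(n_symbols)]
    for sym, length in runs:
        P[sym - 1][length - 1] += 1.0
    col_values = [float(j) for j in range(1, max_run + 1)]
    n_p = sum(length for _, length in runs)
    return P, col_values, len(runs), n_p


def descriptors_bruteforce(P, col_values, n_r, n_p) -> dict[str, float]:
    """All eleven descriptors by explicit double loops."""
    M = len(P)
    N = len(col_values)
    sre = lre = lare = hare = srlae = srhae = lrlae = lrhae = 0.0
    for i in range(1, M + 1):
        for jc in range(N):
            p = P[i - 1][jc]
            j = col_values[jc]
            sre += p / j**2
            lre += p * j**2
            lare += p / i**2
            hare += p * i**2
            srlae += p / (i**2 * j**2)
            srhae += p * i**2 / j**2
            lrlae += p * j**2 / i**2
            lrhae += p * i**2 * j**2
    aln = 0.0
    for i in range(M):
        row = 0.0
        for jc in range(N):
            row += P[i][jc]
        aln += row**2
    rln = 0.0
    for jc in range(N):
        col = 0.0
        for i in range(M):
            col += P[i][jc]
        rln += col**2
    return {
        "SRE": sre / n_r,
        "LRE": lre / n_r,
        "LARE": lare / n_r,
        "HARE": hare / n_r,
        "SRLAE": srlae / n_r,
        "SRHAE": srhae / n_r,
        "LRLAE": lrlae / n_r,
        "LRHAE": lrhae / n_r,
        "ALN": aln / n_r,
        "RLN": rln / n_r,
        "RP": n_r / n_p,
    }


def heading_deg(x0, y0, x1, y1) -> float:
    return math.degrees(math.atan2(y1 - y0, x1 - x0))


def circ_diff_deg(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return 360.0 - d if d > 180.0 else d
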