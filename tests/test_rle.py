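"""Run-length encoding, the bin scheme, and the matrix variants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from wormrle import (
    InputError,
    RunLengthSequence,
    build_matrix,
    log_transform,
    make_bin_scheme,
    run_length_decode,
    run_length_encode,
)
from _oracles import imf_matrix_bruteforce, runs_by_scan

WORKED_STRING = "22122221222"
WORKED_RUNS = [(2, 2), (1, 1), (2, 4), (1, 1), (2, 3)]


# -- encode / decode -------------------------------------------------------

def test_worked_example_encodes_to_expected_runs():
    r = run_length_encode(WORKED_STRING)
    assert r.runs == WORKED_RUNS
    assert r.n_runs == 5
    assert r.n_symbols == 11
    assert r.max_run == 4


def test_worked_example_decodes_back():
    s = run_length_decode(RunLengthSequence(WORKED_RUNS))
    assert s.as_text() == WORKED_STRING


@pytest.mark.parametrize(
    "string,runs",
    [("", []), ("111", [(1, 3)]), ("12121", [(1, 1), (2, 1)] * 2 + [(1, 1)])],
)
def test_small_cases(string, runs):
    assert run_length_encode(string).runs == runs


def test_decode_rejects_nonpositive_run():
    with pytest.raises(InputError):
        run_length_decode(RunLengthSequence([(1, 0)]))


@given(
    st.lists(st.integers(min_value=1, max_value=5), min_size=0, max_size=200)
)
def test_decode_encode_roundtrip(symbols):
    r = run_length_encode(symbols)
    assert list(run_length_decode(r).symbols) == symbols
    # adjacent runs always change symbol
    for (s1, _), (s2, _) in zip(r.runs, r.runs[1:]):
        assert s1 != s2
    assert r.runs == runs_by_scan(symbols)


# -- bin scheme ------------------------------------------------------------

@pytest.mark.parametrize(
    "max_run,expected",
    [
        (37, [(1, 1), (2, 2), (3, 3), (4, 8), (9, 16), (17, 32), (33, 37)]),
        (3, [(1, 1), (2, 2), (3, 3)]),
        (20, [(1, 1), (2, 2), (3, 3), (4, 8), (9, 16), (17, 20)]),
        (1, [(1, 1)]),
        (8, [(1, 1), (2, 2), (3, 3), (4, 8)]),
        (100, [(1, 1), (2, 2), (3, 3), (4, 8), (9, 16), (17, 32),
               (33, 64), (65, 100)]),
    ],
)
def test_bin_edges(max_run, expected):
    scheme = make_bin_scheme(max_run)
    assert list(scheme.edges) == expected


def test_bins_partition_range():
    for max_run in (1, 2, 7, 16, 33, 64, 65, 200):
        scheme = make_bin_scheme(max_run)
        covered = [
            scheme.bin_index(j) for j in range(1, max_run + 1)
        ]
        # every length maps to exactly one bin, indices are nondecreasing
        assert covered == sorted(covered)
        assert covered[0] == 1 and covered[-1] == scheme.n_bins


def test_bin_scheme_rejects_zero():
    with pytest.raises(InputError):
        make_bin_scheme(0)


# -- matrices --------------------------------------------------------------

def test_imf_of_worked_example():
    m = build_matrix(run_length_encode(WORKED_STRING), "IMF")
    assert m.P.shape == (2, 4)
    expected = np.zeros((2, 4))
    expected[0, 0] = 2  # symbol 1, run length 1, twice
    expected[1, 1] = 1
    expected[1, 2] = 1
    expected[1, 3] = 1
    assert np.array_equal(m.P, expected)
    assert m.n_r == 5 and m.n_p == 11
    assert np.array_equal(m.col_values, [1, 2, 3, 4])


def test_amf_pads_to_global_max():
    m = build_matrix(run_length_encode(WORKED_STRING), "AMF",
                     global_max_run=37)
    assert m.P.shape == (2, 37)
    assert m.P[:, 4:].sum() == 0
    assert m.P.sum() == 5


def test_amf_rejects_run_beyond_global_max():
    with pytest.raises(InputError, match="global_max_run"):
        build_matrix(run_length_encode("11111"), "AMF", global_max_run=4)


def test_bamf_of_worked_example_with_37_bins():
    m = build_matrix(
        run_length_encode(WORKED_STRING), "BAMF", global_max_run=37
    )
    assert m.P.shape == (2, 7)
    assert m.P[0, 0] == 2      # two runs of 1 in bin {1}
    assert m.P[1, 1] == 1      # run of 2 in bin {2}
    assert m.P[1, 2] == 1      # run of 3 in bin {3}
    assert m.P[1, 3] == 1      # run of 4 in bin {4..8}
    assert m.P.sum() == 5
    assert np.array_equal(m.col_values, np.arange(1, 8))


def test_baamf_uses_observed_bin_averages():
    m = build_matrix(
        run_length_encode(WORKED_STRING), "BAAMF", global_max_run=37
    )
    # bin {1} saw runs of 1; bin {4..8} saw one run of 4
    assert m.col_values[0] == 1.0
    assert m.col_values[3] == 4.0
    # empty bins fall back to the bin midpoint and are flagged
    assert m.col_values[4] == (9 + 16) / 2
    assert set(m.empty_bins) == {5, 6, 7}


def test_empty_runs_give_zero_matrix():
    m = build_matrix(RunLengthSequence([]), "AMF", global_max_run=5)
    assert m.P.sum() == 0 and m.n_r == 0 and m.n_p == 0


def test_binned_matrix_conserves_mass():
    rng = np.random.default_rng(0)
    for _ in range(50):
        symbols = rng.integers(1, 3, size=rng.integers(1, 300)).tolist()
        runs = run_length_encode(symbols)
        gmax = runs.max_run
        imf = build_matrix(runs, "IMF")
        bamf = build_matrix(runs, "BAMF", global_max_run=gmax)
        assert imf.P.sum() == bamf.P.sum() == runs.n_runs


@given(
    st.lists(st.integers(min_value=1, max_value=2), min_size=1, max_size=300)
)
def test_unbinned_conservation(symbols):
    runs = run_length_encode(symbols)
    for kind, kwargs in (
        ("IMF", {}),
        ("AMF", {"global_max_run": 400}),
    ):
        m = build_matrix(runs, kind, **kwargs)
        assert m.P.sum() == runs.n_runs
        assert (m.P * m.col_values[None, :]).sum() == len(symbols)


def test_matrix_matches_bruteforce_oracle(rng):
    for _ in range(200):
        n = int(rng.integers(1, 120))
        symbols = rng.integers(1, 3, size=n).tolist()
        m = build_matrix(run_length_encode(symbols), "IMF", n_symbols=2)
        P, cols, n_r, n_p = imf_matrix_bruteforce(symbols, 2)
        assert np.array_equal(m.P, np.array(P))
        assert m.n_r == n_r and m.n_p == n_p
        assert np.array_equal(m.col_values, cols)


# -- log transform ---------------------------------------------------------

def test_log_transform_values_and_kind():
    m = build_matrix(run_length_encode(WORKED_STRING), "IMF")
    lm = log_transform(m)
    assert lm.kind == "IMFL"
    assert np.allclose(lm.P, np.log1p(m.P))
    assert lm.n_r == m.n_r and lm.n_p == m.n_p
    # zero entries stay zero: ln(1+0) = 0
    assert np.all(lm.P[m.P == 0] == 0)


def test_log_transform_entry_closed_form():
    m = build_matrix(run_length_encode("1212121"), "IMF")
    m.P[0, 0] = np.e - 1
    lm = log_transform(m)
    assert np.isclose(lm.P[0, 0], 1.0)


def test_log_transform_is_monotone_entrywise(rng):
    symbols = rng.integers(1, 3, size=500).tolist()
    m = build_matrix(run_length_encode(symbols), "IMF")
    lm = log_transform(m)
    order = np.argsort(m.P, axis=None)
    assert np.all(np.diff(lm.P.flatten()[order]) >= 0)


def test_log_transform_rejects_wrong_kinds():
    m = build_matrix(run_length_encode(WORKED_STRING), "IMF")
    lm = log_transform(m)
    with pytest.raises(InputError):
        log_transform(lm)
    bamf = build_matrix(
        run_length_encode(WORKED_STRING), "BAMF", global_max_run=10
    )
    with pytest.raises(InputError):
        log_transform(bamf)
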