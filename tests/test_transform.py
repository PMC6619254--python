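import numpy as np
import pytest

from tfnbs import (
    EdgeStatMatrix,
    TfnbsParams,
    compute_dh,
    edge_vector_to_matrix,
    tfnbs_transform,
    threshold_ladder,
)
from oracles import naive_stack_scores


def random_stat(n, seed, density=0.6, scale=2.0):
    rng = np.random.default_rng(seed)
    ii, jj = np.triu_indices(n, k=1)
    w = rng.exponential(scale, ii.size) * (rng.random(ii.size) < density)
    return EdgeStatMatrix(edge_vector_to_matrix(w, n), 1, 10)


def test_params_validation():
    with pytest.raises(ValueError):
        TfnbsParams(E=0.0, H=2.0)
    with pytest.raises(ValueError):
        TfnbsParams(E=0.5, H=2.0, n_intervals=0)
    with pytest.raises(ValueError):
        TfnbsParams(E=0.5, H=2.0, h0=-1.0)


def test_dh_is_the_maximum_over_n_intervals():
    stat = EdgeStatMatrix(edge_vector_to_matrix(np.array([5.0, 1.0, 0.2]), 3), 1, 10)
    assert compute_dh(stat, 100) == pytest.approx(0.05)
    stat2 = EdgeStatMatrix(edge_vector_to_matrix(np.array([101.0, 1.0, 0.2]), 3), 1, 10)
    assert compute_dh(stat2, 100) == pytest.approx(1.01)
    with pytest.warns(RuntimeWarning, match="degenerate"):
        assert compute_dh(EdgeStatMatrix(np.zeros((3, 3)), 1, 10)) == 0.0


def test_ladder_counts():
    assert len(threshold_ladder(1.0, 0.01)) == 101  # observed matrix: 101 steps
    np.testing.assert_allclose(
        threshold_ladder(0.55, 0.1), [0.0, 0.1, 0.2, 0.3, 0.4, 0.5], atol=1e-12
    )
    assert len(threshold_ladder(1.37, 0.01)) == 138
    with pytest.raises(ValueError):
        threshold_ladder(1.0, 0.0)


def test_all_zero_stat_gives_zero_scores():
    stat = EdgeStatMatrix(np.zeros((4, 4)), 1, 10)
    out = tfnbs_transform(stat, TfnbsParams(E=0.5, H=2.0), dh=0.0)
    assert not out.values.any()


def test_single_edge_closed_form():
    """Isolated unit-height edge, H=2, dh=0.01: score = 1e-4 * sum k^2 = 33.835."""
    stat = EdgeStatMatrix(edge_vector_to_matrix(np.array([1.0] + [0.0] * 9), 5), 1, 10)
    for E in (0.5, 1.0, 2.7):
        out = tfnbs_transform(stat, TfnbsParams(E=E, H=2.0), dh=0.01)
        assert out.values[0, 1] == pytest.approx(33.835, abs=1e-9)
    # H=3: 1e-6 * sum_{k=1..100} k^3 = 1e-6 * (100*101/2)^2
    out3 = tfnbs_transform(stat, TfnbsParams(E=1.0, H=3.0), dh=0.01)
    assert out3.values[0, 1] == pytest.approx(1e-6 * (100 * 101 / 2) ** 2, rel=1e-9)


def test_disjoint_identical_edges_score_identically():
    stat = np.zeros((6, 6))
    stat[0, 1] = stat[1, 0] = 1.3
    stat[3, 4] = stat[4, 3] = 1.3
    out = tfnbs_transform(EdgeStatMatrix(stat, 1, 10), TfnbsParams(E=0.7, H=2.5), dh=0.013)
    assert out.values[0, 1] == pytest.approx(out.values[3, 4], rel=1e-12)


@pytest.mark.parametrize("seed", range(8))
@pytest.mark.parametrize("E,H", [(0.5, 3.0), (1.0, 2.0), (2.0, 0.5)])
def test_sweep_equals_naive_stack_oracle(seed, E, H):
    """The incremental sweep equals the materialised N x N x t stack."""
    stat = random_stat(12, seed)
    dh = stat.max() / 37  # deliberately not a round count
    out = tfnbs_transform(stat, TfnbsParams(E=E, H=H), dh=dh)
    oracle = naive_stack_scores(stat.values, E, H, dh)
    assert np.abs(out.values - oracle).max() < 1e-9 * max(1.0, oracle.max())


def test_multiply_dh_rescales_without_changing_ranking():
    stat = random_stat(10, 3)
    dh = stat.max() / 100
    off = tfnbs_transform(stat, TfnbsParams(E=0.5, H=3.0), dh=dh)
    on = tfnbs_transform(stat, TfnbsParams(E=0.5, H=3.0, multiply_dh=True), dh=dh)
    assert np.allclose(on.values, off.values * dh, rtol=1e-12)


def test_raising_one_edge_never_decreases_any_score():
    stat = random_stat(9, 5)
    params = TfnbsParams(E=0.6, H=2.0)
    dh = stat.max() / 100
    base = tfnbs_transform(stat, params, dh).values
    bumped = stat.values.copy()
    ii, jj = np.triu_indices(9, k=1)
    nz = [(a, b) for a, b in zip(ii, jj) if bumped[a, b] > 0]
    a, b = nz[len(nz) // 2]
    bumped[a, b] = bumped[b, a] = bumped[a, b] * 1.5
    out = tfnbs_transform(EdgeStatMatrix(bumped, 1, 10), params, dh).values
    assert np.all(out >= base - 1e-9)


def test_clustered_edges_outscore_isolated_edge_of_same_height():
    n = 7
    lone = np.zeros((n, n))
    lone[0, 1] = lone[1, 0] = 2.0
    pair = lone.copy()
    pair[1, 2] = pair[2, 1] = 2.0  # neighbour at the same height
    params = TfnbsParams(E=0.8, H=2.0)
    s_lone = tfnbs_transform(EdgeStatMatrix(lone, 1, 10), params, dh=0.02).values[0, 1]
    s_pair = tfnbs_transform(EdgeStatMatrix(pair, 1, 10), params, dh=0.02).values[0, 1]
    assert s_pair > s_lone


def test_refining_the_ladder_converges():
    """Scores with 200 intervals differ from 100 intervals by < 5% per edge."""
    stat = random_stat(14, 11, density=0.9, scale=1.0)
    params100 = TfnbsParams(E=0.5, H=2.0, multiply_dh=True)
    params200 = TfnbsParams(E=0.5, H=2.0, n_intervals=200, multiply_dh=True)
    s100 = tfnbs_transform(stat, params100, stat.max() / 100).values
    s200 = tfnbs_transform(stat, params200, stat.max() / 200).values
    # edges with appreciable height; near-zero edges see only 1-2 rungs and
    # their relative discretisation error is irreducibly large
    mask = stat.values >= 0.2 * stat.max()
    rel = np.abs(s200[mask] - s100[mask]) / s100[mask]
    assert rel.max() < 0.05
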