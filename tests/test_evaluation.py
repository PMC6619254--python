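import numpy as np
import pandas as pd
import pytest

from tfnbs import (
    aggregate_grid,
    build_ground_truth,
    confusion_counts,
    per_component_sensitivity,
    spurious_neighbor_probability,
)
from tfnbs import DEFAULT_COMPONENT_SIZES


@pytest.fixture(scope="module")
def reference_mask():
    return build_ground_truth(DEFAULT_COMPONENT_SIZES, "tree", N=82, seed=0)


def test_perfect_detection(reference_mask):
    cs = confusion_counts(reference_mask.T, reference_mask)
    assert (cs.TP, cs.FP, cs.FN) == (32, 0, 0)
    assert cs.TN == 3289  # 82*81/2 - 32
    assert cs.sensitivity == 1.0 and cs.specificity == 1.0
    assert cs.fwe_indicator == 0


def test_empty_and_single_false_positive(reference_mask):
    n = reference_mask.node_count
    empty = np.zeros((n, n))
    cs = confusion_counts(empty, reference_mask)
    assert cs.sensitivity == 0.0 and cs.specificity == 1.0 and cs.fwe_indicator == 0
    p = reference_mask.T.copy().astype(float)
    free = np.argwhere(np.triu(p == 0, k=1))[0]
    p[free[0], free[1]] = p[free[1], free[0]] = 1
    cs2 = confusion_counts(p, reference_mask)
    assert cs2.FP == 1 and cs2.fwe_indicator == 1
    assert cs2.sensitivity == 1.0


@pytest.mark.parametrize("seed", range(5))
def test_confusion_conservation(reference_mask, seed):
    """TP+FP+FN+TN always equals the number of unique edges."""
    rng = np.random.default_rng(seed)
    n = reference_mask.node_count
    p = (rng.random((n, n)) < 0.1).astype(int)
    p = np.triu(p, 1)
    p = p + p.T
    cs = confusion_counts(p, reference_mask)
    assert cs.total == n * (n - 1) // 2


def test_shape_mismatch_rejected(reference_mask):
    with pytest.raises(ValueError, match="shape"):
        confusion_counts(np.zeros((10, 10)), reference_mask)


def test_per_component_sensitivity_and_weighted_mean(reference_mask):
    rng = np.random.default_rng(1)
    n = reference_mask.node_count
    p = (rng.random((n, n)) < 0.4).astype(int)
    p = np.triu(p, 1)
    p = p + p.T
    sens = per_component_sensitivity(p, reference_mask)
    assert len(sens) == 5
    extents = [c.extent for c in reference_mask.components]
    weighted = sum(s * e for s, e in zip(sens, extents)) / sum(extents)
    overall = confusion_counts(p, reference_mask).sensitivity
    assert abs(weighted - overall) < 1e-12
    # single-edge component: sensitivity is exactly its detection indicator
    a, b = reference_mask.components[3].edges[0]
    assert sens[3] == float(p[a, b])


def test_spurious_neighbor_probability_values():
    """634 candidate edges at 3.33e-4 each: ~0.21; scaled to 20 nodes: ~0.53."""
    res = spurious_neighbor_probability(8, 82, 3.33e-4, 634)
    assert res.linear == pytest.approx(0.211, abs=5e-4)
    assert round(res.linear, 2) == 0.21
    scaled = spurious_neighbor_probability(20, 82, 3.33e-4, round(634 * 20 / 8))
    assert round(scaled.linear, 2) == 0.53
    assert spurious_neighbor_probability(8, 82, 0.0, 634).linear == 0.0
    # the exact complement never exceeds the linear expected count
    assert res.exact <= res.linear
    with pytest.raises(ValueError):
        spurious_neighbor_probability(8, 82, 1.5, 634)


def test_aggregate_single_record_and_fwe_mixture():
    rec = {
        "method": "tfnbs", "E": 0.5, "H": 3.0, "sensitivity": 0.8,
        "specificity": 0.99, "false_positive_rate": 0.01, "fwe": 1, "fp": 3,
    }
    out = aggregate_grid([rec], ["method", "E", "H"])
    assert len(out) == 1
    assert out.loc[0, "sensitivity"] == 0.8
    assert out.loc[0, "mean_fp_given_any"] == 3

    half = [dict(rec, fwe=1, fp=2) for _ in range(5)] + [dict(rec, fwe=0, fp=0) for _ in range(5)]
    out2 = aggregate_grid(half, ["method"])
    assert out2.loc[0, "fwe_rate"] == 0.5
    assert out2.loc[0, "mean_fp_given_any"] == 2.0


def test_aggregate_matches_streaming_mean_oracle():
    rng = np.random.default_rng(2)
    rows = []
    for i in range(500):
        rows.append({
            "method": "tfnbs" if i % 2 else "nbs_extent",
            "sensitivity": rng.random(),
            "specificity": rng.random(),
            "false_positive_rate": rng.random(),
            "fwe": int(rng.random() < 0.3),
            "fp": int(rng.integers(0, 5)),
        })
    out = aggregate_grid(rows, ["method"]).set_index("method")
    df = pd.DataFrame(rows)
    for method, grp in df.groupby("method"):
        # independent streaming mean
        acc, k = 0.0, 0
        for v in grp["sensitivity"]:
            k += 1
            acc += (v - acc) / k
        assert out.loc[method, "sensitivity"] == pytest.approx(acc, rel=1e-12)
        assert out.loc[method, "n"] == len(grp)

    with pytest.raises(ValueError):
        aggregate_grid([], ["method"])
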