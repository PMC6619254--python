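"""Batch simulation experiments over parameter grids.

These drivers reproduce the simulation-study design: many replicate
cohorts, each analysed with the threshold-free transform over a grid of
(E, H) combinations and with the NBS baseline over a grid of hard F
thresholds, sharing one permutation label stream per cohort so that
method comparisons are paired.  Per-comparison confusion summaries are
returned as tidy tables ready for :func:`tfnbs.evaluation.aggregate_grid`.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from ._kernels import nbs_max_measures, tfnbs_sweep
from .cohort import CohortStack, EdgeStatMatrix, edge_vector_to_matrix, triu_edges
from .components import suprathreshold_components
from .edge_stats import FStatEngine
from .evaluation import confusion_counts, per_component_sensitivity
from .permutation import permutation_labels
from .synthetic import (
    GroundTruthMask,
    ScenarioConfig,
    empty_mask,
    simulate_cohort,
    simulate_scenario,
)
from .transform import threshold_ladder


def conservative_grid() -> list[tuple[float, float]]:
    """The 44 conservative (E, H) combinations: E 0.25-1, H 2.25-4.75, step 0.25."""
    es = np.arange(0.25, 1.01, 0.25)
    hs = np.arange(2.25, 4.76, 0.25)
    return [(round(float(e), 3), round(float(h), 3)) for e in es for h in hs]


def full_grid() -> list[tuple[float, float]]:
    """The 260 initial-search combinations: E in {0.125, 0.25..3}, H 0.25..5."""
    es = [0.125] + [round(0.25 * k, 3) for k in range(1, 13)]
    hs = [round(0.25 * k, 3) for k in range(1, 21)]
    return [(float(e), float(h)) for e in es for h in hs]


def nbs_threshold_grid() -> list[float]:
    """The 25 component-defining F thresholds, 4 to 16 at intervals of 0.5."""
    return [round(4 + 0.5 * k, 2) for k in range(25)]


def _multi_scores(f_edges, dh, h0, es, hs, ei, ej, n_nodes):
    mx = float(f_edges.max())
    if dh <= 0 or mx <= h0:
        return np.zeros((es.shape[0], f_edges.shape[0]))
    heights = threshold_ladder(mx, dh, h0)
    return tfnbs_sweep(ei, ej, np.ascontiguousarray(f_edges), heights, es, hs, n_nodes)


def analyse_cohort(
    cohort: CohortStack,
    mask: GroundTruthMask,
    combos: Sequence[tuple[float, float]],
    f_thresholds: Sequence[float] = (),
    n_perm: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    n_intervals: int = 100,
) -> list[dict]:
    """One cohort, all methods, one shared permutation stream.

    Returns one record per method/parameter cell with confusion counts,
    rates, the FWE indicator and per-component sensitivities.
    """
    n = cohort.node_count
    ii, jj = triu_edges(n)
    ei = ii.astype(np.int64)
    ej = jj.astype(np.int64)
    engine = FStatEngine(cohort.edge_data())
    f_obs = engine.f_values(cohort.labels)
    mx = float(f_obs.max())
    dh = mx / n_intervals if mx > 0 else 0.0

    es = np.array([c[0] for c in combos], dtype=float)
    hs = np.array([c[1] for c in combos], dtype=float)
    obs_scores = _multi_scores(f_obs, dh, 0.0, es, hs, ei, ej, n)

    f_thresholds = list(f_thresholds)
    obs_stat = EdgeStatMatrix(edge_vector_to_matrix(f_obs, n), df1=1, df2=cohort.n_subjects - 2)
    obs_components = {
        thr: suprathreshold_components(obs_stat, thr) for thr in f_thresholds
    }

    k = len(combos)
    tfnbs_null_max = np.empty((k, n_perm))
    nbs_null_ext = np.empty((len(f_thresholds), n_perm))
    nbs_null_int = np.empty((len(f_thresholds), n_perm))
    for p in range(1, n_perm + 1):
        b = permutation_labels(cohort.labels, seed, p)
        f_p = engine.f_values(b)
        s_p = _multi_scores(f_p, dh, 0.0, es, hs, ei, ej, n)
        tfnbs_null_max[:, p - 1] = s_p.max(axis=1) if s_p.size else 0.0
        for t_idx, thr in enumerate(f_thresholds):
            me, mi = nbs_max_measures(ei, ej, f_p, thr, n)
            nbs_null_ext[t_idx, p - 1] = me
            nbs_null_int[t_idx, p - 1] = mi

    records: list[dict] = []

    def _record(method, params, positives_matrix):
        cs = confusion_counts(positives_matrix, mask)
        rec = {
            "method": method,
            **params,
            "TP": cs.TP,
            "FP": cs.FP,
            "FN": cs.FN,
            "TN": cs.TN,
            "fp": cs.FP,
            "sensitivity": cs.sensitivity,
            "specificity": cs.specificity,
            "false_positive_rate": cs.false_positive_rate,
            "fwe": cs.fwe_indicator,
        }
        for c_idx, sens in enumerate(per_component_sensitivity(positives_matrix, mask), 1):
            rec[f"comp_sens_{c_idx}"] = sens
        records.append(rec)

    for c_idx, (e_par, h_par) in enumerate(combos):
        null_sorted = np.sort(tfnbs_null_max[c_idx])
        ge = n_perm - np.searchsorted(null_sorted, obs_scores[c_idx], side="left")
        p_fwe = (1.0 + ge) / (1.0 + n_perm)
        pos = edge_vector_to_matrix((p_fwe <= alpha).astype(float), n)
        _record("tfnbs", {"E": e_par, "H": h_par}, pos)

    for t_idx, thr in enumerate(f_thresholds):
        comps = obs_components[thr]
        for variant, null in (("extent", nbs_null_ext[t_idx]), ("intensity", nbs_null_int[t_idx])):
            null_sorted = np.sort(null)
            pos = np.zeros((n, n))
            for comp in comps:
                meas = (
                    float(comp.extent)
                    if variant == "extent"
                    else comp.intensity - comp.extent * thr
                )
                r = n_perm - np.searchsorted(null_sorted, meas, side="left")
                if (1.0 + r) / (1.0 + n_perm) <= alpha:
                    for a, b_ in comp.edges:
                        pos[a, b_] = 1
                        pos[b_, a] = 1
            _record(f"nbs_{variant}", {"f_threshold": thr}, pos)

    return records


def random_noise_fwe_experiment(
    n_cohorts: int = 100,
    combos: Sequence[tuple[float, float]] = ((0.5, 3.0), (0.25, 2.25)),
    n_perm: int = 500,
    seed: int = 0,
    N: int = 82,
    n_per_group: int = 100,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Family-wise error of the threshold-free test on pure-noise cohorts.

    Generates ``n_cohorts`` null cohorts (two groups, iid standard normal
    edges) and records, per (E, H) combination, whether any edge reached
    corrected significance.  Returns one row per cohort x combination.
    """
    config = ScenarioConfig(
        scenario="random_noise", N=N, n_per_group=n_per_group, seed=seed
    )
    mask = empty_mask(N)
    rows = []
    for c in range(n_cohorts):
        ss = np.random.SeedSequence((int(seed), 2, c))
        cohort_seed, perm_seed = (int(s % 2**31) for s in ss.generate_state(2))
        cohort = simulate_cohort(mask, config, cohort_seed)
        recs = analyse_cohort(
            cohort, mask, combos, f_thresholds=(), n_perm=n_perm,
            seed=perm_seed, alpha=alpha,
        )
        for r in recs:
            r["cohort"] = c
        rows.extend(recs)
    return pd.DataFrame(rows)


def mixed_cnr_experiment(
    n_replicates: int = 50,
    combos: Sequence[tuple[float, float]] = ((0.25, 2.25), (0.5, 3.0), (0.75, 3.5), (1.0, 4.75)),
    f_thresholds: Sequence[float] = (8.5, 12.0, 16.0),
    n_perm: int = 500,
    seed: int = 0,
    topology: str = "tree",
    N: int = 82,
    n_per_group: int = 100,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Replicate mixed-CNR cohorts analysed with all methods.

    Components of 20/7/3/1/1 edges carry CNRs 0.75/1/0.5/1/0.5; each
    replicate draws a fresh mask and cohort, and all methods share the
    replicate's permutation stream.  Returns one row per replicate x
    method x parameter cell.
    """
    rows = []
    for r in range(n_replicates):
        config = ScenarioConfig(
            scenario="mixed_cnr", N=N, n_per_group=n_per_group,
            topology=topology, seed=0,
        )
        ss = np.random.SeedSequence((int(seed), 3, r))
        scen_seed, perm_seed = (int(s % 2**31) for s in ss.generate_state(2))
        mask, cohort = simulate_scenario(config, seed=scen_seed)
        recs = analyse_cohort(
            cohort, mask, combos, f_thresholds=f_thresholds,
            n_perm=n_perm, seed=perm_seed, alpha=alpha,
        )
        for rec in recs:
            rec["replicate"] = r
        rows.extend(recs)
    return pd.DataFrame(rows)
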