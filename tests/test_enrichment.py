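"""Enrichment metrics: ROC construction, adjusted LogAUC, EF, model selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dockeval import (
    EnrichmentResult,
    EnsembleSummary,
    ScoreSimSpec,
    adjusted_logauc,
    compute_roc,
    enrichment_factor,
    evaluate_model_ensemble,
    gen_score_matrix,
    select_models,
)
from dockeval.enrichment import logauc_bounds, rank_order

PERFECT = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
DIAGONAL = np.array([[0.0, 0.0], [1.0, 1.0]])


# --------------------------------------------------------------------- ROC


def roc_threshold_oracle(scores, labels):
    """Brute-force ROC: one point per threshold, enumerated exhaustively."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    n_act, n_dec = labels.sum(), (~labels).sum()
    pts = {(0.0, 0.0)}
    for t in scores:
        sel = scores <= t
        pts.add(((sel & ~labels).sum() / n_dec, (sel & labels).sum() / n_act))
    return sorted(pts)


def test_roc_all_actives_first_is_step():
    scores = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
    labels = np.array([True, True, True, False, False, False])
    roc = compute_roc(scores, labels)
    assert (0.0, 1.0) in {tuple(p) for p in roc}
    assert tuple(roc[0]) == (0.0, 0.0) and tuple(roc[-1]) == (1.0, 1.0)


def test_roc_matches_threshold_enumeration():
    rng = np.random.default_rng(7)
    scores = rng.permutation(6).astype(float)
    labels = np.array([True, False, True, False, True, False])
    roc = compute_roc(scores, labels)
    assert sorted(map(tuple, roc)) == roc_threshold_oracle(scores, labels)


def test_roc_random_labels_near_diagonal():
    rng = np.random.default_rng(2)
    n = 20000
    scores = rng.normal(size=n)
    labels = rng.random(n) < 0.5
    roc = compute_roc(scores, labels)
    assert np.abs(roc[:, 1] - roc[:, 0]).max() < 0.03


def test_roc_monotone_and_excludes_missing():
    scores = np.array([1.0, 2.0, 3.0, 4.0])
    labels = np.array([True, False, True, False])
    missing = np.array([False, False, True, False])
    roc = compute_roc(scores, labels, missing)
    assert np.all(np.diff(roc[:, 0]) >= 0) and np.all(np.diff(roc[:, 1]) >= 0)
    assert len(roc) == 4  # 3 scored compounds + origin


def test_roc_requires_both_classes():
    with pytest.raises(ValueError, match="active"):
        compute_roc(np.array([1.0, 2.0]), np.array([True, True]))


# ---------------------------------------------------------------- LogAUC


def test_logauc_closed_forms():
    assert adjusted_logauc(DIAGONAL) == pytest.approx(0.0, abs=1e-12)
    assert adjusted_logauc(PERFECT) == pytest.approx(85.538, abs=1e-3)
    lo, hi = logauc_bounds(0.001)
    assert hi == pytest.approx(85.538, abs=1e-3)
    assert lo == pytest.approx(-14.462, abs=1e-3)


def test_logauc_matches_dense_grid_quadrature():
    rng = np.random.default_rng(0)
    fpr = np.sort(np.concatenate([[0.0, 1.0], rng.random(8)]))
    tpr = np.sort(np.concatenate([[0.0, 1.0], rng.random(8)]))
    roc = np.column_stack([fpr, tpr])
    lam = 0.001
    grid = np.logspace(np.log10(lam), 0.0, 10**6)
    area = np.trapezoid(np.interp(grid, fpr, tpr), np.log10(grid)) / 3.0
    oracle = 100.0 * (area - (1 - lam) / (np.log(10.0) * 3.0))
    assert adjusted_logauc(roc, lam) == pytest.approx(oracle, abs=1e-6)


def test_logauc_rejects_bad_lambda():
    for lam in (0.0, 1.0, -0.1, 2.0):
        with pytest.raises(ValueError):
            adjusted_logauc(DIAGONAL, lam)


@settings(derandomize=True, max_examples=25)
@given(st.integers(min_value=0, max_value=10**6))
def test_logauc_invariant_under_monotone_score_transforms(seed):
    """Metrics depend only on the ranking, not the score scale."""
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=60)
    labels = rng.random(60) < 0.3
    if labels.all() or not labels.any():
        return
    base = adjusted_logauc(compute_roc(scores, labels))
    for transform in (lambda s: 3 * s + 7, np.exp, lambda s: s**3 + 0.5 * s):
        t = adjusted_logauc(compute_roc(transform(scores), labels))
        assert t == pytest.approx(base, abs=1e-9)


# -------------------------------------------------------------------- EF


def ef_count_oracle(scores, labels, fraction):
    order = np.lexsort((np.arange(len(scores)), scores))
    n_top = math.ceil(fraction * len(scores))
    top = order[:n_top]
    return (labels[top].sum() / labels.sum()) / fraction


def test_ef_maximal_when_actives_lead():
    scores = np.concatenate([np.zeros(10), np.ones(990)])
    labels = np.concatenate([np.ones(10, bool), np.zeros(990, bool)])
    assert enrichment_factor(scores, labels, 0.01) == pytest.approx(100.0)


def test_ef_matches_brute_force_count():
    rng = np.random.default_rng(3)
    scores = rng.normal(size=200)
    labels = np.zeros(200, bool)
    labels[rng.choice(200, 5, replace=False)] = True
    for fraction in (0.01, 0.05, 0.5):
        assert enrichment_factor(scores, labels, fraction) == pytest.approx(
            ef_count_oracle(scores, labels, fraction)
        )


def test_ef_random_ranking_mean_near_one():
    rng = np.random.default_rng(4)
    labels = np.zeros(1000, bool)
    labels[:10] = True
    efs = [
        enrichment_factor(rng.normal(size=1000), labels, 0.01) for _ in range(1000)
    ]
    assert np.mean(efs) == pytest.approx(1.0, abs=0.3)


def test_ef_bounds_and_validation():
    scores = np.arange(100.0)
    labels = np.zeros(100, bool)
    labels[:5] = True
    assert 0.0 <= enrichment_factor(scores, labels, 0.05) <= 20.0
    with pytest.raises(ValueError):
        enrichment_factor(scores, labels, 0.0)


def test_ef_and_logauc_agree_in_enrichment_sign():
    """Graded separations give EF1% > 1 together with LogAUC > 0."""
    for delta in (0.5, 1.0, 2.0):
        spec = ScoreSimSpec(
            n_models=1, n_actives=100, n_decoys=2000,
            separation_per_model=[delta], seed=17,
        )
        s = evaluate_model_ensemble(gen_score_matrix(spec))
        assert s.results[0].ef[0.01] > 1.0
        assert s.results[0].logauc_adjusted > 0.0


# ------------------------------------------------------------- ensembles


def test_identical_columns_give_identical_results(graded_matrix):
    m = graded_matrix
    m.scores[:, 1] = m.scores[:, 0]
    m.missing[:, 1] = m.missing[:, 0]
    m.scores[:, 2] = m.scores[:, 0]
    m.missing[:, 2] = m.missing[:, 0]
    s = evaluate_model_ensemble(m)
    values = [r.logauc_adjusted for r in s.results]
    assert values[0] == values[1] == values[2]
    assert s.results[0].ef == s.results[1].ef


def _fake_summary(logaucs):
    results = [
        EnrichmentResult(
            model_id=f"m{i:04d}", logauc_adjusted=v, ef={0.01: 1.0},
            n_active_scored=10, n_decoy_scored=100,
        )
        for i, v in enumerate(logaucs)
    ]
    return EnsembleSummary(results)


def test_percentile_cut_is_nearest_rank_counting():
    rng = np.random.default_rng(5)
    logaucs = rng.uniform(-10, 80, size=1000)
    summary = _fake_summary(logaucs)
    top = summary.percentile_cut_ids(98.0)
    assert len(top) == 20
    expected = set(np.argsort(-logaucs)[:20])
    assert {int(m[1:]) for m in top} == expected


def test_ensemble_percentiles_recomputable_from_results(graded_matrix):
    s = evaluate_model_ensemble(graded_matrix)
    assert s.median_logauc() == pytest.approx(
        float(np.median([r.logauc_adjusted for r in s.results]))
    )


def test_model_error_is_tagged_with_model_id(graded_matrix):
    m = graded_matrix
    m.missing[m.is_active, 1] = True  # model_2 loses all actives
    with pytest.raises(ValueError, match="model_2"):
        evaluate_model_ensemble(m)


# ---------------------------------------------------------- model selection


def greedy_maxmin_oracle(logaucs, dist, k):
    """Independent naive loop implementing the documented greedy rule."""
    n = len(logaucs)
    ids = [f"m{i:04d}" for i in range(n)]
    order = sorted(range(n), key=lambda i: (-logaucs[i], ids[i]))
    selected = [order[0]]
    while len(selected) < k:
        best, best_key = None, None
        for i in range(n):
            if i in selected:
                continue
            key = (min(dist[i][j] for j in selected), logaucs[i], ids[i])
            # prefer larger min-dist, larger logauc, then smaller id
            if best is None or (key[0], key[1], [-ord(c) for c in key[2]]) > (
                best_key[0], best_key[1], [-ord(c) for c in best_key[2]]
            ):
                best, best_key = i, key
        selected.append(best)
    return [ids[i] for i in selected]


def test_select_k1_is_best_model():
    summary = _fake_summary([5.0, 30.0, 10.0])
    assert select_models(summary, percentile=0, k=1) == ["m0001"]


def test_select_maxmin_avoids_duplicate_of_seed():
    logaucs = [40.0, 30.0, 20.0, 10.0]
    dist = np.array(
        [
            [0.0, 0.0, 2.0, 3.0],
            [0.0, 0.0, 2.0, 3.0],  # model 1 identical to the seed
            [2.0, 2.0, 0.0, 1.0],
            [3.0, 3.0, 1.0, 0.0],
        ]
    )
    summary = _fake_summary(logaucs)
    picked = select_models(summary, percentile=0, k=3, diversity_matrix=dist)
    assert picked[0] == "m0000"
    assert "m0001" not in picked


def test_select_matches_independent_greedy_oracle():
    rng = np.random.default_rng(6)
    n, k = 20, 3
    logaucs = rng.uniform(0, 50, size=n)
    d = rng.random((n, n))
    dist = (d + d.T) / 2
    np.fill_diagonal(dist, 0.0)
    summary = _fake_summary(logaucs)
    picked = select_models(summary, percentile=0, k=k, diversity_matrix=dist)
    assert picked == greedy_maxmin_oracle(logaucs, dist, k)


def test_select_errors_when_too_few_eligible():
    summary = _fake_summary([1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="need k"):
        select_models(summary, percentile=98, k=2)


def test_rank_order_tie_break_by_id():
    scores = np.array([1.0, 1.0, 0.5])
    ids = ["b", "a", "c"]
    order = rank_order(scores, ids)
    assert [ids[i] for i in order] == ["c", "a", "b"]
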