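"""Retrospective enrichment metrics for receptor-model evaluation.

Given docking scores of known actives and property-matched decoys against an
ensemble of receptor models, this module builds ROC curves, computes the
adjusted semilogarithmic LogAUC and enrichment factors, summarises model
ensembles, and selects a diverse top subset of models for prospective use.

The adjusted LogAUC is the area under the ROC curve with the false-positive
axis on a log10 scale between a lower bound ``lambda_low`` (default 0.001)
and 1, normalised to percent, minus the same integral for the random-guess
diagonal, so that random scoring gives 0 and a perfect classifier gives
100 − 100·(1 − λ)/(ln 10 · log10(1/λ)) ≈ 85.538 at λ = 0.001. This early
recognition-weighted metric is the standard figure of merit for docking
benchmarks, where the interesting signal sits in the first fraction of a
percent of a multi-million-compound ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .scorematrix import ScoreMatrix

__all__ = [
    "EnrichmentResult",
    "EnsembleSummary",
    "compute_roc",
    "adjusted_logauc",
    "enrichment_factor",
    "evaluate_model_ensemble",
    "select_models",
    "rank_order",
]


def rank_order(scores: np.ndarray, compound_ids: list[str] | None = None) -> np.ndarray:
    """Ranking permutation: best (lowest) score first.

    Ties are broken by compound id (stable, documented tie rule) so that every
    ranking-derived quantity is deterministic.
    """
    scores = np.asarray(scores, dtype=float)
    if compound_ids is None:
        compound_ids = [str(i) for i in range(len(scores))]
    order = sorted(range(len(scores)), key=lambda i: (scores[i], compound_ids[i]))
    return np.asarray(order, dtype=int)


def compute_roc(
    scores: np.ndarray,
    labels: np.ndarray,
    missing: np.ndarray | None = None,
    compound_ids: list[str] | None = None,
) -> np.ndarray:
    """ROC points for one model column; lower score = better.

    Parameters
    ----------
    scores, labels:
        Per-compound docking score and boolean active flag.
    missing:
        Optional mask of compounds that failed to dock; they are excluded
        from the ranking entirely (the per-model N therefore varies).

    Returns
    -------
    (k+1, 2) array of (FPR, TPR) points starting at (0, 0) and ending at
    (1, 1), one step per ranked compound under the stable (score, id) tie
    rule, monotone non-decreasing in both coordinates.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if missing is not None:
        keep = ~np.asarray(missing, dtype=bool)
        scores = scores[keep]
        labels = labels[keep]
        if compound_ids is not None:
            compound_ids = [c for c, k in zip(compound_ids, keep) if k]
    n_act = int(labels.sum())
    n_dec = int((~labels).sum())
    if n_act == 0 or n_dec == 0:
        raise ValueError(
            f"ROC needs at least one active and one decoy with scores "
            f"(got {n_act} actives, {n_dec} decoys)"
        )
    order = rank_order(scores, compound_ids)
    act_sorted = labels[order]
    tpr = np.concatenate([[0.0], np.cumsum(act_sorted) / n_act])
    fpr = np.concatenate([[0.0], np.cumsum(~act_sorted) / n_dec])
    return np.column_stack([fpr, tpr])


def adjusted_logauc(roc: np.ndarray, lambda_low: float = 0.001) -> float:
    """Adjusted semilog ROC AUC, percent scale; 0 = random, negative = worse.

    Integral of TPR over log10(FPR) on [λ, 1], normalised by log10(1/λ),
    minus the diagonal's contribution (1 − λ)/(ln10 · log10(1/λ)). The ROC is
    treated as piecewise linear in FPR between its points and each segment is
    integrated against d log10(FPR) in closed form, which reduces to the
    trapezoid rule for the horizontal/vertical segments of a step curve and
    is exact for interpolated segments (so the diagonal scores exactly 0).
    The TPR at FPR = λ is obtained by linear interpolation and points with
    FPR < λ are dropped after interpolation.
    """
    if not (0.0 < lambda_low < 1.0):
        raise ValueError(f"lambda_low must be in (0, 1), got {lambda_low}")
    roc = np.asarray(roc, dtype=float)
    fpr, tpr = roc[:, 0], roc[:, 1]
    # TPR at the lower bound; fpr is non-decreasing so interp is well defined
    # (repeated x values fall back on the last, which matches a step curve).
    tpr_at_lambda = float(np.interp(lambda_low, fpr, tpr))
    keep = fpr > lambda_low
    fpr = np.concatenate([[lambda_low], fpr[keep]])
    tpr = np.concatenate([[tpr_at_lambda], tpr[keep]])
    if fpr[-1] < 1.0:  # defensive: ROC should already end at (1, 1)
        fpr = np.append(fpr, 1.0)
        tpr = np.append(tpr, tpr[-1])
    # exact integral of the piecewise-linear ROC against d log10(FPR):
    # per segment, y = y1 + m (x − x1), and
    # ∫ y dlog10 x = [(y1 − m·x1)·ln(x2/x1) + m·(x2 − x1)] / ln 10
    x1, x2 = fpr[:-1], fpr[1:]
    y1, y2 = tpr[:-1], tpr[1:]
    run = x2 - x1
    nonzero = run > 0
    x1, x2, y1, y2, run = x1[nonzero], x2[nonzero], y1[nonzero], y2[nonzero], run[nonzero]
    m = (y2 - y1) / run
    seg = ((y1 - m * x1) * np.log(x2 / x1) + m * run) / math.log(10.0)
    span = math.log10(1.0 / lambda_low)
    area = float(seg.sum()) / span
    random_area = (1.0 - lambda_low) / (math.log(10.0) * span)
    return 100.0 * (area - random_area)


def logauc_bounds(lambda_low: float = 0.001) -> tuple[float, float]:
    """Attainable (min, max) of the adjusted LogAUC at a given λ."""
    span = math.log10(1.0 / lambda_low)
    random_pct = 100.0 * (1.0 - lambda_low) / (math.log(10.0) * span)
    return (-random_pct, 100.0 - random_pct)


def enrichment_factor(
    scores: np.ndarray,
    labels: np.ndarray,
    fraction: float = 0.01,
    missing: np.ndarray | None = None,
    compound_ids: list[str] | None = None,
) -> float:
    """Enrichment factor at a top fraction of the ranked database.

    EF(f) = (actives in the top ⌈f·N⌉ / total actives) / f, with N counting
    compounds that docked successfully. EF = 1 is the random expectation and
    the ceiling is 1/f. The ceiling cutoff guarantees a non-empty top set for
    any fraction > 0.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if missing is not None:
        keep = ~np.asarray(missing, dtype=bool)
        scores = scores[keep]
        labels = labels[keep]
        if compound_ids is not None:
            compound_ids = [c for c, k in zip(compound_ids, keep) if k]
    n_act = int(labels.sum())
    n_dec = int((~labels).sum())
    if n_act == 0 or n_dec == 0:
        raise ValueError("enrichment factor needs ≥1 active and ≥1 decoy scored")
    n = len(scores)
    n_top = math.ceil(fraction * n)
    order = rank_order(scores, compound_ids)
    hits = int(labels[order[:n_top]].sum())
    return (hits / n_act) / fraction


@dataclass
class EnrichmentResult:
    """Per-model retrospective metrics."""

    model_id: str
    logauc_adjusted: float
    ef: dict[float, float]
    n_active_scored: int
    n_decoy_scored: int
    lambda_low: float = 0.001

    def __post_init__(self) -> None:
        lo, hi = logauc_bounds(self.lambda_low)
        if not (lo - 1e-9 <= self.logauc_adjusted <= hi + 1e-9):
            raise ValueError(
                f"adjusted LogAUC {self.logauc_adjusted} outside [{lo:.3f}, {hi:.3f}]"
            )
        for f, v in self.ef.items():
            if v < -1e-12 or v > 1.0 / f + 1e-9:
                raise ValueError(f"EF at fraction {f} out of [0, {1 / f:.1f}]: {v}")


@dataclass
class EnsembleSummary:
    """All per-model results for a model ensemble, with percentile helpers."""

    results: list[EnrichmentResult]
    lambda_low: float = 0.001
    fractions: tuple[float, ...] = (0.01,)

    @property
    def model_ids(self) -> list[str]:
        return [r.model_id for r in self.results]

    @property
    def logauc_values(self) -> np.ndarray:
        return np.asarray([r.logauc_adjusted for r in self.results])

    def ef_values(self, fraction: float = 0.01) -> np.ndarray:
        return np.asarray([r.ef[fraction] for r in self.results])

    def median_logauc(self) -> float:
        return float(np.median(self.logauc_values))

    def median_ef(self, fraction: float = 0.01) -> float:
        return float(np.median(self.ef_values(fraction)))

    def percentile_cut_ids(self, percentile: float) -> list[str]:
        """Model ids above the nearest-rank percentile of the LogAUC distribution.

        Nearest-rank convention: with n models, the cut index is
        ⌈percentile/100 · n⌉ in the ascending ordering and the models strictly
        above it are returned, so the 98th percentile of 1000 models is
        exactly the top 20. Ordering (and hence the returned subset under
        LogAUC ties) uses the stable (−LogAUC, model_id) rule.
        """
        if not (0.0 <= percentile < 100.0):
            raise ValueError(f"percentile must be in [0, 100), got {percentile}")
        n = len(self.results)
        n_keep = n - math.ceil(percentile / 100.0 * n)
        order = sorted(
            self.results, key=lambda r: (-r.logauc_adjusted, r.model_id)
        )
        return [r.model_id for r in order[:n_keep]]

    def to_frame(self):
        """Per-model metrics as a DataFrame (violin-plot-ready long export)."""
        import pandas as pd

        rows = []
        for r in self.results:
            row = {
                "model_id": r.model_id,
                "logauc_adjusted": r.logauc_adjusted,
                "n_active_scored": r.n_active_scored,
                "n_decoy_scored": r.n_decoy_scored,
            }
            for f, v in r.ef.items():
                row[f"ef_{f:g}"] = v
            rows.append(row)
        return pd.DataFrame(rows)


def evaluate_model_ensemble(
    matrix: ScoreMatrix,
    lambda_low: float = 0.001,
    fractions: tuple[float, ...] = (0.01,),
) -> EnsembleSummary:
    """Score every model column of an actives/decoys matrix.

    Compounds that failed to dock in a model are excluded from that model's
    ranking only, so the effective N varies per model. Per-model failures
    (e.g. a column with no scored actives) are re-raised tagged with the
    model id.
    """
    if matrix.n_models < 1:
        raise ValueError("score matrix has no model columns")
    is_active = matrix.is_active
    results = []
    for model_id in matrix.model_ids:
        scores, miss = matrix.column(model_id)
        try:
            roc = compute_roc(scores, is_active, miss, matrix.compound_ids)
            la = adjusted_logauc(roc, lambda_low)
            efs = {
                f: enrichment_factor(scores, is_active, f, miss, matrix.compound_ids)
                for f in fractions
            }
        except ValueError as exc:
            raise ValueError(f"model {model_id!r}: {exc}") from exc
        scored = ~miss
        results.append(
            EnrichmentResult(
                model_id=model_id,
                logauc_adjusted=la,
                ef=efs,
                n_active_scored=int((is_active & scored).sum()),
                n_decoy_scored=int((~is_active & scored).sum()),
                lambda_low=lambda_low,
            )
        )
    return EnsembleSummary(results, lambda_low=lambda_low, fractions=tuple(fractions))


def select_models(
    summary: EnsembleSummary,
    percentile: float = 98.0,
    k: int = 5,
    diversity_matrix: np.ndarray | None = None,
    model_ids: list[str] | None = None,
) -> list[str]:
    """Pick ``k`` models for the prospective ensemble from the top percentile.

    Without a diversity matrix: top-k by adjusted LogAUC. With one (a pairwise
    model-distance matrix, e.g. binding-site RMSD): greedy max-min selection
    seeded by the best-LogAUC model — each step adds the eligible model whose
    minimum distance to the already-selected set is largest. Ties break by
    (higher LogAUC, model id), making the selection deterministic.
    """
    eligible = summary.percentile_cut_ids(percentile)
    if len(eligible) < k:
        raise ValueError(
            f"only {len(eligible)} models at or above the {percentile:g}th "
            f"percentile cut, need k={k}"
        )
    if diversity_matrix is None:
        return eligible[:k]

    diversity_matrix = np.asarray(diversity_matrix, dtype=float)
    all_ids = model_ids if model_ids is not None else summary.model_ids
    if diversity_matrix.shape != (len(all_ids), len(all_ids)):
        raise ValueError("diversity matrix shape does not match model count")
    idx_of = {m: i for i, m in enumerate(all_ids)}
    logauc_of = {r.model_id: r.logauc_adjusted for r in summary.results}

    selected = [eligible[0]]  # best-LogAUC seed
    remaining = [m for m in eligible[1:]]
    while len(selected) < k:
        best = max(
            remaining,
            key=lambda m: (
                min(diversity_matrix[idx_of[m], idx_of[s]] for s in selected),
                logauc_of[m],
                # reversed-id tiebreak via negative ord trick is overkill;
                # max() with id needs descending order, so invert below
            ),
        )
        # resolve id ties deterministically: among equal (min-dist, logauc),
        # prefer the lexicographically smallest id
        cands = [
            m
            for m in remaining
            if (
                min(diversity_matrix[idx_of[m], idx_of[s]] for s in selected),
                logauc_of[m],
            )
            == (
                min(diversity_matrix[idx_of[best], idx_of[s]] for s in selected),
                logauc_of[best],
            )
        ]
        best = min(cands)
        selected.append(best)
        remaining.remove(best)
    return selected
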