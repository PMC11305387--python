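"""Hit-rate, overlap, potency, and small assay statistics.

Covers the bookkeeping that follows experimental evaluation of a docking
screen's candidates: hit rates (with and without adjustment for compounds
shared between two screens), top-k ranked-list overlap, pEC50 summaries and
unit conversions, response normalisation against a reference agonist,
percent pre-pulse inhibition of the startle response, and the
brain-to-plasma partition coefficient K_p,brain from concentration–time
curves.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "TestedCompound",
    "AssaySeries",
    "hit_rate",
    "adjusted_hit_rate",
    "overlap_fraction",
    "potency_summary",
    "fold_potency",
    "ec50_micromolar",
    "normalize_response",
    "ppi_percent",
    "mean_ppi",
    "brain_penetrance",
]

HIT_EMAX_THRESHOLD = 50.0  # percent of reference maximum at the test concentration


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class TestedCompound:
    """One experimentally evaluated candidate.

    ``origin`` records which screen proposed it ("af", "hm", or "both" for
    the two model ensembles). ``is_hit`` means agonist activity with efficacy
    above 50% of the reference agonist's maximum at the test concentration.
    """

    __test__ = False  # not a pytest class despite the name

    id: str
    origin: str
    is_hit: bool
    pec50: float | None = None
    emax_percent: float | None = None

    def __post_init__(self) -> None:
        if self.pec50 is not None and not (3.0 < self.pec50 < 12.0):
            raise ValueError(
                f"{self.id}: pEC50 {self.pec50} outside sanity bounds (3, 12)"
            )
        if self.emax_percent is not None:
            implied = self.emax_percent > HIT_EMAX_THRESHOLD
            if implied != self.is_hit:
                raise ValueError(
                    f"{self.id}: is_hit={self.is_hit} inconsistent with "
                    f"Emax {self.emax_percent}% (threshold {HIT_EMAX_THRESHOLD}%)"
                )


def hit_rate(tested: list[TestedCompound]) -> tuple[float, int]:
    """Percent of tested compounds confirmed as hits.

    Returns ``(raw_percent, rounded_percent)``; the rounded figure uses
    half-up rounding to an integer (so 21.875 reports as 22).
    """
    if not tested:
        raise ValueError("hit_rate of an empty list")
    hits = sum(t.is_hit for t in tested)
    raw = 100.0 * hits / len(tested)
    return raw, _round_half_up(raw)


def adjusted_hit_rate(
    tested: list[TestedCompound], shared_ids: set[str]
) -> tuple[float, int]:
    """Hit rate after removing compounds shared with another screen.

    Shared compounds are removed from both numerator and denominator, so the
    adjusted rate reflects only the screen's unique proposals. Shared ids not
    present in ``tested`` are ignored with a warning.
    """
    present = {t.id for t in tested}
    stray = shared_ids - present
    if stray:
        log.warning("shared ids not in tested list ignored: %s", sorted(stray))
    remaining = [t for t in tested if t.id not in shared_ids]
    if not remaining:
        raise ValueError("all tested compounds are shared; adjusted rate undefined")
    return hit_rate(remaining)


def overlap_fraction(list_a: list[str], list_b: list[str], k: int = 10000) -> float:
    """Percent overlap of the top-k entries of two ranked id lists."""
    if k <= 0:
        raise ValueError("k must be positive")
    if len(list_a) < k or len(list_b) < k:
        log.warning(
            "ranked lists shorter than k=%d (%d, %d): truncating to shorter",
            k,
            len(list_a),
            len(list_b),
        )
        k = min(k, len(list_a), len(list_b))
        if k == 0:
            raise ValueError("empty ranked list")
    top_a = set(list_a[:k])
    top_b = set(list_b[:k])
    return 100.0 * len(top_a & top_b) / k


def fold_potency(pec50_a: float, pec50_b: float) -> float:
    """Potency ratio 10^(pEC50_a − pEC50_b); direction-sensitive."""
    return 10.0 ** (pec50_a - pec50_b)


def ec50_micromolar(pec50: float, decimals: int | None = 2) -> float:
    """EC50 in μM from pEC50 (−log10 molar); rounded to 2 d.p. by default."""
    value = 10.0 ** (6.0 - pec50)
    return round(value, decimals) if decimals is not None else value


def potency_summary(tested: list[TestedCompound]) -> dict:
    """Range summary of the available pEC50 values.

    Compounds without a pEC50 are excluded from the range with a log entry.
    """
    with_p = [t for t in tested if t.pec50 is not None]
    skipped = [t.id for t in tested if t.pec50 is None]
    if skipped:
        log.info("compounds without pEC50 excluded from range: %s", skipped)
    if not with_p:
        raise ValueError("no pEC50 values available")
    values = [t.pec50 for t in with_p]
    return {
        "min_pec50": min(values),
        "max_pec50": max(values),
        "n": len(values),
        "min_ec50_micromolar": ec50_micromolar(max(values)),
        "max_ec50_micromolar": ec50_micromolar(min(values)),
    }


def normalize_response(raw: float, reference_max: float) -> float:
    """Response as percent of a saturating reference-agonist response."""
    if reference_max <= 0:
        raise ValueError("reference_max must be positive")
    return 100.0 * raw / reference_max


def ppi_percent(startle_mean: float, prepulse_mean: float) -> float:
    """Percent pre-pulse inhibition: [1 − (pre-pulse / startle-only)] × 100."""
    if startle_mean <= 0:
        raise ValueError("startle_mean must be positive")
    return (1.0 - prepulse_mean / startle_mean) * 100.0


def mean_ppi(ppi_values: list[float]) -> float:
    """Mean PPI over the pre-pulse intensities (arithmetic mean)."""
    if not ppi_values:
        raise ValueError("no PPI values")
    return float(np.mean(ppi_values))


@dataclass
class AssaySeries:
    """A concentration–time series for one matrix (plasma or brain).

    ``dilution_factor`` multiplies the concentrations before any AUC is
    taken; brain homogenate prepared at 1:3 (w/v) uses 4.
    """

    times_min: np.ndarray
    concentrations: np.ndarray
    matrix: str = "plasma"
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times_min.shape != self.concentrations.shape:
            raise ValueError("time and concentration arrays differ in length")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("time points must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")

    def auc(self) -> float:
        """Linear-trapezoid AUC after applying the dilution factor."""
        return float(
            np.trapezoid(self.concentrations * self.dilution_factor, self.times_min)
        )


def brain_penetrance(plasma: AssaySeries, brain: AssaySeries) -> dict:
    """Brain-to-plasma partition coefficient K_p,brain = AUC_brain / AUC_plasma."""
    auc_plasma = plasma.auc()
    auc_brain = brain.auc()
    if auc_plasma <= 0:
        raise ValueError("plasma AUC must be positive")
    return {
        "auc_plasma": auc_plasma,
        "auc_brain": auc_brain,
        "kp_brain": auc_brain / auc_plasma,
    }
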