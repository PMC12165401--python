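"""Discrete information-measure estimators and the composed pipeline.

The plug-in estimator evaluates a measure on the estimated PMF directly;
it systematically underestimates Shannon entropy at small sample sizes.
The jackknife works for any measure, while Miller–Madow, Horvitz–Thompson
and Chao–Shen are Shannon-specific bias corrections operating on the raw
counts.

``information(data, ospace, ...)`` chains
discretize -> estimate_pmf -> estimate_from_counts and is bit-identical to
running the three stages by hand.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import Counts, UnsupportedOperationError
from .measures import InformationMeasure, Shannon
from .outcome_spaces import OutcomeSpace, OrdinalPatterns
from .probabilities import RelativeAmount, estimate_pmf

__all__ = [
    "PlugIn",
    "Jackknife",
    "MillerMadow",
    "HorvitzThompson",
    "ChaoShen",
    "Pipeline",
    "estimate_from_counts",
    "information",
    "information_normalized",
]


@dataclass(frozen=True)
class PlugIn:
    """Evaluate the measure on the estimated PMF (naive estimator)."""


@dataclass(frozen=True)
class Jackknife:
    """Leave-one-out bias reduction: N H - ((N-1)/N) Σ_i H_{-i}.

    Works for any measure; the N leave-one-out terms collapse into one
    term per observed outcome (removing any of the n_k samples of outcome
    k yields the same configuration), so the cost is O(K) measure
    evaluations rather than O(N).
    """


@dataclass(frozen=True)
class MillerMadow:
    """Shannon plug-in plus the (K_obs - 1)/(2N) first-order bias term."""


@dataclass(frozen=True)
class HorvitzThompson:
    """Shannon estimator weighting each term by its inclusion probability:
    -Σ p̂ log p̂ / (1 - (1 - p̂)^N)."""


@dataclass(frozen=True)
class ChaoShen:
    """Coverage-adjusted Shannon estimator.

    C = 1 - f1/N (f1 = number of singletons; C := 1 when f1 = N),
    p̃ = C p̂, H = -Σ p̃ log p̃ / (1 - (1 - p̃)^N).
    """


SHANNON_ONLY = (MillerMadow, HorvitzThompson, ChaoShen)
_ALL_ESTIMATORS = (PlugIn, Jackknife) + SHANNON_ONLY


def _check_compatible(measure, est):
    if isinstance(est, SHANNON_ONLY) and not isinstance(measure, Shannon):
        raise TypeError(
            f"{type(est).__name__} is a Shannon-entropy-specific estimator; "
            f"it cannot estimate {type(measure).__name__}"
        )


def _int_counts(counts: Counts) -> np.ndarray:
    if not counts.is_count:
        raise TypeError(
            "this estimator needs integer counts; the outcome space yields "
            "real weights"
        )
    return np.asarray(counts.values, dtype=np.int64)


def estimate_from_counts(measure: InformationMeasure, est, counts: Counts,
                         prob_est=RelativeAmount()) -> float:
    """Estimate a discrete information measure from a counts table."""
    if not isinstance(est, _ALL_ESTIMATORS):
        raise TypeError(f"unknown discrete estimator {est!r}")
    _check_compatible(measure, est)
    if counts.total <= 0:
        raise ValueError("total count is zero")

    if isinstance(est, PlugIn):
        pmf = estimate_pmf(counts, prob_est)
        return measure.value(pmf.probs)

    if isinstance(est, Jackknife):
        n = _int_counts(counts)
        N = int(n.sum())
        if N < 2:
            raise ValueError("jackknife needs at least 2 observations")
        h_full = measure.value(estimate_pmf(counts, prob_est).probs)
        loo_sum = 0.0
        for k in range(n.size):
            if n[k] == 0:
                continue
            reduced = n.astype(float).copy()
            reduced[k] -= 1
            ct_k = Counts(counts.outcomes, reduced, counts.total_possible,
                          all_outcomes=counts.all_outcomes)
            h_k = measure.value(estimate_pmf(ct_k, prob_est).probs)
            loo_sum += int(n[k]) * h_k
        return N * h_full - (N - 1) / N * loo_sum

    # Shannon-specific estimators: MLE probabilities inside the correction
    n = _int_counts(counts)
    n = n[n > 0]
    N = int(n.sum())
    phat = n / N
    ln_b = math.log(measure.base)

    if isinstance(est, MillerMadow):
        pmf = estimate_pmf(counts, prob_est)
        k_obs = n.size
        return measure.value(pmf.probs) + (k_obs - 1) / (2 * N) / ln_b

    if isinstance(est, HorvitzThompson):
        terms = -phat * np.log(phat) / (1.0 - (1.0 - phat) ** N)
        return float(terms.sum() / ln_b)

    # ChaoShen
    f1 = int((n == 1).sum())
    C = 1.0 if f1 == N else 1.0 - f1 / N
    ptilde = C * phat
    ptilde = ptilde[ptilde > 0]
    terms = -ptilde * np.log(ptilde) / (1.0 - (1.0 - ptilde) ** N)
    return float(terms.sum() / ln_b)


@dataclass
class Pipeline:
    """A fully parameterized discrete estimation route.

    The four components are orthogonal: any valid combination of outcome
    space, probabilities estimator, measure and (compatible) discrete
    estimator composes into a valid pipeline.
    """

    ospace: OutcomeSpace = field(default_factory=lambda: OrdinalPatterns(m=3))
    measure: InformationMeasure = field(default_factory=Shannon)
    est: object = field(default_factory=PlugIn)
    prob_est: object = field(default_factory=RelativeAmount)

    def run(self, data, normalized: bool = False) -> float:
        if normalized:
            return information_normalized(data, self.ospace, measure=self.measure,
                                          est=self.est, prob_est=self.prob_est)
        return information(data, self.ospace, measure=self.measure,
                           est=self.est, prob_est=self.prob_est)


def information(data, ospace: OutcomeSpace, *, measure: InformationMeasure = None,
                est=None, prob_est=None) -> float:
    """Estimate a discrete information measure of ``data``.

    Defaults (Shannon, plug-in, relative amount) make
    ``information(x, OrdinalPatterns(m=3))`` the permutation entropy.
    """
    measure = Shannon() if measure is None else measure
    est = PlugIn() if est is None else est
    prob_est = RelativeAmount() if prob_est is None else prob_est
    counts = ospace.counts(data)
    return estimate_from_counts(measure, est, counts, prob_est)


def information_normalized(data, ospace: OutcomeSpace, *, measure=None,
                           est=None, prob_est=None) -> float:
    """Measure divided by its maximum over the outcome space's cardinality.

    1 for a maximally disordered series, 0 for a perfectly ordered one.
    The value is clamped to [0, 1]; bias-corrected estimators can
    otherwise overshoot the theoretical maximum slightly.
    """
    measure = Shannon() if measure is None else measure
    K = ospace.cardinality()
    if K is None:
        raise UnsupportedOperationError(
            f"{type(ospace).__name__} has data-dependent cardinality; "
            "normalization is undefined"
        )
    raw = information(data, ospace, measure=measure, est=est, prob_est=prob_est)
    mx = measure.maximum(K)
    if mx <= 0:
        raise ValueError(f"measure maximum {mx} is not positive for K={K}")
    return float(min(max(raw / mx, 0.0), 1.0))
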