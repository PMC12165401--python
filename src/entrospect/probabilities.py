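"""Probabilities estimators: from outcome counts to a PMF.

Four estimators are provided.  Relative amount (maximum likelihood) is the
plug-in choice and the only one applicable to weighted (non-count) outcome
spaces; add-constant, Bayesian (symmetric Dirichlet) regularization and
James–Stein-type shrinkage smooth the counts and can assign positive mass
to unobserved outcomes when the full support is requested.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import PMF, Counts
from .outcome_spaces import OutcomeSpace

__all__ = [
    "RelativeAmount",
    "AddConstant",
    "BayesianRegularization",
    "Shrinkage",
    "estimate_pmf",
    "all_probabilities",
]


@dataclass(frozen=True)
class RelativeAmount:
    """Maximum-likelihood (plug-in) estimator: p_i = n_i / N."""


@dataclass(frozen=True)
class AddConstant:
    """Add-constant smoothing: p_i = (n_i + c) / (N + c K), c > 0.

    c = 1 is Laplace's rule of succession.
    """

    c: float = 1.0

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("add-constant c must be > 0")


@dataclass(frozen=True)
class BayesianRegularization:
    """Posterior mean under a symmetric Dirichlet(a) prior:
    p_i = (n_i + a) / (N + a K), a >= 0."""

    a: float = 1.0

    def __post_init__(self):
        if self.a < 0:
            raise ValueError("Dirichlet concentration a must be >= 0")


@dataclass(frozen=True)
class Shrinkage:
    """Shrink the MLE toward a target distribution (uniform by default).

    p_i = lam * t_i + (1 - lam) * p̂_i with the data-driven intensity
    lam = clamp((1 - Σ p̂_i²) / ((N - 1) Σ (t_i - p̂_i)²), 0, 1)
    unless ``lam`` is fixed; lam := 1 when the denominator vanishes
    (the MLE already equals the target).
    """

    target: tuple | None = field(default=None)
    lam: float | None = None

    def __post_init__(self):
        if self.lam is not None and not 0.0 <= self.lam <= 1.0:
            raise ValueError("fixed shrinkage lambda must lie in [0, 1]")


_ESTIMATORS = (RelativeAmount, AddConstant, BayesianRegularization, Shrinkage)


def _support(counts: Counts, support: str):
    if support == "observed":
        return list(counts.outcomes), np.asarray(counts.values, dtype=float)
    if support != "full":
        raise ValueError("support must be 'observed' or 'full'")
    if counts.all_outcomes is None:
        raise ValueError(
            "full support requires a finite outcome-space cardinality "
            "(use all_probabilities with an explicit outcome space)"
        )
    outcomes = list(counts.all_outcomes)
    index = {o: i for i, o in enumerate(outcomes)}
    vec = np.zeros(len(outcomes))
    for o, v in zip(counts.outcomes, np.asarray(counts.values, dtype=float)):
        vec[index[o]] = v
    return outcomes, vec


def estimate_pmf(counts: Counts, est=RelativeAmount(), support: str = "observed") -> PMF:
    """Turn a counts table into a probability mass function.

    ``support='full'`` places every outcome of the (finite) space on the
    support, with zero (relative amount) or smoothed positive mass for the
    unobserved ones.
    """
    if not isinstance(est, _ESTIMATORS):
        raise TypeError(f"unknown probabilities estimator {est!r}")
    if not counts.is_count and not isinstance(est, RelativeAmount):
        raise TypeError(
            f"{type(est).__name__} requires integer counts; "
            f"this outcome space yields real weights (use RelativeAmount)"
        )
    outcomes, vec = _support(counts, support)
    N = vec.sum()
    if N <= 0:
        raise ValueError("total count/weight is zero; cannot form a PMF")
    K = vec.size

    if isinstance(est, RelativeAmount):
        probs = vec / N
    elif isinstance(est, (AddConstant, BayesianRegularization)):
        c = est.c if isinstance(est, AddConstant) else est.a
        probs = (vec + c) / (N + c * K)
    else:  # Shrinkage
        mle = vec / N
        if est.target is None:
            target = np.full(K, 1.0 / K)
        else:
            target = np.asarray(est.target, dtype=float)
            if target.size != K:
                raise ValueError(
                    f"shrinkage target has {target.size} entries, support has {K}"
                )
        if est.lam is not None:
            lam = est.lam
        else:
            denom = (N - 1) * np.sum((target - mle) ** 2)
            if denom <= 0:
                lam = 1.0
            else:
                lam = float(np.clip((1.0 - np.sum(mle ** 2)) / denom, 0.0, 1.0))
        probs = lam * target + (1.0 - lam) * mle
    probs = probs / probs.sum()  # exact renormalization
    return PMF(outcomes, probs)


def all_probabilities(data, space: OutcomeSpace, est=RelativeAmount()) -> PMF:
    """PMF over *all* |Ω| outcomes of a finite outcome space.

    Unobserved outcomes receive zero mass under relative-amount estimation
    and strictly positive mass under the smoothing estimators.  Outcomes
    are returned in the canonical enumeration order of the space.
    """
    K = space.cardinality()
    if K is None:
        raise ValueError(
            f"{type(space).__name__} has data-dependent cardinality; "
            "full-support probabilities are undefined"
        )
    ct = space.counts(data)
    all_out = ct.all_outcomes if ct.all_outcomes is not None else space.outcomes()
    full = Counts(ct.outcomes, ct.values, total_possible=K,
                  is_count=ct.is_count, all_outcomes=all_out)
    return estimate_pmf(full, est, support="full")
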