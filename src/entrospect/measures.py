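"""Information-measure definitions evaluated on a PMF.

Each measure is a small frozen dataclass with

* ``value(p)``    -- evaluate the definition on a probability vector,
* ``maximum(K)``  -- the measure's maximum over PMFs with K outcomes
  (attained at the uniform PMF for every definition here), used for
  normalization.

The convention ``0 * log 0 := 0`` applies throughout, so PMFs with or
without explicit zero entries give identical values.  Default logarithm
base is 2 for the log-based measures; Tsallis, Curado, Kaniadakis and the
Tsallis extropy are base-free (natural units).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaincc, gamma as _gamma

from .core import PMF, UnsupportedOperationError

__all__ = [
    "InformationMeasure",
    "Shannon",
    "Renyi",
    "Tsallis",
    "Curado",
    "Kaniadakis",
    "StretchedExponential",
    "ShannonExtropy",
    "RenyiExtropy",
    "TsallisExtropy",
    "FluctuationComplexity",
    "evaluate_measure",
    "measure_maximum",
    "normalized_value",
]

# |q - 1| (or |kappa|) below this threshold dispatches to the Shannon limit
_SINGULAR_TOL = 1e-12


def _probs(p) -> np.ndarray:
    if isinstance(p, PMF):
        return p.probs
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError("input is not a valid PMF")
    return arr


def _shannon_nats(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


class InformationMeasure:
    """Base class; subclasses implement ``value`` and optionally closed-form
    maxima (the default evaluates at the uniform PMF)."""

    def value(self, p) -> float:
        raise NotImplementedError

    def maximum(self, K: int) -> float:
        if K < 1:
            raise ValueError("K must be >= 1")
        return self.value(np.full(K, 1.0 / K))


@dataclass(frozen=True)
class Shannon(InformationMeasure):
    """H = -Σ p_i log_b p_i."""

    base: float = 2.0

    def value(self, p) -> float:
        return _shannon_nats(_probs(p)) / math.log(self.base)

    def maximum(self, K: int) -> float:
        return math.log(K) / math.log(self.base)


@dataclass(frozen=True)
class Renyi(InformationMeasure):
    """H_q = log_b(Σ p_i^q) / (1 - q); Shannon in the q -> 1 limit."""

    q: float = 2.0
    base: float = 2.0

    def __post_init__(self):
        if self.q <= 0:
            raise ValueError("Renyi order q must be > 0")

    def value(self, p) -> float:
        p = _probs(p)
        if abs(self.q - 1.0) < _SINGULAR_TOL:
            return _shannon_nats(p) / math.log(self.base)
        nz = p[p > 0]
        return float(np.log(np.sum(nz ** self.q)) / (1.0 - self.q) / math.log(self.base))

    def maximum(self, K: int) -> float:
        # Renyi entropy of the uniform PMF is log K for every q
        return math.log(K) / math.log(self.base)


@dataclass(frozen=True)
class Tsallis(InformationMeasure):
    """S_q = (k / (q - 1)) (1 - Σ p_i^q); k-scaled Shannon (nats) at q -> 1."""

    q: float = 2.0
    k: float = 1.0

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("Tsallis scale k must be > 0")

    def value(self, p) -> float:
        p = _probs(p)
        if abs(self.q - 1.0) < _SINGULAR_TOL:
            return self.k * _shannon_nats(p)
        nz = p[p > 0]
        return float(self.k * (1.0 - np.sum(nz ** self.q)) / (self.q - 1.0))

    def maximum(self, K: int) -> float:
        if abs(self.q - 1.0) < _SINGULAR_TOL:
            return self.k * math.log(K)
        return self.k * (K ** (1.0 - self.q) - 1.0) / (1.0 - self.q)


@dataclass(frozen=True)
class Curado(InformationMeasure):
    """H_C = Σ (1 - e^{-b p_i}) + e^{-b} - 1, b > 0."""

    b: float = 1.0

    def __post_init__(self):
        if self.b <= 0:
            raise ValueError("Curado b must be > 0")

    def value(self, p) -> float:
        p = _probs(p)
        return float(np.sum(1.0 - np.exp(-self.b * p)) + math.exp(-self.b) - 1.0)


@dataclass(frozen=True)
class Kaniadakis(InformationMeasure):
    """H_κ = -Σ (p^{1+κ} - p^{1-κ}) / (2κ); Shannon (nats) at κ -> 0."""

    kappa: float = 0.5

    def __post_init__(self):
        if not -1.0 < self.kappa < 1.0:
            raise ValueError("kappa must lie in (-1, 1)")

    def value(self, p) -> float:
        p = _probs(p)
        if abs(self.kappa) < _SINGULAR_TOL:
            return _shannon_nats(p)
        nz = p[p > 0]
        return float(-np.sum(nz ** (1 + self.kappa) - nz ** (1 - self.kappa))
                     / (2 * self.kappa))


@dataclass(frozen=True)
class StretchedExponential(InformationMeasure):
    """Anteneodo–Plastino stretched-exponential entropy.

    H_η = Σ_i [ Γ((η+1)/η, -ln p_i) - p_i Γ((η+1)/η) ] / ln b
    with Γ(s, x) the upper incomplete gamma function; the log base enters
    as a unit conversion, so η = 1 recovers the Shannon entropy in base b
    exactly.
    """

    eta: float = 2.0
    base: float = 2.0

    def __post_init__(self):
        if self.eta <= 0:
            raise ValueError("eta must be > 0")

    def value(self, p) -> float:
        p = _probs(p)
        nz = p[p > 0]
        s = (self.eta + 1.0) / self.eta
        upper = gammaincc(s, -np.log(nz)) * _gamma(s)
        return float(np.sum(upper - nz * _gamma(s)) / math.log(self.base))


@dataclass(frozen=True)
class ShannonExtropy(InformationMeasure):
    """J = -Σ (1 - p_i) log_b(1 - p_i): the complement-dual of entropy."""

    base: float = 2.0

    def value(self, p) -> float:
        p = _probs(p)
        comp = 1.0 - p
        nz = comp[comp > 0]
        return float(-(nz * np.log(nz)).sum() / math.log(self.base))

    def maximum(self, K: int) -> float:
        if K == 1:
            return 0.0
        return (K - 1) * math.log(K / (K - 1)) / math.log(self.base)


@dataclass(frozen=True)
class RenyiExtropy(InformationMeasure):
    """q-analog of the Shannon extropy.

    J_q = log_b(Σ (1 - p_i)^q - (K - 2)) / (1 - q); reduces to the Shannon
    extropy as q -> 1 and vanishes on degenerate PMFs.
    """

    q: float = 2.0
    base: float = 2.0

    def __post_init__(self):
        if self.q <= 0:
            raise ValueError("q must be > 0")

    def value(self, p) -> float:
        p = _probs(p)
        if abs(self.q - 1.0) < _SINGULAR_TOL:
            return ShannonExtropy(self.base).value(p)
        K = p.size
        inner = np.sum((1.0 - p) ** self.q) - (K - 2)
        if inner <= 0:
            raise ValueError(f"Renyi extropy undefined for q={self.q} on this PMF")
        return float(np.log(inner) / (1.0 - self.q) / math.log(self.base))


@dataclass(frozen=True)
class TsallisExtropy(InformationMeasure):
    """q-analog of the Shannon extropy in Tsallis form.

    J_q = (K - 1 - Σ (1 - p_i)^q) / (q - 1); Shannon extropy (nats) as
    q -> 1, zero on degenerate PMFs.
    """

    q: float = 2.0

    def __post_init__(self):
        if self.q <= 0:
            raise ValueError("q must be > 0")

    def value(self, p) -> float:
        p = _probs(p)
        if abs(self.q - 1.0) < _SINGULAR_TOL:
            comp = 1.0 - p
            nz = comp[comp > 0]
            return float(-(nz * np.log(nz)).sum())
        K = p.size
        return float((K - 1 - np.sum((1.0 - p) ** self.q)) / (self.q - 1.0))


@dataclass(frozen=True)
class FluctuationComplexity(InformationMeasure):
    """Standard deviation of the information content around its mean.

    sqrt(Σ p_i (I_i - H)^2) with I_i = -log_b p_i and H the Shannon value.
    Zero for uniform *and* degenerate PMFs, so it has no uniform-PMF
    maximum and cannot be normalized.
    """

    base: float = 2.0

    def value(self, p) -> float:
        p = _probs(p)
        nz = p[p > 0]
        info = -np.log(nz) / math.log(self.base)
        h = float((nz * info).sum())
        return float(np.sqrt(np.sum(nz * (info - h) ** 2)))

    def maximum(self, K: int) -> float:
        raise UnsupportedOperationError(
            "fluctuation complexity is zero at the uniform PMF; "
            "it has no normalizing maximum"
        )


def evaluate_measure(measure: InformationMeasure, p) -> float:
    """Evaluate a measure definition on a PMF."""
    return measure.value(p)


def measure_maximum(measure: InformationMeasure, K: int) -> float:
    """Maximum possible value of the measure over K-outcome PMFs."""
    return measure.maximum(K)


def normalized_value(measure: InformationMeasure, p, K: int) -> float:
    """evaluate_measure / measure_maximum; 1 at uniform, 0 at degenerate
    PMFs for entropy-type measures."""
    mx = measure.maximum(K)
    if mx <= 0:
        raise ValueError(f"measure maximum {mx} is not positive for K={K}")
    return measure.value(p) / mx
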