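"""Complexity measures that are not plain functionals of a PMF.

Sample/approximate entropy are entropy *rates* computed from template
matches; Lempel–Ziv 76 counts production phrases; missing/reverse
dispersion and statistical complexity are PMF-shape statistics; bubble
entropy is a scaled difference of two Rényi entropies of swap-count
distributions.  A generic multiscale wrapper applies any of these (or any
discrete pipeline) across coarse-grained copies of the series.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import UnsupportedOperationError, as_series
from .measures import InformationMeasure, Renyi, Shannon, normalized_value
from .outcome_spaces import (
    BubbleSortSwaps,
    Dispersion,
    OutcomeSpace,
    delay_embed,
    missing_outcomes,
)
from .probabilities import RelativeAmount, all_probabilities, estimate_pmf

__all__ = [
    "ApproximateEntropy",
    "SampleEntropy",
    "LempelZiv76",
    "MissingDispersionPatterns",
    "ReverseDispersion",
    "StatisticalComplexity",
    "BubbleEntropy",
    "approximate_entropy",
    "sample_entropy",
    "lempel_ziv_76",
    "missing_dispersion_patterns",
    "reverse_dispersion",
    "statistical_complexity",
    "bubble_entropy",
    "complexity",
    "complexity_normalized",
    "coarse_grain",
    "moving_average",
    "multiscale",
]


def _radius(x: np.ndarray, r: float | None) -> float:
    """Default tolerance r = 0.2 * std of the *original* series."""
    if r is None:
        r = 0.2 * float(np.std(x))
    if r <= 0:
        raise ValueError("tolerance r must be > 0")
    return r


def _chebyshev_ball_counts(points: np.ndarray, r: float) -> np.ndarray:
    """Number of points (self included) within Chebyshev distance r."""
    tree = cKDTree(points)
    return np.asarray(
        tree.query_ball_point(points, r, p=np.inf, return_length=True)
    )


def approximate_entropy(x, m: int = 2, r: float | None = None, tau: int = 1) -> float:
    """Approximate entropy: Φ^m - Φ^{m+1} with Φ^m the mean log fraction of
    windows within Chebyshev distance r (self-matches included)."""
    x = as_series(x)
    r = _radius(x, r)
    if x.size <= m * tau + 1:
        raise ValueError(f"series too short for ApEn with m={m}, tau={tau}")

    def phi(dim):
        pts = delay_embed(x, dim, tau)
        counts = _chebyshev_ball_counts(pts, r)
        return float(np.mean(np.log(counts / pts.shape[0])))

    return phi(m) - phi(m + 1)


def sample_entropy(x, m: int = 2, r: float | None = None, tau: int = 1) -> float:
    """Sample entropy: -log(A/B) over matched templates, self-matches
    excluded.

    B counts pairs within r at dimension m, A at m+1; both dimensions use
    the same template index set (the first N - m*tau windows).  Returns
    +inf with a warning when no matches exist at either dimension.
    """
    x = as_series(x)
    r = _radius(x, r)
    n_templates = x.size - m * tau
    if n_templates < 2:
        raise ValueError(f"series too short for SampEn with m={m}, tau={tau}")

    def pairs(dim):
        pts = delay_embed(x, dim, tau)[:n_templates]
        tree = cKDTree(pts)
        return len(tree.query_pairs(r, p=np.inf))

    B = pairs(m)
    A = pairs(m + 1)
    if A == 0 or B == 0:
        warnings.warn(
            "sample entropy undefined (no template matches at one "
            "dimension); returning +inf",
            RuntimeWarning,
            stacklevel=2,
        )
        return math.inf
    return -math.log(A / B)


def _binarize(x, rule) -> np.ndarray:
    arr = np.asarray(x)
    if arr.dtype.kind in "iub" and set(np.unique(arr)) <= {0, 1}:
        return arr.astype(np.int8)
    if rule == "median":
        xs = as_series(arr)
        return (xs > np.median(xs)).astype(np.int8)
    raise ValueError(f"unknown binarization rule {rule!r}")


def lempel_ziv_76(x, binarization: str = "median") -> int:
    """Number of phrases in the exhaustive LZ76 production parsing.

    Real-valued series are binarized at their median; 0/1 symbol
    sequences (or strings) are parsed directly.
    """
    if isinstance(x, str):
        s = np.array([int(ch) for ch in x], dtype=np.int8)
    else:
        s = _binarize(x, binarization)
    n = s.size
    if n == 0:
        raise ValueError("empty sequence")
    if n == 1:
        return 1
    # Kaspar-Schuster scan
    c, l, i, k, kmax = 1, 1, 0, 1, 1
    while True:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            if k > kmax:
                kmax = k
            i += 1
            if i == l:
                c += 1
                l += kmax
                if l + 1 > n:
                    break
                i, k, kmax = 0, 1, 1
            else:
                k = 1
    return c


def missing_dispersion_patterns(x, c: int = 5, m: int = 2, tau: int = 1) -> int:
    """Number of possible-but-unobserved dispersion patterns (of c^m)."""
    return missing_outcomes(Dispersion(c=c, m=m, tau=tau), x)


def reverse_dispersion(x, c: int = 5, m: int = 2, tau: int = 1) -> float:
    """Squared distance of the dispersion PMF from uniformity:
    Σ (p_i - 1/K)^2 over the full support, K = c^m."""
    space = Dispersion(c=c, m=m, tau=tau)
    pmf = all_probabilities(x, space)
    K = space.cardinality()
    return float(np.sum((pmf.probs - 1.0 / K) ** 2))


def _js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence (nats)."""
    def h(v):
        nz = v[v > 0]
        return float(-(nz * np.log(nz)).sum())
    mix = 0.5 * (p + q)
    return h(mix) - 0.5 * (h(p) + h(q))


def statistical_complexity(x, ospace: OutcomeSpace, measure: InformationMeasure = None,
                           prob_est=None) -> tuple[float, float]:
    """Generalized statistical complexity on the complexity-entropy plane.

    Returns ``(H_norm, C)`` where H_norm is the normalized measure over
    the full support and C = Q_J * H_norm, with Q_J the Jensen-Shannon
    divergence of the PMF from the uniform PMF, normalized by its maximum
    (attained between a point mass and the uniform PMF).  C vanishes at
    both perfect order (degenerate PMF) and perfect disorder (uniform).
    """
    measure = Shannon() if measure is None else measure
    prob_est = RelativeAmount() if prob_est is None else prob_est
    K = ospace.cardinality()
    if K is None:
        raise UnsupportedOperationError(
            f"{type(ospace).__name__} has data-dependent cardinality"
        )
    pmf = all_probabilities(x, ospace, prob_est)
    h_norm = normalized_value(measure, pmf.probs, K)
    uniform = np.full(K, 1.0 / K)
    degenerate = np.zeros(K)
    degenerate[0] = 1.0
    q_max = _js_divergence(degenerate, uniform)
    q_j = _js_divergence(pmf.probs, uniform) / q_max
    return float(h_norm), float(q_j * h_norm)


def bubble_entropy(x, m: int = 3, tau: int = 1) -> float:
    """Scaled difference of Rényi-2 entropies of bubble-sort swap counts:
    (H2(m+1) - H2(m)) / log((m+1)/(m-1)), natural log, unnormalized."""
    if m < 2:
        raise ValueError("bubble entropy requires m >= 2")

    def h2(dim):
        pmf = estimate_pmf(BubbleSortSwaps(m=dim, tau=tau).counts(x))
        return Renyi(q=2.0, base=math.e).value(pmf.probs)

    return (h2(m + 1) - h2(m)) / math.log((m + 1) / (m - 1))


# ---------------------------------------------------------------------------
# estimator specs + the two-function surface
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ApproximateEntropy:
    m: int = 2
    r: float | None = None
    tau: int = 1

    def compute(self, x) -> float:
        return approximate_entropy(x, self.m, self.r, self.tau)


@dataclass(frozen=True)
class SampleEntropy:
    m: int = 2
    r: float | None = None
    tau: int = 1

    def compute(self, x) -> float:
        return sample_entropy(x, self.m, self.r, self.tau)


@dataclass(frozen=True)
class LempelZiv76:
    binarization: str = "median"

    def compute(self, x) -> float:
        return float(lempel_ziv_76(x, self.binarization))

    def maximum(self, x) -> float:
        # asymptotic upper bound n / log2(n) for a binary alphabet
        n = len(np.asarray(x).ravel())
        return n / math.log2(n) if n > 1 else 1.0


@dataclass(frozen=True)
class MissingDispersionPatterns:
    c: int = 5
    m: int = 2
    tau: int = 1

    def compute(self, x) -> float:
        return float(missing_dispersion_patterns(x, self.c, self.m, self.tau))

    def maximum(self, x) -> float:
        return float(self.c ** self.m)


@dataclass(frozen=True)
class ReverseDispersion:
    c: int = 5
    m: int = 2
    tau: int = 1

    def compute(self, x) -> float:
        return reverse_dispersion(x, self.c, self.m, self.tau)

    def maximum(self, x) -> float:
        return 1.0 - 1.0 / self.c ** self.m


@dataclass(frozen=True)
class StatisticalComplexity:
    ospace: OutcomeSpace = None
    measure: InformationMeasure = field(default_factory=Shannon)

    def _space(self):
        from .outcome_spaces import OrdinalPatterns
        return self.ospace if self.ospace is not None else OrdinalPatterns(m=3)

    def compute(self, x) -> float:
        return statistical_complexity(x, self._space(), self.measure)[1]


@dataclass(frozen=True)
class BubbleEntropy:
    m: int = 3
    tau: int = 1

    def compute(self, x) -> float:
        return bubble_entropy(x, self.m, self.tau)


def complexity(est, x) -> float:
    """Evaluate a non-PMF complexity estimator on a series."""
    if not hasattr(est, "compute"):
        raise TypeError(f"{est!r} is not a complexity estimator")
    return est.compute(x)


def complexity_normalized(est, x) -> float:
    """Complexity divided by its maximum possible value, where one exists
    (missing/reverse dispersion, LZ76, statistical complexity)."""
    if isinstance(est, StatisticalComplexity):
        return est.compute(x)  # C is already built from normalized parts
    if hasattr(est, "maximum"):
        return est.compute(x) / est.maximum(x)
    raise UnsupportedOperationError(
        f"{type(est).__name__} has no finite maximum; normalization undefined"
    )


# ---------------------------------------------------------------------------
# multiscale wrapper
# ---------------------------------------------------------------------------

def coarse_grain(x, s: int) -> np.ndarray:
    """Non-overlapping window means of length s (length floor(N/s))."""
    x = as_series(x)
    if s < 1:
        raise ValueError("scale must be >= 1")
    n = x.size // s
    if n < 1:
        raise ValueError(f"series of length {x.size} too short at scale {s}")
    return x[: n * s].reshape(n, s).mean(axis=1)


def moving_average(x, s: int) -> np.ndarray:
    """Sliding mean of width s (length N - s + 1)."""
    x = as_series(x)
    if s < 1:
        raise ValueError("scale must be >= 1")
    if x.size < s:
        raise ValueError(f"series of length {x.size} too short at scale {s}")
    return np.convolve(x, np.full(s, 1.0 / s), mode="valid")


def _as_callable(spec):
    if callable(spec) and not hasattr(spec, "compute") and not hasattr(spec, "run"):
        return spec
    if hasattr(spec, "compute"):
        return spec.compute
    if hasattr(spec, "run"):
        return spec.run
    raise TypeError(f"cannot evaluate {spec!r} on a series")


def multiscale(spec, x, scales, scheme: str = "coarse_grain") -> np.ndarray:
    """Evaluate a measure across timescales.

    ``spec`` may be a callable ``series -> float``, a complexity estimator,
    or a discrete :class:`~entrospect.discrete.Pipeline`.  ``scales`` is an
    iterable of integers (or an int S meaning 1..S); scale 1 reproduces the
    base measure exactly.
    """
    if scheme not in ("coarse_grain", "moving_average"):
        raise ValueError("scheme must be 'coarse_grain' or 'moving_average'")
    fn = _as_callable(spec)
    reducer = coarse_grain if scheme == "coarse_grain" else moving_average
    if isinstance(scales, (int, np.integer)):
        scales = range(1, int(scales) + 1)
    return np.array([fn(x) if s == 1 else fn(reducer(x, int(s))) for s in scales])
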