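"""Differential (continuous) entropy estimators.

Two families are implemented, neither of which builds an explicit density:

* spacing estimators (Vasicek, Ebrahimi, Correa, Alizadeh–Arghami) use
  gaps between order statistics of a univariate sample;
* nearest-neighbor estimators (Kozachenko–Leonenko, Kraskov,
  Leonenko–Prozanto–Savani) use k-th-neighbor distances in d dimensions,
  searched with a KD-tree.

All estimators return nats by default; pass ``base`` to convert.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma, gammaln

from .core import as_series, as_state_space

__all__ = [
    "Vasicek",
    "Ebrahimi",
    "Correa",
    "AlizadehArghami",
    "KozachenkoLeonenko",
    "Kraskov",
    "LeonenkoProzantoSavani",
    "estimate_differential",
]


@dataclass(frozen=True)
class Vasicek:
    """Spacing estimator: mean of log(N/(2w) (X_(i+w) - X_(i-w))).

    Order statistics are clamped at the boundaries (X_(i) := X_(1) for
    i < 1, X_(N) for i > N).  Default window w = floor(sqrt(N)).
    """

    w: int | None = None


@dataclass(frozen=True)
class Ebrahimi:
    """Vasicek with boundary-corrected coefficients c_i.

    c_i = 1 + (i-1)/w for i <= w, 1 + (N-i)/w for i >= N-w+1, else 2
    (Ebrahimi, Pflughoeft & Soofi 1994).
    """

    w: int | None = None


@dataclass(frozen=True)
class Correa:
    """Local linear-regression spacing estimator (Correa 1995).

    H = -(1/N) Σ log( Σ_j (X_(j) - mean_i)(j - i) / (N Σ_j (X_(j) - mean_i)^2) )
    with j running over the clamped window i-w..i+w.
    """

    w: int | None = None


@dataclass(frozen=True)
class AlizadehArghami:
    """Vasicek variant with boundary coefficient 1 instead of 2
    (Alizadeh Noughabi & Arghami 2010)."""

    w: int | None = None


@dataclass(frozen=True)
class KozachenkoLeonenko:
    """First-nearest-neighbor estimator; identical to Kraskov with k = 1."""

    metric: str = "euclidean"


@dataclass(frozen=True)
class Kraskov:
    """k-th-nearest-neighbor Shannon estimator:
    H = ψ(N) - ψ(k) + log V_d + (d/N) Σ log ρ_{i,k}."""

    k: int = 3
    metric: str = "euclidean"


@dataclass(frozen=True)
class LeonenkoProzantoSavani:
    """kNN estimator of Σ p^q: Rényi or Tsallis entropy for q != 1, the
    Shannon entropy in the q -> 1 limit."""

    k: int = 3
    q: float = 1.0
    measure: str = "shannon"  # 'shannon' | 'renyi' | 'tsallis'
    metric: str = "euclidean"


_SPACING = (Vasicek, Ebrahimi, Correa, AlizadehArghami)
_NEIGHBOR = (KozachenkoLeonenko, Kraskov, LeonenkoProzantoSavani)


def _log_unit_ball(d: int, metric: str) -> float:
    if metric == "euclidean":
        return d / 2 * math.log(math.pi) - gammaln(d / 2 + 1)
    if metric == "chebyshev":
        return d * math.log(2.0)
    raise ValueError("metric must be 'euclidean' or 'chebyshev'")


def _window(w, N: int) -> int:
    if w is None:
        w = int(math.floor(math.sqrt(N)))
    if not 1 <= w <= N // 2:
        raise ValueError(f"spacing window w={w} must satisfy 1 <= w <= N/2")
    return w


def _knn_radii(pts: np.ndarray, k: int, metric: str) -> np.ndarray:
    """Distance to the k-th nearest neighbor of each point, self excluded."""
    N = pts.shape[0]
    if k >= N:
        raise ValueError(f"k={k} must be smaller than the sample size {N}")
    tree = cKDTree(pts)
    p = np.inf if metric == "chebyshev" else 2
    dists, _ = tree.query(pts, k=k + 1, p=p)
    return dists[:, -1]


def _log_radii(rho: np.ndarray) -> np.ndarray:
    """Log of neighbor radii; zero distances (duplicate points) are dropped
    from the log-sum with a warning."""
    nz = rho > 0
    if not np.all(nz):
        warnings.warn(
            f"{int((~nz).sum())} duplicate points give zero neighbor "
            "distance; dropping them from the log-sum (consider adding "
            "tiny jitter to the data)",
            RuntimeWarning,
            stacklevel=3,
        )
        rho = rho[nz]
        if rho.size == 0:
            raise ValueError("all neighbor distances are zero; data is degenerate")
    return np.log(rho)


def _spacing_gaps(xs: np.ndarray, w: int) -> np.ndarray:
    N = xs.size
    i = np.arange(N)
    hi = np.minimum(i + w, N - 1)
    lo = np.maximum(i - w, 0)
    return xs[hi] - xs[lo]


def _vasicek(xs, w):
    N = xs.size
    gaps = _spacing_gaps(xs, w)
    if np.any(gaps <= 0):
        raise ValueError("tied order statistics give zero spacing; add jitter")
    return float(np.mean(np.log(N / (2 * w) * gaps)))


def _ebrahimi(xs, w):
    N = xs.size
    i = np.arange(1, N + 1)
    c = np.full(N, 2.0)
    left = i <= w
    right = i >= N - w + 1
    c[left] = 1.0 + (i[left] - 1) / w
    c[right] = 1.0 + (N - i[right]) / w
    gaps = _spacing_gaps(xs, w)
    if np.any(gaps <= 0):
        raise ValueError("tied order statistics give zero spacing; add jitter")
    return float(np.mean(np.log(N / (c * w) * gaps)))


def _alizadeh_arghami(xs, w):
    N = xs.size
    i = np.arange(1, N + 1)
    c = np.full(N, 2.0)
    c[(i <= w) | (i >= N - w + 1)] = 1.0
    gaps = _spacing_gaps(xs, w)
    if np.any(gaps <= 0):
        raise ValueError("tied order statistics give zero spacing; add jitter")
    return float(np.mean(np.log(N / (c * w) * gaps)))


def _correa(xs, w):
    N = xs.size
    total = 0.0
    for i in range(N):
        lo = max(i - w, 0)
        hi = min(i + w, N - 1)
        win = xs[lo:hi + 1]
        j = np.arange(lo, hi + 1)
        xbar = win.mean()
        num = np.sum((win - xbar) * (j - i))
        den = N * np.sum((win - xbar) ** 2)
        if num <= 0 or den <= 0:
            raise ValueError("degenerate local regression (tied values); add jitter")
        total += math.log(num / den)
    return -total / N


def _kraskov(pts, k, metric):
    N, d = pts.shape
    rho = _knn_radii(pts, k, metric)
    logs = _log_radii(rho)
    return float(digamma(N) - digamma(k) + _log_unit_ball(d, metric)
                 + d * logs.mean())


def _lps(pts, k, q, measure, metric):
    N, d = pts.shape
    rho = _knn_radii(pts, k, metric)
    log_vd = _log_unit_ball(d, metric)
    if measure == "shannon" or abs(q - 1.0) < 1e-12:
        logs = _log_radii(rho)
        h = math.log(N - 1) - digamma(k) + log_vd + d * logs.mean()
        if measure == "renyi" or measure == "shannon":
            return float(h)
        return float(h)  # Tsallis -> Shannon in the q -> 1 limit (k = 1 scale)
    if k + 1 - q <= 0:
        raise ValueError(f"LPS requires k + 1 - q > 0 (k={k}, q={q})")
    logs = _log_radii(rho)
    # I_hat estimates the integral of f^q
    log_ck = (gammaln(k) - gammaln(k + 1 - q)) / (1.0 - q)
    log_zeta = math.log(N - 1) + log_ck + log_vd + d * logs
    i_hat = float(np.mean(np.exp((1.0 - q) * log_zeta)))
    if measure == "renyi":
        return math.log(i_hat) / (1.0 - q)
    if measure == "tsallis":
        return (1.0 - i_hat) / (q - 1.0)
    raise ValueError("measure must be 'shannon', 'renyi' or 'tsallis'")


def estimate_differential(est, x, base: float | None = None) -> float:
    """Estimate a differential information measure from raw samples.

    Spacing estimators accept 1-D samples only; neighbor estimators accept
    1-D series or (N, d) point sets.  Returns nats unless ``base`` is given.
    """
    if isinstance(est, _SPACING):
        xs = np.sort(as_series(x))
        w = _window(est.w, xs.size)
        if xs.size < 2 * w + 1:
            raise ValueError(f"need at least {2 * w + 1} samples for window w={w}")
        fn = {Vasicek: _vasicek, Ebrahimi: _ebrahimi,
              Correa: _correa, AlizadehArghami: _alizadeh_arghami}[type(est)]
        h = fn(xs, w)
    elif isinstance(est, _NEIGHBOR):
        pts = as_state_space(x)
        if isinstance(est, KozachenkoLeonenko):
            h = _kraskov(pts, 1, est.metric)
        elif isinstance(est, Kraskov):
            if est.k < 1:
                raise ValueError("k must be >= 1")
            h = _kraskov(pts, est.k, est.metric)
        else:
            h = _lps(pts, est.k, est.q, est.measure, est.metric)
    else:
        raise TypeError(f"unknown differential estimator {est!r}")
    if base is not None:
        h /= math.log(base)
    return float(h)
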