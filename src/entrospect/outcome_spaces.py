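"""Outcome spaces: rules that discretize data into countable outcomes.

An outcome space pairs a finite (or data-dependent) set of symbols with a
rule mapping raw data windows onto them.  Permutation entropy, dispersion
entropy, spectral entropy etc. all reduce to "pick an outcome space, count
outcomes, estimate probabilities, evaluate a measure"; this module supplies
the first two steps.

All spaces share the interface

* ``counts(data)``     -- encode the data and tally outcome frequencies,
* ``cardinality()``    -- |Ω|, or ``None`` when data-dependent,
* ``outcomes()``       -- canonical enumeration of Ω (finite spaces only),
* ``is_count_based``   -- False for spaces yielding real weights instead of
  integer window counts.
"""
from __future__ import annotations

import itertools
import math
from abc import ABC, abstractmethod
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal
from scipy.stats import norm as _norm

from .core import (
    Counts,
    UnsupportedOperationError,
    as_matrix,
    as_series,
    as_state_space,
)

__all__ = [
    "OutcomeSpace",
    "UniqueElements",
    "ValueBinning",
    "OrdinalPatterns",
    "WeightedOrdinalPatterns",
    "AmplitudeAwareOrdinalPatterns",
    "Dispersion",
    "CosineSimilarityBinning",
    "BubbleSortSwaps",
    "SequentialPairDistances",
    "PowerSpectrum",
    "Stencil",
    "SpatialOrdinalPatterns",
    "SpatialDispersion",
    "delay_embed",
    "encode_ordinal",
    "decode_ordinal",
    "sparse_joint_histogram",
    "discretize",
    "missing_outcomes",
]

# Canonical enumerations are materialized on the counts table only up to
# this cardinality; above it, use OutcomeSpace.outcomes() explicitly.
_MAX_MATERIALIZED = 100_000


# ---------------------------------------------------------------------------
# embeddings and ordinal encodings
# ---------------------------------------------------------------------------

def delay_embed(x, m: int, tau: int) -> np.ndarray:
    """Delay-coordinate embedding of a univariate series.

    Returns the ``N - (m-1)*tau`` vectors ``(x_i, x_{i+tau}, ...,
    x_{i+(m-1)tau})`` as an (n, m) array.
    """
    x = as_series(x)
    if m < 1 or tau < 1:
        raise ValueError("embedding dimension m and delay tau must be >= 1")
    need = (m - 1) * tau + 1
    n = x.size - (m - 1) * tau
    if n < 1:
        raise ValueError(
            f"series of length {x.size} too short for (m={m}, tau={tau}) "
            f"embedding; need at least {need} points"
        )
    idx = np.arange(n)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


def _lehmer_ranks(perms: np.ndarray) -> np.ndarray:
    """Lehmer-code ranks of an (n, d) array of permutations of 0..d-1."""
    n, d = perms.shape
    ranks = np.zeros(n, dtype=np.int64)
    for i in range(d - 1):
        smaller_after = (perms[:, i + 1:] < perms[:, [i]]).sum(axis=1)
        ranks += smaller_after * math.factorial(d - 1 - i)
    return ranks


def encode_ordinal(v) -> int:
    """Lehmer-code rank of the permutation that sorts ``v`` ascending.

    Ties are broken by original index order (stable sort), so equal values
    keep their temporal ordering.  The rank lies in ``[0, d!-1]``; the
    identity permutation (strictly increasing window) has rank 0.
    """
    v = np.atleast_2d(np.asarray(v, dtype=float))
    perms = np.argsort(v, axis=1, kind="stable")
    ranks = _lehmer_ranks(perms)
    return int(ranks[0]) if ranks.size == 1 else ranks


def decode_ordinal(k: int, d: int) -> tuple:
    """Inverse of :func:`encode_ordinal`: rank -> permutation of 0..d-1."""
    if d < 1:
        raise ValueError("d must be >= 1")
    if not 0 <= k < math.factorial(d):
        raise ValueError(f"rank {k} outside [0, {d}!-1]")
    digits = []
    for i in range(d - 1, -1, -1):
        f = math.factorial(i)
        digits.append(k // f)
        k %= f
    avail = list(range(d))
    return tuple(avail.pop(c) for c in digits)


# ---------------------------------------------------------------------------
# sparse joint histogram
# ---------------------------------------------------------------------------

def sparse_joint_histogram(points, n_bins: int | None = None, edges=None) -> Counts:
    """Joint histogram of d-dimensional points storing only occupied bins.

    Counts are identical to a dense D-dimensional histogram, but memory is
    proportional to the number of *occupied* bins (at most N), never to the
    product of per-dimension bin counts — a 30-D binning with 2 bins per
    dimension never allocates 2^30 cells.

    Parameters
    ----------
    n_bins
        Equal-width bins per dimension, derived from the data's min/max.
        Bins are half-open ``[lo, hi)``; the global maximum is assigned to
        the top bin.
    edges
        Explicit bin edges: one ascending array per dimension (overrides
        ``n_bins``).  Points outside the edges raise.
    """
    pts = as_state_space(points)
    n, d = pts.shape
    if edges is not None:
        edges = [np.asarray(e, dtype=float) for e in edges]
        if len(edges) != d:
            raise ValueError(f"need {d} edge arrays, got {len(edges)}")
        idx = np.empty((n, d), dtype=np.int64)
        for j, e in enumerate(edges):
            if e.size < 2 or np.any(np.diff(e) <= 0):
                raise ValueError("each edge array must be ascending with >= 2 entries")
            col = np.searchsorted(e, pts[:, j], side="right") - 1
            # the global maximum belongs to the last bin, not an orphan one
            col[pts[:, j] == e[-1]] = e.size - 2
            if np.any((col < 0) | (col > e.size - 2)):
                raise ValueError(f"points outside bin edges in dimension {j}")
            idx[:, j] = col
        total_possible = int(np.prod([e.size - 1 for e in edges]))
    else:
        if n_bins is None or n_bins < 1:
            raise ValueError("n_bins must be a positive integer")
        lo = pts.min(axis=0)
        hi = pts.max(axis=0)
        width = (hi - lo) / n_bins
        idx = np.zeros((n, d), dtype=np.int64)
        nz = width > 0
        if np.any(nz):
            idx[:, nz] = np.floor((pts[:, nz] - lo[nz]) / width[nz]).astype(np.int64)
        np.clip(idx, 0, n_bins - 1, out=idx)  # max value into the top bin
        total_possible = None  # edges are data-derived
    uniq, cts = np.unique(idx, axis=0, return_counts=True)
    if d == 1:
        outcomes = [int(r[0]) for r in uniq]
    else:
        outcomes = [tuple(int(v) for v in r) for r in uniq]
    return Counts(outcomes, cts, total_possible=total_possible)


# ---------------------------------------------------------------------------
# outcome-space hierarchy
# ---------------------------------------------------------------------------

class OutcomeSpace(ABC):
    """Base class for discretization rules."""

    is_count_based: bool = True

    @abstractmethod
    def counts(self, data) -> Counts:
        """Encode ``data`` and tally the frequency of each outcome."""

    def cardinality(self) -> int | None:
        """|Ω| when computable from parameters alone, else ``None``."""
        return None

    def outcomes(self) -> list:
        """Canonical enumeration of Ω for finite spaces."""
        raise UnsupportedOperationError(
            f"{type(self).__name__} has a data-dependent outcome space"
        )

    def _finalize(self, outcomes, values, *, is_count=True) -> Counts:
        K = self.cardinality()
        all_out = None
        if K is not None and K <= _MAX_MATERIALIZED:
            all_out = self.outcomes()
        return Counts(outcomes, values, total_possible=K, is_count=is_count,
                      all_outcomes=all_out)


class UniqueElements(OutcomeSpace):
    """Each distinct value of the series is its own outcome."""

    def counts(self, data) -> Counts:
        x = as_series(data)
        vals, cts = np.unique(x, return_counts=True)
        return Counts(list(vals), cts, total_possible=None)


@dataclass
class ValueBinning(OutcomeSpace):
    """Rectangular (histogram) binning of values or embedding vectors.

    By default bins are equal-width per dimension, derived from the data's
    min/max (data-dependent cardinality); explicit ``edges`` override and
    make the cardinality finite.
    """

    n_bins: int | None = 10
    edges: list | None = None

    def cardinality(self) -> int | None:
        if self.edges is not None:
            return int(np.prod([len(e) - 1 for e in self.edges]))
        return None

    def outcomes(self) -> list:
        if self.edges is None:
            return super().outcomes()
        ranges = [range(len(e) - 1) for e in self.edges]
        if len(ranges) == 1:
            return list(ranges[0])
        return [tuple(t) for t in itertools.product(*ranges)]

    def counts(self, data) -> Counts:
        pts = as_state_space(data)
        ct = sparse_joint_histogram(pts, n_bins=self.n_bins, edges=self.edges)
        K = self.cardinality()
        all_out = None
        if K is not None and K <= _MAX_MATERIALIZED:
            all_out = self.outcomes()
        return Counts(ct.outcomes, ct.values, total_possible=K, all_outcomes=all_out)


@dataclass
class OrdinalPatterns(OutcomeSpace):
    """Ordinal (permutation) patterns of delay-embedding windows.

    Each m-window maps to the permutation that sorts it ascending,
    Lehmer-encoded to an integer in [0, m!-1].  |Ω| = m!.
    """

    m: int = 3
    tau: int = 1

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("ordinal patterns require m >= 2")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")

    def cardinality(self) -> int:
        return math.factorial(self.m)

    def outcomes(self) -> list:
        return [decode_ordinal(k, self.m) for k in range(self.cardinality())]

    def _ranks(self, data) -> np.ndarray:
        emb = delay_embed(data, self.m, self.tau)
        return _lehmer_ranks(np.argsort(emb, axis=1, kind="stable"))

    def counts(self, data) -> Counts:
        ranks = self._ranks(data)
        uniq, cts = np.unique(ranks, return_counts=True)
        outcomes = [decode_ordinal(int(r), self.m) for r in uniq]
        return self._finalize(outcomes, cts)


@dataclass
class WeightedOrdinalPatterns(OrdinalPatterns):
    """Ordinal patterns where each window contributes its variance as weight.

    This is the weighted-permutation-entropy convention: windows with large
    amplitude fluctuations dominate the distribution.  Yields real weights,
    so only relative-amount probabilities apply.
    """

    is_count_based = False

    def counts(self, data) -> Counts:
        emb = delay_embed(data, self.m, self.tau)
        ranks = _lehmer_ranks(np.argsort(emb, axis=1, kind="stable"))
        weights = emb.var(axis=1)
        agg = np.bincount(ranks, weights=weights, minlength=self.cardinality())
        uniq = np.nonzero(agg)[0]
        # a zero-variance (constant) window carries zero weight; keep its
        # pattern observed so window conservation still holds for counts>0
        if uniq.size == 0:
            uniq = np.unique(ranks)
            agg = agg.astype(float)
            agg[uniq] = 0.0
        outcomes = [decode_ordinal(int(r), self.m) for r in uniq]
        return self._finalize(outcomes, agg[uniq], is_count=False)


@dataclass
class AmplitudeAwareOrdinalPatterns(OrdinalPatterns):
    """Ordinal patterns weighted by a blend of amplitude and variation.

    Window weight = A * mean(|x|) + (1-A) * mean(|adjacent differences|),
    blend A in [0, 1] (default 0.5).
    """

    A: float = 0.5
    is_count_based = False

    def __post_init__(self):
        super().__post_init__()
        if not 0.0 <= self.A <= 1.0:
            raise ValueError("blend A must lie in [0, 1]")

    def counts(self, data) -> Counts:
        emb = delay_embed(data, self.m, self.tau)
        ranks = _lehmer_ranks(np.argsort(emb, axis=1, kind="stable"))
        amp = np.abs(emb).sum(axis=1) / self.m
        diff = np.abs(np.diff(emb, axis=1)).sum(axis=1) / (self.m - 1)
        weights = self.A * amp + (1.0 - self.A) * diff
        agg = np.bincount(ranks, weights=weights, minlength=self.cardinality())
        uniq = np.nonzero(agg)[0]
        if uniq.size == 0:
            uniq = np.unique(ranks)
        outcomes = [decode_ordinal(int(r), self.m) for r in uniq]
        return self._finalize(outcomes, agg[uniq], is_count=False)


@dataclass
class Dispersion(OutcomeSpace):
    """Dispersion patterns: Gaussian-CDF quantization into c categories.

    Each value maps to category ``clamp(ceil(c * Phi(x)), 1, c)`` where Phi
    is the normal CDF with the series' empirical mean and (population)
    standard deviation; categories are then delay-embedded into m-tuples.
    |Ω| = c^m.
    """

    c: int = 5
    m: int = 2
    tau: int = 1

    def __post_init__(self):
        if self.c < 2:
            raise ValueError("dispersion requires c >= 2 categories")
        if self.m < 1 or self.tau < 1:
            raise ValueError("m and tau must be >= 1")

    def cardinality(self) -> int:
        return self.c ** self.m

    def outcomes(self) -> list:
        return [tuple(t) for t in
                itertools.product(range(1, self.c + 1), repeat=self.m)]

    def categories(self, data) -> np.ndarray:
        """Map a series to integer categories in {1..c}."""
        x = as_series(data)
        sd = x.std()  # population (uncorrected) standard deviation
        if sd == 0:
            phi = np.full(x.shape, 0.5)
        else:
            phi = _norm.cdf(x, loc=x.mean(), scale=sd)
        z = np.ceil(self.c * phi).astype(np.int64)
        return np.clip(z, 1, self.c)

    def counts(self, data) -> Counts:
        z = self.categories(data)
        emb = delay_embed(z.astype(float), self.m, self.tau).astype(np.int64)
        # base-c integer code, first element most significant
        powers = self.c ** np.arange(self.m - 1, -1, -1)
        codes = ((emb - 1) * powers).sum(axis=1)
        uniq, cts = np.unique(codes, return_counts=True)
        outcomes = [self._decode(int(k)) for k in uniq]
        return self._finalize(outcomes, cts)

    def _decode(self, code: int) -> tuple:
        digits = []
        for _ in range(self.m):
            digits.append(code % self.c + 1)
            code //= self.c
        return tuple(reversed(digits))


@dataclass
class CosineSimilarityBinning(OutcomeSpace):
    """Binned cosine similarities of consecutive embedding vectors.

    Similarities lie in [-1, 1] and are split into ``n_bins`` equal-width
    bins; |Ω| = n_bins.
    """

    m: int = 2
    tau: int = 1
    n_bins: int = 10

    def cardinality(self) -> int:
        return self.n_bins

    def outcomes(self) -> list:
        return list(range(self.n_bins))

    def counts(self, data) -> Counts:
        emb = delay_embed(data, self.m, self.tau)
        if emb.shape[0] < 2:
            raise ValueError("need at least two embedding vectors")
        a, b = emb[:-1], emb[1:]
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
        denom = na * nb
        sims = np.zeros(denom.shape)
        ok = denom > 0
        sims[ok] = (a[ok] * b[ok]).sum(axis=1) / denom[ok]
        np.clip(sims, -1.0, 1.0, out=sims)
        idx = np.floor((sims + 1.0) / 2.0 * self.n_bins).astype(np.int64)
        np.clip(idx, 0, self.n_bins - 1, out=idx)
        uniq, cts = np.unique(idx, return_counts=True)
        return self._finalize([int(i) for i in uniq], cts)


def _inversion_counts(emb: np.ndarray) -> np.ndarray:
    """Bubble-sort swap count (= number of inversions) per row."""
    n, m = emb.shape
    swaps = np.zeros(n, dtype=np.int64)
    for i in range(m - 1):
        swaps += (emb[:, i + 1:] < emb[:, [i]]).sum(axis=1)
    return swaps


@dataclass
class BubbleSortSwaps(OutcomeSpace):
    """Number of bubble-sort swaps needed to sort each embedding window.

    |Ω| = m(m-1)/2 + 1 (swap counts 0 .. m(m-1)/2).
    """

    m: int = 3
    tau: int = 1

    def cardinality(self) -> int:
        return self.m * (self.m - 1) // 2 + 1

    def outcomes(self) -> list:
        return list(range(self.cardinality()))

    def counts(self, data) -> Counts:
        emb = delay_embed(data, self.m, self.tau)
        swaps = _inversion_counts(emb)
        uniq, cts = np.unique(swaps, return_counts=True)
        return self._finalize([int(s) for s in uniq], cts)


@dataclass
class SequentialPairDistances(OutcomeSpace):
    """Binned distances between consecutive embedding vectors.

    Bin edges span the observed [min, max] of the distances with
    ``n_bins`` equal-width bins; |Ω| = n_bins.
    """

    m: int = 2
    tau: int = 1
    n_bins: int = 10
    metric: str = "chebyshev"

    def __post_init__(self):
        if self.metric not in ("chebyshev", "euclidean"):
            raise ValueError("metric must be 'chebyshev' or 'euclidean'")

    def cardinality(self) -> int:
        return self.n_bins

    def outcomes(self) -> list:
        return list(range(self.n_bins))

    def counts(self, data) -> Counts:
        emb = delay_embed(data, self.m, self.tau)
        if emb.shape[0] < 2:
            raise ValueError("need at least two embedding vectors")
        diff = emb[1:] - emb[:-1]
        if self.metric == "chebyshev":
            dists = np.abs(diff).max(axis=1)
        else:
            dists = np.linalg.norm(diff, axis=1)
        lo, hi = dists.min(), dists.max()
        if hi > lo:
            idx = np.floor((dists - lo) / (hi - lo) * self.n_bins).astype(np.int64)
            np.clip(idx, 0, self.n_bins - 1, out=idx)
        else:
            idx = np.zeros(dists.size, dtype=np.int64)
        uniq, cts = np.unique(idx, return_counts=True)
        return self._finalize([int(i) for i in uniq], cts)


class PowerSpectrum(OutcomeSpace):
    """Positive-frequency periodogram ordinates as weighted outcomes.

    The "outcome" at frequency f_j carries the periodogram power at f_j as
    weight; normalizing these weights and applying Shannon entropy yields
    the spectral entropy.  Not count-based; cardinality depends on N.
    """

    is_count_based = False

    def counts(self, data) -> Counts:
        x = as_series(data)
        freqs, pxx = _signal.periodogram(x, detrend=False)
        mask = freqs > 0
        return Counts(list(freqs[mask]), pxx[mask], total_possible=None,
                      is_count=False)


# ---------------------------------------------------------------------------
# spatial encodings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Stencil:
    """Local pixel arrangement: integer (row, col) offsets, first (0, 0)."""

    offsets: tuple

    def __post_init__(self):
        offs = tuple((int(r), int(c)) for r, c in self.offsets)
        object.__setattr__(self, "offsets", offs)
        if len(offs) < 2:
            raise ValueError("stencil needs at least 2 offsets")
        if len(set(offs)) != len(offs):
            raise ValueError("stencil offsets must be unique")
        if offs[0] != (0, 0):
            raise ValueError("first stencil offset must be (0, 0)")

    def __len__(self) -> int:
        return len(self.offsets)

    @classmethod
    def square(cls, k: int = 2) -> "Stencil":
        """A k-by-k square window in row-major order."""
        return cls(tuple((r, c) for r in range(k) for c in range(k)))


def _stencil_windows(img: np.ndarray, stencil: Stencil) -> np.ndarray:
    """Extract (n_anchors, L) pixel vectors at every in-bounds anchor."""
    rows, cols = img.shape
    drs = [o[0] for o in stencil.offsets]
    dcs = [o[1] for o in stencil.offsets]
    r_lo, r_hi = -min(drs), rows - 1 - max(drs)
    c_lo, c_hi = -min(dcs), cols - 1 - max(dcs)
    if r_hi < r_lo or c_hi < c_lo:
        raise ValueError("stencil does not fit inside the image")
    rs = np.arange(r_lo, r_hi + 1)
    cs = np.arange(c_lo, c_hi + 1)
    cols_list = [img[rs[:, None] + dr, cs[None, :] + dc].ravel()
                 for dr, dc in stencil.offsets]
    return np.stack(cols_list, axis=1)


@dataclass
class SpatialOrdinalPatterns(OutcomeSpace):
    """Ordinal patterns of pixel values under a sliding stencil; |Ω| = L!."""

    stencil: Stencil = Stencil.square(2)

    def cardinality(self) -> int:
        return math.factorial(len(self.stencil))

    def outcomes(self) -> list:
        L = len(self.stencil)
        return [decode_ordinal(k, L) for k in range(self.cardinality())]

    def counts(self, data) -> Counts:
        img = as_matrix(data)
        win = _stencil_windows(img, self.stencil)
        ranks = _lehmer_ranks(np.argsort(win, axis=1, kind="stable"))
        uniq, cts = np.unique(ranks, return_counts=True)
        L = len(self.stencil)
        outcomes = [decode_ordinal(int(r), L) for r in uniq]
        return self._finalize(outcomes, cts)


@dataclass
class SpatialDispersion(OutcomeSpace):
    """Dispersion-category tuples of pixel values under a stencil; |Ω| = c^L."""

    stencil: Stencil = Stencil.square(2)
    c: int = 3

    def __post_init__(self):
        if self.c < 2:
            raise ValueError("dispersion requires c >= 2 categories")

    def cardinality(self) -> int:
        return self.c ** len(self.stencil)

    def outcomes(self) -> list:
        return [tuple(t) for t in
                itertools.product(range(1, self.c + 1), repeat=len(self.stencil))]

    def counts(self, data) -> Counts:
        img = as_matrix(data)
        # categories from the whole image's empirical distribution
        disp = Dispersion(c=self.c, m=1, tau=1)
        z = disp.categories(img.ravel()).reshape(img.shape)
        win = _stencil_windows(z.astype(float), self.stencil).astype(np.int64)
        L = len(self.stencil)
        powers = self.c ** np.arange(L - 1, -1, -1)
        codes = ((win - 1) * powers).sum(axis=1)
        uniq, cts = np.unique(codes, return_counts=True)
        outcomes = [self._decode(int(k)) for k in uniq]
        return self._finalize(outcomes, cts)

    def _decode(self, code: int) -> tuple:
        L = len(self.stencil)
        digits = []
        for _ in range(L):
            digits.append(code % self.c + 1)
            code //= self.c
        return tuple(reversed(digits))


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------

def discretize(data, space: OutcomeSpace) -> Counts:
    """Encode ``data`` with the given outcome space and tally outcomes."""
    return space.counts(data)


def missing_outcomes(space: OutcomeSpace, data) -> int:
    """Number of outcomes deemed possible by the space but absent from data.

    Requires a finite, data-independent cardinality (forbidden/missing
    patterns are only meaningful when |Ω| is known a priori).
    """
    K = space.cardinality()
    if K is None:
        raise UnsupportedOperationError(
            f"{type(space).__name__} has data-dependent cardinality; "
            "missing outcomes are undefined"
        )
    ct = space.counts(data)
    return K - ct.n_observed
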