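"""Core containers shared across the estimation pipeline.

The pipeline is ``data -> outcome space -> counts -> probabilities ->
measure``.  This module holds the two containers that flow between the
stages — :class:`Counts` and :class:`PMF` — plus input validation helpers.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Counts",
    "PMF",
    "UnsupportedOperationError",
    "as_series",
    "as_state_space",
    "as_matrix",
]


class UnsupportedOperationError(RuntimeError):
    """Raised when an operation is undefined for the given component.

    Examples: querying missing outcomes of a data-dependent outcome space,
    or normalizing a measure that has no uniform-PMF maximum.
    """


def as_series(x) -> np.ndarray:
    """Validate and return a univariate timeseries as a 1-D float array.

    Rejects empty input and non-finite (NaN/Inf) values at ingestion, so
    that downstream encodings never have to handle them.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"expected a 1-D timeseries, got shape {arr.shape}")
    if arr.size < 1:
        raise ValueError("timeseries must contain at least one observation")
    if not np.all(np.isfinite(arr)):
        raise ValueError("timeseries contains NaN or Inf values")
    return arr


def as_state_space(points) -> np.ndarray:
    """Validate a collection of d-dimensional points as an (N, d) array."""
    arr = np.asarray(points, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError(f"expected an (N, d) point set, got shape {arr.shape}")
    if arr.shape[0] < 1:
        raise ValueError("state-space set must contain at least one point")
    if not np.all(np.isfinite(arr)):
        raise ValueError("state-space set contains NaN or Inf values")
    return arr


def as_matrix(img) -> np.ndarray:
    """Validate a 2-D numeric array (e.g. a grayscale image)."""
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("array contains NaN or Inf values")
    return arr


@dataclass
class Counts:
    """Frequencies (or weights) of the outcomes observed in some data.

    Parameters
    ----------
    outcomes
        Observed outcome identifiers, each decodable to a human-readable
        label (permutation tuples, category tuples, bin indices, ...).
    values
        Matching nonnegative integer counts, or nonnegative real weights
        for non-count outcome spaces.
    total_possible
        Cardinality of the outcome space, or ``None`` when it is
        data-dependent (e.g. unique elements, data-derived bin edges).
    is_count
        True when ``values`` are integer window counts; False for weighted
        encodings (weighted/amplitude-aware ordinal patterns, power
        spectrum).
    all_outcomes
        Canonical enumeration of the full outcome space when it is finite
        and small enough to materialize; used for full-support PMFs.
    """

    outcomes: list
    values: np.ndarray
    total_possible: int | None = None
    is_count: bool = True
    all_outcomes: list | None = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if len(self.outcomes) != self.values.size:
            raise ValueError("outcomes and values must have equal length")
        if np.any(self.values < 0):
            raise ValueError("counts/weights must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.values.sum())

    @property
    def n_observed(self) -> int:
        """Number of outcomes with strictly positive count/weight."""
        return int(np.count_nonzero(self.values > 0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"outcome_label": [str(o) for o in self.outcomes], "count": self.values}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class PMF:
    """A probability mass function over a list of outcomes.

    Probabilities are validated to be nonnegative and to sum to 1 (within
    1e-9; the estimators in :mod:`entrospect.probabilities` normalize
    explicitly, so in practice the defect is at machine precision).
    """

    outcomes: list
    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if len(self.outcomes) != self.probs.size:
            raise ValueError("outcomes and probs must have equal length")
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {self.probs.sum()}, not 1")

    def __len__(self) -> int:
        return self.probs.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"outcome_label": [str(o) for o in self.outcomes], "probability": self.probs}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_dict(self) -> dict:
        return {str(o): float(p) for o, p in zip(self.outcomes, self.probs)}
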