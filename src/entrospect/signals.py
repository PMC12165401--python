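"""Synthetic signal generators, surrogate series, and the missing-outcome
surrogate test for nonlinearity.

The generators cover the canonical test systems of the complexity
literature: the fully chaotic logistic map, a stationary AR(2) process,
the Lorenz-96 spatiotemporal chaotic model, white noise and sines.  All
randomness flows through an explicit seed (or numpy Generator), making
every signal bit-reproducible.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import as_series
from .outcome_spaces import OutcomeSpace, missing_outcomes

__all__ = [
    "logistic_map",
    "ar2",
    "lorenz96",
    "white_noise",
    "sine",
    "with_noise",
    "shuffle_surrogate",
    "fourier_surrogate",
    "make_surrogates",
    "SurrogateTestReport",
    "missing_outcome_surrogate_test",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def logistic_map(n: int, r: float = 4.0, x0: float = 0.4,
                 transient: int = 1000) -> np.ndarray:
    """Iterates of x_{k+1} = r x_k (1 - x_k) after discarding a transient.

    r = 4 is the fully chaotic regime; iterates stay in [0, 1].
    """
    if not 0.0 < x0 < 1.0:
        raise ValueError("x0 must lie in (0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    x = x0
    for _ in range(transient):
        x = r * x * (1.0 - x)
    out = np.empty(n)
    for i in range(n):
        out[i] = x
        x = r * x * (1.0 - x)
    return out


def ar2(n: int, phi1: float = 0.9, phi2: float = -0.2, sigma: float = 1.0,
        seed=None, transient: int = 500) -> np.ndarray:
    """Stationary AR(2) process x_t = phi1 x_{t-1} + phi2 x_{t-2} + eps_t.

    Stationarity (roots of 1 - phi1 z - phi2 z^2 outside the unit circle)
    is enforced.
    """
    if phi2 != 0.0 or phi1 != 0.0:
        roots = np.roots([-phi2, -phi1, 1.0]) if phi2 != 0.0 else np.roots([-phi1, 1.0])
        if np.any(np.abs(roots) <= 1.0):
            raise ValueError(
                f"AR(2) coefficients (phi1={phi1}, phi2={phi2}) are nonstationary"
            )
    rng = _rng(seed)
    eps = rng.normal(0.0, sigma, n + transient)
    x = np.zeros(n + transient)
    for t in range(2, n + transient):
        x[t] = phi1 * x[t - 1] + phi2 * x[t - 2] + eps[t]
    return x[transient:]


def _l96_deriv(x: np.ndarray, forcing: float) -> np.ndarray:
    # dx_i/dt = (x_{i+1} - x_{i-2}) x_{i-1} - x_i + F, cyclic indices
    return (np.roll(x, -1) - np.roll(x, 2)) * np.roll(x, 1) - x + forcing


def lorenz96(n: int, ndim: int = 8, forcing: float = 8.0, dt: float = 0.05,
             transient: int = 1000, coord: int = 0) -> np.ndarray:
    """One observed coordinate of the Lorenz-96 model, fixed-step RK4.

    The model couples ``ndim >= 4`` cyclic variables driven by a constant
    forcing F; F = 8 with ndim = 8 is chaotic.
    """
    if ndim < 4:
        raise ValueError("Lorenz-96 needs at least 4 dimensions")
    if not 0 <= coord < ndim:
        raise ValueError("observed coordinate out of range")
    state = np.full(ndim, forcing)
    state[0] += 0.01  # deterministic perturbation off the fixed point
    out = np.empty(n)
    for step in range(transient + n):
        k1 = _l96_deriv(state, forcing)
        k2 = _l96_deriv(state + 0.5 * dt * k1, forcing)
        k3 = _l96_deriv(state + 0.5 * dt * k2, forcing)
        k4 = _l96_deriv(state + dt * k3, forcing)
        state = state + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(state)):
            raise FloatingPointError("Lorenz-96 integration diverged")
        if step >= transient:
            out[step - transient] = state[coord]
    return out


def white_noise(n: int, sigma: float = 1.0, seed=None) -> np.ndarray:
    """Gaussian white noise with standard deviation sigma."""
    return _rng(seed).normal(0.0, sigma, n)


def sine(n: int, freq: float = 0.05, amplitude: float = 1.0,
         phase: float = 0.0) -> np.ndarray:
    """Sine wave with ``freq`` cycles per sample."""
    t = np.arange(n)
    return amplitude * np.sin(2.0 * math.pi * freq * t + phase)


def with_noise(x, fraction: float = 0.1, seed=None) -> np.ndarray:
    """Add observational Gaussian noise with sd = fraction * std(signal).

    "10% white noise" corresponds to fraction = 0.1.
    """
    x = as_series(x)
    if fraction < 0:
        raise ValueError("noise fraction must be >= 0")
    if fraction == 0:
        return x.copy()
    return x + _rng(seed).normal(0.0, fraction * x.std(), x.size)


# ---------------------------------------------------------------------------
# surrogates
# ---------------------------------------------------------------------------

def shuffle_surrogate(x, seed=None) -> np.ndarray:
    """Random permutation of the series: preserves the value distribution
    exactly, destroys all temporal structure (iid null)."""
    x = as_series(x)
    return _rng(seed).permutation(x)


def fourier_surrogate(x, seed=None) -> np.ndarray:
    """Phase-randomized surrogate: preserves the amplitude spectrum (hence
    the linear autocorrelation), destroys nonlinear structure."""
    x = as_series(x)
    if x.size < 8:
        raise ValueError("phase randomization needs at least 8 samples")
    rng = _rng(seed)
    spec = np.fft.rfft(x)
    phases = rng.uniform(0.0, 2.0 * math.pi, spec.size)
    phases[0] = np.angle(spec[0])  # keep the mean (DC) term
    if x.size % 2 == 0:
        phases[-1] = np.angle(spec[-1])  # Nyquist term must stay real
    return np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=x.size)


_SURROGATE_METHODS = {"shuffle": shuffle_surrogate, "fourier_phase": fourier_surrogate}


def make_surrogates(x, method: str = "shuffle", n_surrogates: int = 1,
                    seed=None) -> list[np.ndarray]:
    """Generate ``n_surrogates`` surrogate realizations of the series."""
    if method not in _SURROGATE_METHODS:
        raise ValueError(
            f"unknown surrogate method {method!r}; "
            f"choose from {sorted(_SURROGATE_METHODS)}"
        )
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    rng = _rng(seed)
    fn = _SURROGATE_METHODS[method]
    return [fn(x, rng) for _ in range(n_surrogates)]


@dataclass
class SurrogateTestReport:
    """Result of the missing-outcome surrogate test.

    ``outside_flag`` is True when the data's missing-outcome percentage
    falls outside the [min, max] range of the surrogate percentages — the
    decision rule for "inconsistent with the surrogate null".
    """

    data_pct: float
    surrogate_pcts: list[float]
    outside_flag: bool
    method: str


def missing_outcome_surrogate_test(x, space: OutcomeSpace, method: str = "shuffle",
                                   n_surrogates: int = 100,
                                   seed=None) -> SurrogateTestReport:
    """Compare the percentage of missing outcomes of a series against the
    distribution over surrogate realizations.

    Forbidden (missing) patterns are a signature of deterministic or
    nonlinear structure; surrogates consistent with a linear/iid null
    bracket the data value when no such structure exists.
    """
    K = space.cardinality()
    if K is None:
        raise ValueError("surrogate test needs a finite-cardinality outcome space")
    rng = _rng(seed)
    data_pct = 100.0 * missing_outcomes(space, x) / K
    pcts = [100.0 * missing_outcomes(space, s) / K
            for s in make_surrogates(x, method, n_surrogates, rng)]
    outside = data_pct < min(pcts) or data_pct > max(pcts)
    return SurrogateTestReport(float(data_pct), [float(p) for p in pcts],
                               bool(outside), method)
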