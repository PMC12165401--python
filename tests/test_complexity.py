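"""Non-PMF complexity measures and the multiscale wrapper."""
import math

import numpy as np
import pytest

import entrospect as E
from entrospect.core import UnsupportedOperationError


def _brute_chebyshev(points):
    diff = points[:, None, :] - points[None, :, :]
    return np.abs(diff).max(axis=2)


class TestApproximateEntropy:
    def test_constant_zero(self):
        assert E.approximate_entropy(np.ones(60), r=0.1) == pytest.approx(0.0)

    def test_mirror_invariance(self, rng):
        x = rng.normal(size=300)
        assert E.approximate_entropy(x) == pytest.approx(E.approximate_entropy(-x))

    def test_tree_equals_brute_force(self, rng):
        x = rng.normal(size=300)
        m, r = 2, 0.2 * x.std()

        def phi(dim):
            pts = E.delay_embed(x, dim, 1)
            counts = (_brute_chebyshev(pts) <= r).sum(axis=1)  # self included
            return np.mean(np.log(counts / len(pts)))

        expected = phi(m) - phi(m + 1)
        assert E.approximate_entropy(x, m=m, r=r) == pytest.approx(expected, rel=1e-10)

    def test_r_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            E.approximate_entropy(np.arange(50.0), r=0.0)


class TestSampleEntropy:
    def test_constant_zero(self):
        assert E.sample_entropy(np.ones(60), r=0.1) == pytest.approx(0.0)

    def test_tree_equals_brute_force(self, rng):
        x = rng.normal(size=300)
        m, r = 2, 0.2 * x.std()
        n_templates = x.size - m

        def pairs(dim):
            pts = E.delay_embed(x, dim, 1)[:n_templates]
            dmat = _brute_chebyshev(pts)
            iu = np.triu_indices(len(pts), k=1)
            return int((dmat[iu] <= r).sum())

        expected = -math.log(pairs(m + 1) / pairs(m))
        assert E.sample_entropy(x, m=m, r=r) == pytest.approx(expected, rel=1e-12)

    def test_periodic_less_than_shuffled(self, rng):
        x = E.sine(600, freq=0.02)
        shuffled = rng.permutation(x)
        r = 0.2 * x.std()
        assert E.sample_entropy(x, r=r) < E.sample_entropy(shuffled, r=r)

    def test_no_matches_returns_inf_with_warning(self):
        x = np.arange(30.0)  # strictly monotone: no m+1 matches at tiny r
        with pytest.warns(RuntimeWarning, match="no template matches"):
            assert E.sample_entropy(x, r=1e-9) == math.inf

    def test_regularity_ordering_noise_vs_sine(self):
        """White noise is less regular than a sine of equal variance."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            sine = E.sine(400, freq=0.03, amplitude=math.sqrt(2))  # unit variance
            noise = rng.normal(0, 1, 400)
            r = 0.2
            if E.sample_entropy(noise, r=r) > E.sample_entropy(sine, r=r) and \
               E.approximate_entropy(noise, r=r) > E.approximate_entropy(sine, r=r):
                wins += 1
        assert wins == 20


class TestLempelZiv:
    @pytest.mark.parametrize("seq,phrases", [
        ("0000000", 2),       # 0 | 000000
        ("0101010101", 3),    # 0 | 1 | 01010101
        ("0", 1),
        ("01", 2),
    ])
    def test_manual_parses(self, seq, phrases):
        assert E.lempel_ziv_76(seq) == phrases

    def test_prefix_monotonicity(self, rng):
        s = "".join(rng.choice(["0", "1"], size=200))
        vals = [E.lempel_ziv_76(s[:n]) for n in range(1, 201)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_median_binarization(self, rng):
        x = rng.normal(size=500)
        sym = "".join("1" if v > np.median(x) else "0" for v in x)
        assert E.lempel_ziv_76(x) == E.lempel_ziv_76(sym)


class TestDispersionStatistics:
    def test_constant_series_missing(self):
        # a constant series occupies a single category tuple
        assert E.missing_dispersion_patterns(np.ones(100), c=3, m=2) == 3 ** 2 - 1

    def test_long_noise_no_missing(self, rng):
        x = rng.normal(size=20_000)
        assert E.missing_dispersion_patterns(x, c=3, m=2) == 0

    def test_equals_generic_missing_outcomes(self, rng):
        x = rng.normal(size=500)
        assert E.missing_dispersion_patterns(x, c=4, m=3, tau=2) == \
            E.missing_outcomes(E.Dispersion(c=4, m=3, tau=2), x)

    def test_reverse_dispersion_degenerate(self):
        K = 3 ** 2
        v = E.reverse_dispersion(np.ones(100), c=3, m=2)
        assert v == pytest.approx(1.0 - 1.0 / K)

    def test_reverse_dispersion_bounds(self, rng):
        for _ in range(5):
            x = rng.normal(size=300)
            v = E.reverse_dispersion(x, c=3, m=2)
            assert 0.0 <= v <= 1.0 - 1.0 / 9


class TestStatisticalComplexity:
    def test_uniform_noise_low_complexity(self, rng):
        # near-uniform ordinal PMF: Q_J ~ 0 so C ~ 0
        x = rng.uniform(size=50_000)
        h, c = E.statistical_complexity(x, E.OrdinalPatterns(m=3))
        assert h > 0.99
        assert c < 0.02

    def test_monotone_zero_complexity(self):
        h, c = E.statistical_complexity(np.arange(100.0), E.OrdinalPatterns(m=3))
        assert h == 0.0 and c == 0.0

    def test_chaotic_map_strictly_between(self, logistic_long):
        h, c = E.statistical_complexity(logistic_long[:20_000], E.OrdinalPatterns(m=3))
        assert 0.0 < h < 1.0
        assert c > 0.05

    def test_qj_in_unit_interval(self, rng):
        """Normalized Jensen-Shannon disequilibrium stays in [0, 1] for
        random PMFs (cross-checked against a direct JS computation)."""
        from entrospect.complexity_estimators import _js_divergence
        for k in (2, 6, 24):
            q_max = _js_divergence(
                np.eye(k)[0], np.full(k, 1 / k))
            for _ in range(300):
                p = rng.dirichlet(np.ones(k))
                qj = _js_divergence(p, np.full(k, 1 / k)) / q_max
                assert 0.0 <= qj <= 1.0 + 1e-12

    def test_works_with_other_measures(self, logistic_long):
        h, c = E.statistical_complexity(logistic_long[:5000], E.OrdinalPatterns(m=3),
                                        measure=E.Tsallis(q=2))
        assert 0.0 < h <= 1.0 and c >= 0.0

    def test_fluctuation_complexity_rejected(self, rng):
        with pytest.raises((UnsupportedOperationError, ValueError)):
            E.statistical_complexity(rng.normal(size=200), E.OrdinalPatterns(m=3),
                                     measure=E.FluctuationComplexity())


class TestBubbleEntropy:
    def test_constant_zero(self):
        assert E.bubble_entropy(np.ones(100)) == pytest.approx(0.0)

    def test_monotone_zero(self):
        assert E.bubble_entropy(np.arange(100.0)) == pytest.approx(0.0)

    def test_swap_distribution_matches_enumeration(self, rng):
        """Swap-count frequencies agree with exhaustive per-window counting."""
        import itertools
        x = rng.normal(size=40)
        m = 3
        windows = E.delay_embed(x, m, 1)

        def swaps(w):
            w = list(w)
            s = 0
            for i in range(len(w)):
                for j in range(len(w) - 1 - i):
                    if w[j] > w[j + 1]:
                        w[j], w[j + 1] = w[j + 1], w[j]
                        s += 1
            return s

        expected = {}
        for w in windows:
            expected[swaps(w)] = expected.get(swaps(w), 0) + 1
        ct = E.discretize(x, E.BubbleSortSwaps(m=m))
        assert dict(zip(ct.outcomes, ct.values)) == expected


class TestMultiscale:
    def test_coarse_grain_window_means(self):
        assert E.coarse_grain([1, 2, 3, 4], 2).tolist() == [1.5, 3.5]

    def test_coarse_grain_length(self, rng):
        x = rng.normal(size=103)
        for s in (1, 2, 5, 10):
            assert E.coarse_grain(x, s).size == 103 // s

    def test_moving_average_length(self, rng):
        x = rng.normal(size=50)
        assert E.moving_average(x, 4).size == 47

    def test_scale_one_identity(self, rng):
        x = rng.normal(size=400)
        est = E.SampleEntropy(r=0.25)
        vals = E.multiscale(est, x, scales=3)
        assert vals[0] == E.complexity(est, x)

    def test_pipeline_and_callable_specs(self, rng):
        x = rng.normal(size=600)
        p = E.Pipeline(ospace=E.OrdinalPatterns(m=3))
        v1 = E.multiscale(p, x, scales=[1, 2, 4])
        v2 = E.multiscale(lambda y: E.information(y, E.OrdinalPatterns(m=3)),
                          x, scales=[1, 2, 4])
        assert np.allclose(v1, v2)

    def test_runs_for_every_complexity_estimator(self, rng):
        """Multiscale composes with any complexity estimator or pipeline."""
        x = rng.normal(size=500)
        specs = [E.ApproximateEntropy(), E.SampleEntropy(), E.LempelZiv76(),
                 E.MissingDispersionPatterns(c=3, m=2), E.ReverseDispersion(c=3, m=2),
                 E.StatisticalComplexity(), E.BubbleEntropy(),
                 E.Pipeline(ospace=E.Dispersion(c=3, m=2), measure=E.Tsallis(q=2))]
        for spec in specs:
            vals = E.multiscale(spec, x, scales=3)
            assert vals.shape == (3,)
            assert np.all(np.isfinite(vals))

    def test_too_short_at_scale(self):
        with pytest.raises(ValueError):
            E.coarse_grain(np.arange(4.0), 5)


class TestNormalizedComplexity:
    def test_missing_patterns_normalized(self, rng):
        v = E.complexity_normalized(E.MissingDispersionPatterns(c=3, m=2),
                                    rng.normal(size=50))
        assert 0.0 <= v <= 1.0

    def test_sample_entropy_has_no_maximum(self, rng):
        with pytest.raises(UnsupportedOperationError):
            E.complexity_normalized(E.SampleEntropy(), rng.normal(size=100))
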