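"""Discretization: embeddings, encodings, counting and missing outcomes."""
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import entrospect as E
from entrospect.core import UnsupportedOperationError
from entrospect.outcome_spaces import _inversion_counts


class TestDelayEmbed:
    def test_definition(self):
        emb = E.delay_embed([1, 2, 3, 4], m=2, tau=1)
        assert emb.tolist() == [[1, 2], [2, 3], [3, 4]]

    def test_vector_count(self):
        emb = E.delay_embed(np.arange(100.0), m=3, tau=2)
        assert emb.shape == (96, 3)

    def test_m1_identity(self, rng):
        x = rng.normal(size=50)
        assert np.array_equal(E.delay_embed(x, 1, 1).ravel(), x)

    def test_too_short_names_minimum(self):
        with pytest.raises(ValueError, match="at least 5"):
            E.delay_embed([1.0, 2.0, 3.0], m=3, tau=2)

    def test_rejects_nan(self):
        with pytest.raises(ValueError, match="NaN"):
            E.delay_embed([1.0, np.nan, 2.0], m=2, tau=1)


class TestOrdinalEncoding:
    def test_identity_rank_zero(self):
        for d in range(1, 7):
            assert E.encode_ordinal(np.arange(d, dtype=float)) == 0

    @pytest.mark.parametrize("d", [2, 3, 4, 5, 6])
    def test_roundtrip_bijection(self, d):
        # exhaustive: encoding a realization of each decoded pattern
        # recovers the rank, and all ranks are hit exactly once
        seen = set()
        for k in range(math.factorial(d)):
            perm = E.decode_ordinal(k, d)
            # build a vector whose ascending sort order is exactly `perm`
            v = np.empty(d)
            for pos, idx in enumerate(perm):
                v[idx] = pos
            assert E.encode_ordinal(v) == k
            seen.add(perm)
        assert len(seen) == math.factorial(d)

    def test_all_permutation_vectors_d4(self):
        # every permutation of 4 distinct values maps into {0..23}, bijectively
        ranks = {E.encode_ordinal(p) for p in itertools.permutations((10, 20, 30, 40))}
        assert ranks == set(range(24))

    def test_tie_break_stable(self):
        # equal values keep temporal order: (1,1) is "already sorted"
        assert E.encode_ordinal([1.0, 1.0]) == E.encode_ordinal([1.0, 2.0])

    def test_decode_out_of_range(self):
        with pytest.raises(ValueError):
            E.decode_ordinal(6, 3)


class TestDiscretize:
    def test_monotone_single_pattern(self):
        ct = E.discretize(np.arange(50.0), E.OrdinalPatterns(m=3))
        assert ct.n_observed == 1
        assert ct.values.tolist() == [48]
        assert ct.outcomes[0] == (0, 1, 2)

    def test_bubble_swap_hand_values(self):
        assert _inversion_counts(np.array([[3.0, 2.0, 1.0]])).tolist() == [3]
        assert _inversion_counts(np.array([[1.0, 2.0, 3.0]])).tolist() == [0]

    def test_bubble_swaps_match_sorting_oracle(self, rng):
        # swap count equals the number of swaps bubble sort actually performs
        def bubble_swaps(w):
            w = list(w)
            swaps = 0
            for i in range(len(w)):
                for j in range(len(w) - 1 - i):
                    if w[j] > w[j + 1]:
                        w[j], w[j + 1] = w[j + 1], w[j]
                        swaps += 1
            return swaps

        windows = rng.normal(size=(50, 5))
        expected = [bubble_swaps(w) for w in windows]
        assert _inversion_counts(windows).tolist() == expected

    def test_dispersion_symmetric_balanced(self, rng):
        x = rng.normal(size=4001)
        x = np.concatenate([x, -x])  # exactly symmetric about its mean (0)
        ct = E.discretize(x, E.Dispersion(c=2, m=1))
        assert ct.total_possible == 2
        counts = dict(zip(ct.outcomes, ct.values))
        lo, hi = counts[(1,)], counts[(2,)]
        assert abs(lo - hi) / (lo + hi) < 0.02

    def test_dispersion_categories_in_range(self, rng):
        z = E.Dispersion(c=4).categories(rng.standard_cauchy(1000))
        assert z.min() >= 1 and z.max() <= 4

    def test_unique_elements(self):
        ct = E.discretize([1.0, 2.0, 2.0, 3.0], E.UniqueElements())
        assert dict(zip(ct.outcomes, ct.values)) == {1.0: 1, 2.0: 2, 3.0: 1}
        assert ct.total_possible is None

    def test_value_binning_max_in_top_bin(self):
        ct = E.discretize(np.linspace(0, 1, 11), E.ValueBinning(n_bins=5))
        assert sum(ct.values) == 11
        counts = dict(zip(ct.outcomes, ct.values))
        assert counts[4] == 3  # 0.8, 0.9 and the max 1.0

    def test_power_spectrum_weights(self):
        x = E.sine(256, freq=0.125)
        ct = E.discretize(x, E.PowerSpectrum())
        assert not ct.is_count
        # nearly all power concentrates at the driving frequency
        assert ct.values.max() / ct.values.sum() > 0.99

    @pytest.mark.parametrize("space", [
        E.OrdinalPatterns(m=3), E.OrdinalPatterns(m=4, tau=2),
        E.Dispersion(c=3, m=2), E.BubbleSortSwaps(m=4),
        E.CosineSimilarityBinning(m=3, n_bins=8),
        E.SequentialPairDistances(m=2, n_bins=6, metric="euclidean"),
        E.ValueBinning(n_bins=7), E.UniqueElements(),
    ])
    def test_count_conservation(self, space, noise_series):
        """Sum of counts equals the number of encoded windows."""
        ct = E.discretize(noise_series, space)
        n = len(noise_series)
        if isinstance(space, (E.OrdinalPatterns, E.BubbleSortSwaps)):
            expected = n - (space.m - 1) * space.tau
        elif isinstance(space, E.Dispersion):
            expected = n - (space.m - 1) * space.tau
        elif isinstance(space, (E.CosineSimilarityBinning, E.SequentialPairDistances)):
            expected = n - (space.m - 1) * space.tau - 1  # consecutive pairs
        else:
            expected = n
        assert ct.total == expected

    def test_weighted_ordinal_weights_are_window_variances(self):
        x = np.array([0.0, 1.0, 0.0, 10.0])
        ct = E.discretize(x, E.WeightedOrdinalPatterns(m=2))
        # windows: (0,1) asc, (1,0) desc, (0,10) asc with variances .25, .25, 25
        w = dict(zip(ct.outcomes, ct.values))
        assert w[(0, 1)] == pytest.approx(0.25 + 25.0)
        assert w[(1, 0)] == pytest.approx(0.25)

    def test_amplitude_aware_blend(self):
        x = np.array([1.0, 3.0])
        ct = E.discretize(x, E.AmplitudeAwareOrdinalPatterns(m=2, A=0.5))
        # weight = 0.5*mean|x| + 0.5*mean|diff| = 0.5*2 + 0.5*2 = 2
        assert ct.values.tolist() == [pytest.approx(2.0)]


class TestSparseJointHistogram:
    def test_grid_one_per_cell(self):
        pts = np.array([(i + 0.5, j + 0.5) for i in range(3) for j in range(3)])
        ct = E.sparse_joint_histogram(pts, n_bins=3)
        assert ct.n_observed == 9
        assert all(v == 1 for v in ct.values)

    @pytest.mark.parametrize("d", [1, 2, 3])
    def test_matches_dense_histogram(self, d, rng):
        pts = rng.normal(size=(500, d))
        bins = 4
        ct = E.sparse_joint_histogram(pts, n_bins=bins)
        edges = [np.linspace(pts[:, j].min(), pts[:, j].max(), bins + 1)
                 for j in range(d)]
        dense, _ = np.histogramdd(pts, bins=edges)
        sparse = np.zeros([bins] * d)
        for o, v in zip(ct.outcomes, ct.values):
            sparse[o if d > 1 else (o,)] = v
        assert np.array_equal(sparse, dense)

    def test_high_dimensional_memory(self, rng):
        # 30-D binning with 2 bins/dim: would need 2^30 dense cells
        pts = rng.normal(size=(10_000, 30))
        ct = E.sparse_joint_histogram(pts, n_bins=2)
        assert ct.total == 10_000
        assert ct.n_observed <= 10_000

    def test_explicit_edges_and_errors(self):
        ct = E.sparse_joint_histogram(np.array([[0.1], [0.9], [1.0]]),
                                      edges=[np.array([0.0, 0.5, 1.0])])
        assert dict(zip(ct.outcomes, ct.values)) == {0: 1, 1: 2}
        with pytest.raises(ValueError):
            E.sparse_joint_histogram(np.array([[2.0]]), edges=[np.array([0.0, 1.0])])
        with pytest.raises(ValueError):
            E.sparse_joint_histogram(np.array([[0.0]]), n_bins=0)


class TestCardinalityAndMissing:
    @pytest.mark.parametrize("space,expected", [
        (E.OrdinalPatterns(m=3), 6),
        (E.Dispersion(c=3, m=2), 9),
        (E.BubbleSortSwaps(m=4), 7),
        (E.CosineSimilarityBinning(n_bins=12), 12),
        (E.SequentialPairDistances(n_bins=5), 5),
        (E.SpatialOrdinalPatterns(E.Stencil.square(2)), 24),
        (E.SpatialDispersion(E.Stencil.square(2), c=3), 81),
    ])
    def test_cardinality(self, space, expected):
        assert space.cardinality() == expected
        assert len(space.outcomes()) == expected

    def test_bubble_cardinality_matches_enumeration(self):
        # swap counts over all 24 permutations of 4 elements hit 0..6
        swaps = {int(_inversion_counts(np.array([p], dtype=float))[0])
                 for p in itertools.permutations(range(4))}
        assert swaps == set(range(7))
        assert E.BubbleSortSwaps(m=4).cardinality() == len(swaps)

    def test_unique_elements_data_dependent(self):
        assert E.UniqueElements().cardinality() is None
        with pytest.raises(UnsupportedOperationError):
            E.missing_outcomes(E.UniqueElements(), [1.0, 2.0])

    def test_monotone_missing(self):
        assert E.missing_outcomes(E.OrdinalPatterns(m=3), np.arange(50.0)) == 5

    def test_iid_uniform_no_missing(self, rng):
        x = rng.uniform(size=100_000)
        assert E.missing_outcomes(E.OrdinalPatterns(m=3), x) == 0

    @pytest.mark.parametrize("space", [
        E.OrdinalPatterns(m=3), E.Dispersion(c=3, m=3), E.BubbleSortSwaps(m=4),
    ])
    def test_missing_plus_observed_is_cardinality(self, space, noise_series):
        ct = E.discretize(noise_series, space)
        assert E.missing_outcomes(space, noise_series) + ct.n_observed \
            == space.cardinality()


class TestSpatial:
    def test_constant_image_single_outcome(self):
        img = np.ones((8, 10))
        ct = E.discretize(img, E.SpatialOrdinalPatterns(E.Stencil.square(2)))
        assert ct.n_observed == 1
        assert ct.values.tolist() == [7 * 9]

    def test_increasing_image_one_pattern(self):
        img = np.arange(30.0).reshape(5, 6)
        space = E.SpatialOrdinalPatterns(E.Stencil.square(2))
        ct = E.discretize(img, space)
        # row-major increasing: within (a, a+1, a+6, a+7) order is fixed
        assert ct.n_observed == 1
        assert E.missing_outcomes(space, img) == 23

    def test_spatial_dispersion_counts(self, rng):
        img = rng.uniform(size=(20, 20))
        space = E.SpatialDispersion(E.Stencil.square(2), c=3)
        ct = E.discretize(img, space)
        assert ct.total == 19 * 19
        assert all(len(o) == 4 and all(1 <= z <= 3 for z in o) for o in ct.outcomes)

    def test_custom_non_square_stencil(self, rng):
        stencil = E.Stencil(((0, 0), (0, 1), (1, 0)))
        img = rng.uniform(size=(10, 10))
        ct = E.discretize(img, E.SpatialOrdinalPatterns(stencil))
        assert ct.total == 9 * 9

    def test_stencil_validation(self):
        with pytest.raises(ValueError):
            E.Stencil(((0, 0),))
        with pytest.raises(ValueError):
            E.Stencil(((0, 1), (0, 0)))
        with pytest.raises(ValueError):
            E.Stencil(((0, 0), (0, 0)))

    def test_stencil_too_large(self):
        with pytest.raises(ValueError, match="fit"):
            E.discretize(np.ones((2, 2)), E.SpatialOrdinalPatterns(E.Stencil.square(3)))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(-100, 100), min_size=6, max_size=60))
def test_ordinal_counts_conserve_windows(values):
    x = np.asarray(values)
    ct = E.discretize(x, E.OrdinalPatterns(m=3))
    assert ct.total == x.size - 2
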