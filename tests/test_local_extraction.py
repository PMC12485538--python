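import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gule.distances import compute_distance_matrix
from gule.exceptions import DataError
from gule.local_extraction import (
    alpha_for_layer,
    credibility,
    enhanced_credibility,
    estimate_neighborhoods_layer1,
    estimate_neighborhoods_layer2,
    neighborhood_size,
)


class TestNeighborhoodSize:
    @pytest.mark.parametrize("n,K,expected", [
        (1000, 10, 11),   # floor(log2 100) = 6
        (160, 16, 8),     # floor(log2 10) = 3
        (2 * 7, 7, 6),    # floor(log2 2) = 1
    ])
    def test_formula(self, n, K, expected):
        assert neighborhood_size(n, K, k0=5) == expected

    def test_rejects_n_below_K(self):
        with pytest.raises(DataError):
            neighborhood_size(5, 6)

    def test_capped_below_dataset_size(self):
        assert neighborhood_size(4, 1, k0=50) == 3


class TestLayer1Neighborhoods:
    def test_collinear_hand_case(self):
        # points at 0, 1, 2 with kc = 2
        D = compute_distance_matrix(np.array([[0.0], [1.0], [2.0]]), "euclidean")
        N = estimate_neighborhoods_layer1(D, 2)
        assert list(N.neighbors[0]) == [0, 1] and N.omega[0] == 2.0
        # x1 is equidistant from both; the lower index wins the tie
        assert list(N.neighbors[1]) == [1, 0] and N.omega[1] == 1.0
        assert list(N.neighbors[2]) == [2, 1] and N.omega[2] == 2.0

    def test_self_is_first_everywhere(self):
        rng = np.random.default_rng(1)
        D = compute_distance_matrix(rng.normal(size=(20, 3)), "euclidean")
        N = estimate_neighborhoods_layer1(D, 5)
        assert all(nb[0] == i for i, nb in enumerate(N.neighbors))
        assert all(len(nb) == 5 for nb in N.neighbors)

    def test_coincident_points_flagged_degenerate(self):
        D = compute_distance_matrix(np.zeros((5, 2)) + 1.0, "euclidean")
        with pytest.warns(UserWarning, match="degenerate"):
            import warnings

            warnings.simplefilter("always")
            N = estimate_neighborhoods_layer1(D, 2)
        assert np.all(N.omega == 0.0)

    def test_kc_equal_to_n_capped(self):
        D = compute_distance_matrix(np.arange(4.0)[:, None], "euclidean")
        N = estimate_neighborhoods_layer1(D, 4)  # capped to n-1 = 3
        assert N.kc == 3
        assert all(len(nb) == 3 for nb in N.neighbors)
        assert np.all(np.isfinite(N.omega))


class TestLayer2Neighborhoods:
    def _dist_from_sorted(self, ds):
        """1-D configuration whose sorted-distance profile is ``ds``."""
        n = len(ds)
        D = np.abs(np.subtract.outer(np.asarray(ds), np.asarray(ds)))
        return compute_distance_matrix(np.asarray(ds, float)[:, None], "euclidean")

    def test_gap_rule_hand_case(self):
        # point 0's sorted distances: 0, .01, .02, .03, .9, .91, ...
        ds = [0.0, 0.01, 0.02, 0.03, 0.9, 0.91, 0.92, 0.93, 0.94, 0.95,
              0.96, 0.97]
        D = self._dist_from_sorted(ds)
        N = estimate_neighborhoods_layer2(D, kc=3, n=12, K=1)
        # largest forward gap at j=4 (0.9 - 0.03)
        assert len(N.neighbors[0]) == 4
        assert N.omega[0] == pytest.approx(0.9)

    def test_equal_gaps_tie_to_kc(self):
        # exactly representable equal gaps so every forward gap ties
        D = self._dist_from_sorted(np.arange(12.0))
        N = estimate_neighborhoods_layer2(D, kc=3, n=12, K=1)
        assert len(N.neighbors[0]) == 3  # smallest j wins argmax ties

    def test_gap_beyond_average_class_size_capped(self):
        # big gap at j=8 but n/K = 4 caps ki
        ds = [0.0] + [0.01 * j for j in range(1, 8)] + [5.0, 5.1, 5.2, 5.3]
        D = self._dist_from_sorted(ds)
        N = estimate_neighborhoods_layer2(D, kc=2, n=12, K=3)
        assert all(len(nb) <= 4 for nb in N.neighbors)

    def test_kc_above_average_class_size_clamps(self):
        D = self._dist_from_sorted(np.linspace(0, 1, 10))
        N = estimate_neighborhoods_layer2(D, kc=5, n=10, K=4)  # n//K = 2 < kc
        assert all(len(nb) == 5 for nb in N.neighbors)

    def test_size_bounds_invariant(self):
        rng = np.random.default_rng(2)
        U = rng.normal(size=(40, 3))
        D = compute_distance_matrix(U, "cosine")
        kc, K = 4, 4
        N = estimate_neighborhoods_layer2(D, kc, 40, K)
        sizes = N.sizes
        assert np.all(sizes >= kc) and np.all(sizes <= 40 // K)


class TestAlpha:
    @pytest.mark.parametrize("n,K,layer,expected", [
        (1000, 10, 1, 9.0),   # n/K = 100 <= 100
        (1010, 10, 1, 6.0),   # n/K = 101 > 100
        (50, 5, 2, 2.0),
        (100000, 2, 2, 2.0),
    ])
    def test_table(self, n, K, layer, expected):
        assert alpha_for_layer(n, K, layer) == expected


class TestEnhancedCredibility:
    @pytest.mark.parametrize("gamma,alpha,expected", [
        (0.0, 2.0, 1.0),
        (1.0, 2.0, 2.0 / (1.0 + np.e ** 2)),   # ~0.23840
        (0.5, 2.0, 2.0 / (1.0 + np.e ** 0.5)),  # ~0.75508
    ])
    def test_values(self, gamma, alpha, expected):
        assert enhanced_credibility(gamma, alpha) == pytest.approx(expected,
                                                                   abs=1e-5)

    def test_overflow_guarded(self):
        assert enhanced_credibility(1e6, 9.0) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(gamma=st.floats(1e-6, 5.0), alpha=st.floats(0.1, 20.0),
           bump=st.floats(1e-3, 1.0))
    def test_decreasing_and_bounded(self, gamma, alpha, bump):
        v = enhanced_credibility(gamma, alpha)
        assert 0.0 <= v <= 1.0
        vg = enhanced_credibility(gamma + bump, alpha)
        va = enhanced_credibility(gamma, alpha + bump)
        assert vg <= v and va <= v
        # strictly decreasing once the exponent moves beyond float resolution
        if (alpha * (gamma + bump)) ** 2 - (alpha * gamma) ** 2 > 1e-6 and v > 0:
            assert vg < v

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(gamma=st.floats(0.0, 3.0), alpha=st.floats(0.1, 10.0))
    def test_sigmoid_lift_relation(self, gamma, alpha):
        c = credibility(gamma, alpha)
        assert enhanced_credibility(gamma, alpha) == pytest.approx(
            2 * c / (1 + c), rel=1e-12)
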