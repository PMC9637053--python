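import numpy as np
import pytest
from scipy import stats

from fatmap.core import NormalizedProfile
from fatmap.spm import (
    InfiniteSmoothnessError,
    SPMTField,
    estimate_fwhm,
    find_clusters,
    monte_carlo_null,
    rft_threshold,
    smooth_gaussian_noise,
    spm_ttest2,
    t_field,
    unpaired_ttest,
)


def _field(t, t_star, fwhm=10.0, df=38, sided="two"):
    t = np.asarray(t, float)
    return SPMTField(
        t=t,
        df=df,
        fwhm=fwhm,
        alpha=0.05,
        t_star=t_star,
        nodes=np.linspace(0, 100, t.size),
        sided=sided,
    )


class TestTField:
    def test_copied_groups_give_zero_everywhere(self, rng):
        curves = rng.normal(30, 5, (6, 41))
        t, _ = t_field(curves, curves.copy())
        assert np.allclose(t, 0.0)

    def test_hand_computed_single_node(self):
        t, _ = t_field(np.array([[1.0], [2.0], [3.0]]), np.array([[4.0], [5.0], [6.0]]))
        assert t[0] == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), abs=1e-9)
        assert t[0] == pytest.approx(-3.674, abs=5e-4)

    def test_matches_scalar_ttest_per_node(self, rng):
        """Node-wise values equal independent scalar two-sample t tests."""
        A = rng.normal(30, 5, (8, 25))
        B = rng.normal(32, 6, (11, 25))
        t, _ = t_field(A, B)
        for q in range(25):
            expected = stats.ttest_ind(A[:, q], B[:, q], equal_var=True).statistic
            assert t[q] == pytest.approx(expected, abs=1e-10)

    def test_mismatched_grids_rejected(self, rng):
        a = [
            NormalizedProfile(np.linspace(0, 100, 11), rng.normal(30, 5, 11), "psoas")
            for _ in range(3)
        ]
        b = [
            NormalizedProfile(np.linspace(0, 100, 21), rng.normal(30, 5, 21), "psoas")
            for _ in range(3)
        ]
        with pytest.raises(ValueError, match="node grid"):
            t_field(a, b)

    def test_zero_pooled_variance_names_node(self, rng):
        A = rng.normal(30, 5, (4, 5))
        B = rng.normal(30, 5, (4, 5))
        A[:, 3] = 1.0
        B[:, 3] = 2.0
        with pytest.raises(ValueError, match="node 3"):
            t_field(A, B)

    def test_residuals_are_group_mean_deviations(self, rng):
        A = rng.normal(30, 5, (4, 7))
        B = rng.normal(30, 5, (5, 7))
        _, res = t_field(A, B)
        assert np.allclose(res[:4], A - A.mean(0))
        assert np.allclose(res[4:], B - B.mean(0))


class TestEstimateFwhm:
    def test_white_noise_is_rough(self, rng):
        ests = [
            estimate_fwhm(rng.standard_normal((20, 101))) for _ in range(200)
        ]
        assert np.mean(ests) < 3.0

    def test_recovers_known_smoothness(self, rng):
        """Monte-Carlo recovery of a 20-node kernel within 25%."""
        ests = [
            estimate_fwhm(smooth_gaussian_noise(20, 101, 20.0, rng)) for _ in range(200)
        ]
        assert np.mean(ests) == pytest.approx(20.0, rel=0.25)

    def test_scale_invariance(self, rng):
        R = smooth_gaussian_noise(8, 51, 8.0, rng)
        assert estimate_fwhm(R) == pytest.approx(estimate_fwhm(123.4 * R), abs=1e-12)

    def test_constant_residuals_flagged(self):
        with pytest.raises(InfiniteSmoothnessError):
            estimate_fwhm(np.ones((5, 20)) * np.array([[1.0], [2.0], [-1.0], [0.5], [-2.5]]))

    def test_zero_residuals_flagged(self):
        with pytest.raises(InfiniteSmoothnessError):
            estimate_fwhm(np.zeros((5, 20)))


class TestRftThreshold:
    def test_scalar_limit_as_resels_vanish(self):
        """With an essentially unresolved field the threshold approaches the
        ordinary one-tailed critical t value."""
        t_star = rft_threshold(38, 101, fwhm=1e9, alpha=0.05, tails=1)
        assert t_star == pytest.approx(stats.t.isf(0.05, 38), rel=1e-2)

    def test_monotone_in_resels(self):
        a = rft_threshold(38, 101, fwhm=10.0, alpha=0.05)
        b = rft_threshold(38, 101, fwhm=5.0, alpha=0.05)  # doubled resels
        assert b > a

    def test_monotone_in_alpha(self):
        a = rft_threshold(38, 101, fwhm=10.0, alpha=0.05)
        b = rft_threshold(38, 101, fwhm=10.0, alpha=0.01)
        assert b > a

    def test_two_sided_threshold_is_higher(self):
        one = rft_threshold(38, 101, fwhm=10.0, alpha=0.05, tails=1)
        two = rft_threshold(38, 101, fwhm=10.0, alpha=0.05, tails=2)
        assert two > one

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            rft_threshold(0, 101, 10.0, 0.05)
        with pytest.raises(ValueError):
            rft_threshold(38, 101, -1.0, 0.05)
        with pytest.raises(ValueError):
            rft_threshold(38, 101, 10.0, 0.7)


class TestFindClusters:
    def test_subthreshold_field_yields_nothing(self, rng):
        assert find_clusters(_field(rng.normal(0, 0.5, 101), t_star=3.0)) == []

    def test_single_cluster_span(self):
        t = np.zeros(101)
        t[13:18] = 4.0  # nodes 13-17 supra-threshold
        clusters = find_clusters(_field(t, t_star=3.0))
        assert len(clusters) == 1
        c = clusters[0]
        assert c.extent == 5
        assert 12.0 < c.start_percent <= 13.0
        assert 17.0 <= c.end_percent < 18.0
        assert 0 < c.p_value <= 1

    def test_two_bumps_sorted_disjoint(self):
        t = np.zeros(101)
        t[10:15] = 5.0
        t[60:70] = -5.0
        clusters = find_clusters(_field(t, t_star=3.0))
        assert len(clusters) == 2
        assert clusters[0].start_percent < clusters[1].start_percent
        assert clusters[0].end_percent < clusters[1].start_percent
        assert clusters[0].sign == 1 and clusters[1].sign == -1

    def test_one_sided_ignores_negative_excursions(self):
        t = np.zeros(101)
        t[60:70] = -5.0
        assert find_clusters(_field(t, t_star=3.0, sided="one")) == []

    def test_boundary_cluster_clipped_to_field_edge(self):
        t = np.zeros(101)
        t[:5] = 4.0
        c = find_clusters(_field(t, t_star=3.0))[0]
        assert c.start_percent == 0.0


class TestSpmTtest2:
    def test_identical_groups_no_clusters(self, rng):
        base = smooth_gaussian_noise(10, 101, 12.0, rng)
        result = spm_ttest2(base + 0.01 * rng.standard_normal((10, 101)), base)
        # nearly identical groups: tiny t everywhere
        assert result.clusters == []

    def test_detects_inserted_bump(self, rng):
        noise = smooth_gaussian_noise(40, 101, 15.0, rng)
        bump = 6.0 * np.exp(-((np.linspace(0, 100, 101) - 15.0) ** 2) / (2 * 6.4**2))
        result = spm_ttest2(30.0 + bump + noise[:20], 30.0 + noise[20:])
        assert any(c.contains(15.0) and c.sign == 1 for c in result.clusters)


class TestUnpairedTtest:
    def test_identical_samples(self):
        t, p = unpaired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_textbook_example(self):
        t, p = unpaired_ttest([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert abs(t) == pytest.approx(3.674, abs=5e-4)
        assert p == pytest.approx(0.0214, abs=5e-4)

    def test_p_uniform_under_null(self, rng):
        """Distributional check: equal-mean samples give uniform p-values."""
        ps = []
        for _ in range(500):
            ps.append(unpaired_ttest(rng.normal(0, 1, 30), rng.normal(0, 1, 30))[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            unpaired_ttest([1.0, 1.0], [1.0, 1.0])


class TestMonteCarloNull:
    def test_deterministic_under_seed(self):
        a = monte_carlo_null(10, 51, 8.0, n_reps=20, seed=42)
        b = monte_carlo_null(10, 51, 8.0, n_reps=20, seed=42)
        assert np.array_equal(a, b)

    def test_huge_fwhm_collapses_to_scalar_t(self):
        """A field smoother than its length behaves like a single t variable."""
        maxima = monte_carlo_null(38, 101, fwhm=101 * 100.0, n_reps=4000, seed=7)
        q95 = np.quantile(maxima, 0.95)
        assert q95 == pytest.approx(stats.t.isf(0.05, 38), rel=0.06)


class TestSmoothGaussianNoise:
    def test_unit_variance_and_shape(self, rng):
        z = smooth_gaussian_noise(4000, 31, 10.0, rng)
        assert z.shape == (4000, 31)
        sd = z.std(axis=0, ddof=1)
        assert np.allclose(sd, 1.0, atol=0.08)

    def test_neighbor_correlation_matches_gaussian_kernel(self, rng):
        """Lag-1 autocorrelation of a FWHM-w field is exp(-4 ln2 / (2 w^2))."""
        w = 10.0
        z = smooth_gaussian_noise(6000, 21, w, rng)
        r = np.mean(z[:, :-1] * z[:, 1:])
        expected = np.exp(-4.0 * np.log(2.0) / (2.0 * w * w))
        assert r == pytest.approx(expected, abs=0.03)
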