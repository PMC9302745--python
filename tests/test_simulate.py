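"""Tests of the paired-count generative model."""

import numpy as np
import pytest
from scipy import integrate, stats

from compda.simulate import (
    CorrelationSpec, SimulationConfig, build_correlation,
    draw_absolute_counts, draw_baseline_log_means, draw_observed_depth,
    draw_sample_multiplier, filter_low_abundance, multinomial_resample,
    perturb_log_means, select_differential, simulate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


class TestBaselineLogMeans:
    def test_zero_variance_is_constant(self, rng):
        assert np.array_equal(draw_baseline_log_means(5, 2.0, 0.0, rng),
                              np.full(5, 2.0))

    def test_single_feature_degenerate(self, rng):
        assert draw_baseline_log_means(1, -3.0, 0.0, rng) == \
            pytest.approx([-3.0])

    def test_large_sample_moments(self, rng):
        theta = draw_baseline_log_means(10_000, 0.0, 1.0, rng)
        # tolerance 3*S/sqrt(P) a la the law of large numbers
        assert abs(theta.mean()) < 0.05
        assert abs(theta.std() - 1.0) < 0.05

    @pytest.mark.parametrize("P,m,S", [(0, 0, 1), (5, np.inf, 1), (5, 0, -1)])
    def test_invalid_parameters(self, rng, P, m, S):
        with pytest.raises(ValueError):
            draw_baseline_log_means(P, m, S, rng)


class TestCorrelationMatrix:
    def test_identity_scale_concentrates_near_identity(self, rng):
        omega = build_correlation(3, CorrelationSpec("identity", df=1000), rng)
        assert np.allclose(np.diag(omega), 1.0)
        off = omega[~np.eye(3, dtype=bool)]
        assert np.max(np.abs(off)) < 0.15

    def test_symmetric_positive_definite(self, rng):
        spec = CorrelationSpec("dense-positive", strength=0.6,
                               frac_correlated=0.5)
        omega = build_correlation(20, spec, rng)
        assert np.allclose(omega, omega.T)
        assert np.min(np.linalg.eigvalsh(omega)) > 0

    def test_correlated_block_is_visible(self, rng):
        spec = CorrelationSpec("dense-positive", strength=0.9,
                               frac_correlated=0.5)
        inside, outside = [], []
        for _ in range(100):
            omega = build_correlation(10, spec, rng)
            k = 5
            blk = omega[:k, :k][~np.eye(k, dtype=bool)]
            rest = omega[k:, k:][~np.eye(10 - k, dtype=bool)]
            inside.append(blk.mean())
            outside.append(rest.mean())
        assert np.mean(inside) > np.mean(outside)

    def test_df_must_exceed_dimension(self, rng):
        with pytest.raises(ValueError):
            build_correlation(10, CorrelationSpec("identity", df=10), rng)


class TestPerturbation:
    def test_zero_scale_returns_theta1(self, rng):
        theta1 = rng.normal(size=50)
        omega = np.eye(50)
        assert np.array_equal(perturb_log_means(theta1, omega, 0.0, rng),
                              theta1)

    def test_marginal_sd_matches_scale(self, rng):
        theta1 = np.zeros(2)
        diffs = np.array([perturb_log_means(theta1, np.eye(2), 1.0, rng)
                          for _ in range(10_000)])
        assert np.allclose(diffs.std(axis=0), 1.0, atol=0.05)

    def test_correlation_is_propagated(self, rng):
        omega = np.array([[1.0, 0.9], [0.9, 1.0]])
        diffs = np.array([perturb_log_means(np.zeros(2), omega, 1.0, rng)
                          for _ in range(10_000)])
        assert np.corrcoef(diffs.T)[0, 1] == pytest.approx(0.9, abs=0.05)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            perturb_log_means(np.zeros(3), np.eye(2), 1.0, rng)


class TestDifferentialSelection:
    def test_c_zero_means_identical(self, rng):
        theta1, theta2 = rng.normal(size=100), rng.normal(size=100)
        truth, mu1, mu2 = select_differential(theta1, theta2, 0.0, rng)
        assert not truth.any()
        assert np.array_equal(mu1, mu2)

    def test_c_one_takes_perturbed_means(self, rng):
        theta1, theta2 = rng.normal(size=100), rng.normal(size=100)
        truth, _, mu2 = select_differential(theta1, theta2, 1.0, rng)
        assert truth.all()
        assert np.allclose(mu2, np.exp(theta2))

    def test_fraction_converges_to_c(self, rng):
        theta = rng.normal(size=10_000)
        truth, _, _ = select_differential(theta, theta, 0.5, rng)
        assert truth.mean() == pytest.approx(0.5, abs=0.02)

    def test_non_differential_features_keep_baseline(self, rng):
        theta1, theta2 = rng.normal(size=200), rng.normal(size=200)
        truth, mu1, mu2 = select_differential(theta1, theta2, 0.5, rng)
        assert np.array_equal(mu1[~truth], mu2[~truth])


class TestSampleMultiplier:
    def test_no_noise_gives_unit(self, rng):
        assert draw_sample_multiplier(0.0, rng) == 1.0

    def test_truncation_floor(self, rng):
        draws = [draw_sample_multiplier(10.0, rng) for _ in range(2000)]
        assert min(draws) >= 0.1

    def test_mean_matches_numeric_integral(self, rng):
        g = 0.2
        # independent oracle: E[max(0.1, N(1, g))] by quadrature
        expected = 0.1 * stats.norm.cdf(0.1, 1.0, g) + integrate.quad(
            lambda x: x * stats.norm.pdf(x, 1.0, g), 0.1, np.inf)[0]
        draws = np.array([draw_sample_multiplier(g, rng)
                          for _ in range(10_000)])
        assert draws.mean() == pytest.approx(expected, abs=0.01)


class TestAbsoluteCounts:
    def test_zero_mean_gives_zero_count(self, rng):
        y = draw_absolute_counts(np.array([0.0, 5.0]), 1.0, 1000.0, rng)
        assert y[0] == 0

    def test_nb_variance(self, rng):
        y = np.array([draw_absolute_counts(np.array([1000.0]), 1.0, 1000.0,
                                           rng)[0] for _ in range(10_000)])
        # var = mu + mu^2/size = 1000 + 1000 = 2000
        assert y.var() == pytest.approx(2000, rel=0.10)

    def test_mean_scales_with_delta(self, rng):
        y = np.array([draw_absolute_counts(np.array([50.0]), 2.0, 1000.0,
                                           rng)[0] for _ in range(10_000)])
        assert y.mean() == pytest.approx(100, rel=0.03)

    def test_negative_mean_rejected(self, rng):
        with pytest.raises(ValueError):
            draw_absolute_counts(np.array([-1.0]), 1.0, 1000.0, rng)


class TestObservedDepth:
    def test_degenerate_bounds(self, rng):
        assert draw_observed_depth(1e5, 1e5, rng) == 100_000

    def test_uniform_mean(self, rng):
        draws = np.array([draw_observed_depth(5_000, 2_000_000, rng)
                          for _ in range(10_000)])
        assert draws.mean() == pytest.approx(1.0025e6, rel=0.02)


class TestMultinomialResample:
    def test_point_mass(self, rng):
        z = multinomial_resample(np.array([10, 0, 0]), 7, rng)
        assert np.array_equal(z, [7, 0, 0])

    def test_total_conserved(self, rng):
        for _ in range(20):
            y = rng.integers(0, 100, size=30) + 1
            u = int(rng.integers(1, 10_000))
            assert multinomial_resample(y, u, rng).sum() == u

    def test_proportions_recovered(self, rng):
        z = multinomial_resample(np.array([1, 1, 2]), 40_000, rng)
        assert z[2] / 40_000 == pytest.approx(0.5, abs=0.02)

    def test_all_zero_rejected(self, rng):
        with pytest.raises(ValueError):
            multinomial_resample(np.zeros(3), 10, rng)


class TestSimulateDataset:
    def test_null_config_has_no_differential_features(self):
        cfg = SimulationConfig(P=50, m=3.0, S=1.0, a=2.0, c=0.0, g=0.0,
                               seed=1)
        data = simulate_dataset(cfg)
        assert not data.truth.any()
        assert np.array_equal(data.mu1, data.mu2)

    def test_same_seed_is_bit_identical(self):
        cfg = SimulationConfig(P=40, m=3.0, S=1.0, a=1.0, c=0.5, g=0.2,
                               seed=99)
        d1, d2 = simulate_dataset(cfg), simulate_dataset(cfg)
        assert np.array_equal(d1.Y, d2.Y)
        assert np.array_equal(d1.Z, d2.Z)
        assert np.array_equal(d1.truth, d2.truth)

    def test_resampling_removes_total_abundance_change(self):
        cfg = SimulationConfig(P=200, m=4.0, S=1.0, a=4.0, c=0.9, g=0.0,
                               seed=5)
        data = simulate_dataset(cfg)
        y_tot1 = data.Y[:, data.condition == 1].sum()
        y_tot2 = data.Y[:, data.condition == 2].sum()
        assert y_tot2 / y_tot1 != pytest.approx(1.0, abs=0.05)
        assert len(np.unique(data.Z.sum(axis=0))) == 1

    def test_depth_shared_across_samples(self):
        cfg = SimulationConfig(P=30, m=3.0, S=0.5, seed=3)
        data = simulate_dataset(cfg)
        assert len(np.unique(data.depth)) == 1


class TestLowAbundanceFilter:
    def test_hand_computed_case(self):
        # feature means 0.5/1.5/2.0 in Y and 2.0/0.9/2.0 in Z: keep only #3
        Y = np.array([[0, 1], [1, 2], [2, 2]])
        Z = np.array([[2, 2], [1, 0], [2, 2]])
        _, _, keep = filter_low_abundance(Y, Z)
        assert np.array_equal(keep, [False, False, True])

    def test_boundary_mean_is_inclusive(self):
        Y = np.array([[1, 1], [0, 0]])
        Z = np.array([[2, 0], [9, 9]])
        _, _, keep = filter_low_abundance(Y, Z)
        assert keep[0] and not keep[1]

    def test_truth_subset(self):
        Y = np.array([[0, 0], [5, 5]])
        Z = np.array([[5, 5], [5, 5]])
        _, _, truth, keep = filter_low_abundance(
            Y, Z, truth=np.array([True, False]))
        assert np.array_equal(truth, [False])

    def test_everything_removed_is_an_error(self):
        Y = np.zeros((2, 2))
        with pytest.raises(ValueError):
            filter_low_abundance(Y, Y)
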