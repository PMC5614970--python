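import numpy as np
import pytest

import mlcfa
from mlcfa.estimation import reference_info, sandwich_covariance, scaled_chisq
from mlcfa.sampling import SimulationCondition


class TestDegreesOfFreedom:
    @pytest.mark.parametrize("name,df", [
        ("2MLR", 4), ("1MLR", 2), ("2MaxB", 2), ("2MaxW", 2), ("2Miss", 7),
    ])
    def test_spec_df(self, name, df):
        assert mlcfa.get_spec(name).df == df

    @pytest.mark.parametrize("name,df", [
        ("2MLR", 4), ("1MLR", 2), ("2MaxB", 2), ("2MaxW", 2), ("2Miss", 7),
    ])
    def test_fitted_df(self, medium_fits, name, df):
        assert medium_fits[name].chisq_df == df


class TestParameterRecovery:
    def test_2mlr_recovers_population_within_3se(self, pop03, big_sample):
        res = mlcfa.fit("2MLR", big_sample)
        assert res.converged and res.admissible
        truth = np.concatenate((
            pop03.within_loadings[1:], [pop03.psi_within], pop03.theta_within,
            pop03.between_loadings[1:], [pop03.psi_between],
            pop03.theta_between, pop03.intercepts))
        assert np.all(np.abs(res.params.values - truth) < 3 * res.bse)

    def test_bias_shrinks_with_sample_size(self, pop03):
        """2MLR is consistent: average loading error shrinks as N grows."""
        truth = pop03.within_loadings[1:]
        errs = []
        for G, n in [(30, 5), (300, 50)]:
            per_rep = []
            for rep in range(8):
                cond = SimulationCondition(G, n, 0.3, seed=77)
                res = mlcfa.fit("2MLR",
                                mlcfa.generate_dataset(pop03, cond, rep))
                if res.converged:
                    per_rep.append(np.abs(res.params.values[:3] - truth).mean())
            errs.append(np.mean(per_rep))
        assert errs[1] < errs[0] / 2


class TestInvariances:
    def test_intercepts_equal_grand_means_in_every_spec(self, medium_fits,
                                                        medium_moments):
        for res in medium_fits.values():
            mu = res.params.values[-4:]
            assert np.allclose(mu, medium_moments.grand_mean, atol=1e-6)

    def test_maxb_between_block_saturates(self, medium_fits, medium_moments):
        # fitted Sigma_W + n Sigma_B equals the scaled cluster-mean scatter
        res = medium_fits["2MaxB"]
        imp = res.spec.implied(res.params.values)
        sigma_n = imp.sigma_within + medium_moments.n * imp.sigma_between
        assert np.allclose(sigma_n, medium_moments.n * medium_moments.between_ml,
                           atol=1e-5)

    def test_maxb_within_estimates_match_2mlr(self, medium_fits):
        a = medium_fits["2MaxB"].params.as_series()
        b = medium_fits["2MLR"].params.as_series()
        for name in a.index:
            if name.startswith(("lambda_w", "psi_w", "theta_w")):
                assert a[name] == pytest.approx(b[name], abs=0.02)

    def test_maxw_between_estimates_match_2mlr(self, medium_fits):
        a = medium_fits["2MaxW"].params.as_series()
        b = medium_fits["2MLR"].params.as_series()
        for name in a.index:
            if name.startswith(("lambda_b", "psi_b", "theta_b")):
                assert a[name] == pytest.approx(b[name], abs=0.05)


class TestSandwich:
    def test_mean_se_closed_form(self, medium_fits, medium_moments):
        """Robust SE of each mean equals sqrt(var of cluster means / G).

        The per-cluster score of a free mean is proportional to the cluster
        mean deviation, so the sandwich collapses to the empirical variance
        of cluster means over G (ML divisor) for every specification.
        """
        pred = np.sqrt(np.diag(medium_moments.between_ml) / medium_moments.G)
        for res in medium_fits.values():
            assert np.allclose(res.bse[-4:], pred, rtol=1e-4)

    def test_sandwich_close_to_information_when_correct(self, big_sample):
        res = mlcfa.fit("2MLR", big_sample)
        from mlcfa.estimation import _hessian_from_grad
        H = _hessian_from_grad(res.spec, res.params.values, res.moments)
        naive = np.sqrt(np.diag(2.0 * np.linalg.inv(H)))
        ratio = res.bse / naive
        assert np.all((ratio > 0.85) & (ratio < 1.15))

    def test_sandwich_covariance_function_matches_fit(self, medium_fits,
                                                      medium_moments):
        res = medium_fits["1MLR"]
        V = sandwich_covariance(res.spec, res.params, medium_moments)
        assert np.allclose(np.sqrt(np.diag(V)), res.bse, rtol=1e-10)


class TestRobustChisq:
    def test_mean_scaled_statistic_near_df(self, pop03):
        """With many clusters the scaled statistic is chi-square calibrated.

        The mean approaches df from above as G grows (finite-G inflation is
        expected and visible in small-cluster settings), so calibration is
        asserted at G = 300.
        """
        cond = SimulationCondition(300, 5, 0.3, seed=58)
        stats, scales = [], []
        for rep in range(80):
            mom = mlcfa.compute_moments(
                mlcfa.generate_dataset(pop03, cond, rep))
            res = mlcfa.fit("2MLR", mom)
            if res.converged:
                stats.append(res.chisq)
                scales.append(res.scaling_factor)
        # chi-square(4) has mean 4, sd sqrt(8); 80 reps give se ~ 0.32
        assert np.mean(stats) == pytest.approx(4.0, abs=1.0)
        assert np.mean(scales) == pytest.approx(1.0, abs=0.1)

    def test_scaled_chisq_propagates_nonconvergence(self, medium_moments):
        res = mlcfa.fit("2MLR", medium_moments, maxiter=1)
        if not res.converged:
            stat, scale = scaled_chisq(res)
            assert np.isnan(stat)

    def test_misspecified_statistic_far_above_df(self, big_sample):
        res = mlcfa.fit("2Miss", big_sample)
        assert res.chisq > 5 * res.chisq_df


class TestRobustness:
    def test_never_raises_on_hard_samples(self, pop03):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pop = mlcfa.with_icc(mlcfa.harter_population(), 0.1)
        cond = SimulationCondition(15, 3, 0.1, seed=13)
        flags = []
        heywood = []
        for rep in range(20):
            mom = mlcfa.compute_moments(mlcfa.generate_dataset(pop, cond, rep))
            res = mlcfa.fit("2MLR", mom)
            flags.append((res.converged, res.admissible))
            series = res.params.as_series()
            heywood.append(min(series["psi_b"],
                               series[[f"theta_b[{lab}]"
                                       for lab in pop.labels]].min()))
        assert all(isinstance(c, bool) and isinstance(a, bool)
                   for c, a in flags)
        # Heywood cases are reported as-is, never truncated at zero
        assert min(heywood) < 0

    def test_reference_info_reused(self, medium_moments):
        ref = reference_info(medium_moments, onelevel=False)
        res = mlcfa.fit("2MLR", medium_moments, reference=ref)
        assert res._reference is ref
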