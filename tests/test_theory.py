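import numpy as np
import pytest

import mlcfa
from mlcfa.theory import (composite_reliability, conflated_loadings,
                          conflation_curve, derived_quantities,
                          design_based_reliability, indicator_r2,
                          pseudo_true_onelevel)


class TestConflatedLoadings:
    def test_printed_values_at_icc_03(self, pop03):
        lam = conflated_loadings(pop03)
        assert lam[0] == 1.0
        assert lam[1] == pytest.approx(0.3 * 0.78 + 0.7 * 0.45, abs=1e-12)
        assert lam[1] == pytest.approx(0.549, abs=1e-12)
        assert lam[2] == pytest.approx(0.824, abs=1e-12)

    @pytest.mark.parametrize("icc,attr", [(0.0, "within_loadings"),
                                          (1.0, "between_loadings")])
    def test_boundary_identities_exact(self, icc, attr):
        with pytest.warns(UserWarning):
            pop = mlcfa.with_icc(mlcfa.harter_population(), icc)
        assert np.array_equal(conflated_loadings(pop), getattr(pop, attr))


class TestPseudoTrueOneLevel:
    def test_matches_large_sample_simulation_means(self, pop03):
        pt = pseudo_true_onelevel(pop03).as_series()
        # exact probability limits sit slightly below the weighted averages
        assert pt["lambda[CPCSA]"] == pytest.approx(0.534, abs=0.01)
        assert pt["lambda[CPCAC]"] == pytest.approx(0.791, abs=0.01)
        assert pt["lambda[CPCSA]"] < 0.549
        assert pt["lambda[CPCAC]"] < 0.824

    def test_factor_variance_near_total(self, pop03):
        pt = pseudo_true_onelevel(pop03).as_series()
        # approximately psi_B + psi_W = 1; conflation shifts it slightly up
        assert pt["psi"] == pytest.approx(1.0, abs=0.05)

    def test_equal_loadings_recovered_exactly(self):
        pop = mlcfa.PopulationModel(
            within_loadings=[1, 0.5, 0.8, 0.3],
            between_loadings=[1, 0.5, 0.8, 0.3],
            theta_within=[0.5] * 4, theta_between=[0.2] * 4,
            intercepts=[0.0] * 4).with_icc(0.4)
        pt = pseudo_true_onelevel(pop).as_series()
        assert np.allclose(pt.iloc[:3], [0.5, 0.8, 0.3], atol=1e-5)
        assert pt["psi"] == pytest.approx(1.0, abs=1e-5)


class TestCompositeReliability:
    def test_perfect_indicator(self):
        assert composite_reliability([1.0], [0.0], 1.0) == 1.0

    def test_within_level_value_at_icc_03(self, pop03):
        rho = composite_reliability(pop03.within_loadings, pop03.theta_within,
                                    pop03.psi_within)
        expected = 2.73 ** 2 * 0.7 / (2.73 ** 2 * 0.7 + 2.0)
        assert rho == pytest.approx(expected, abs=1e-12)
        assert rho == pytest.approx(0.723, abs=0.001)

    def test_monotone_in_error_variance(self, pop03):
        lo = composite_reliability(pop03.within_loadings,
                                   2 * pop03.theta_within, pop03.psi_within)
        hi = composite_reliability(pop03.within_loadings,
                                   pop03.theta_within, pop03.psi_within)
        assert lo < hi

    def test_marker_scaling_invariance(self, pop03):
        c = 2.0
        a = composite_reliability(pop03.within_loadings, pop03.theta_within,
                                  pop03.psi_within)
        b = composite_reliability(c * pop03.within_loadings,
                                  pop03.theta_within, pop03.psi_within / c ** 2)
        assert a == pytest.approx(b, rel=1e-12)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            composite_reliability([0.0, 0.0], [0.0, 0.0], 1.0)


class TestDesignBasedReliability:
    @pytest.mark.parametrize("icc", [0.0, 1.0])
    def test_boundary_equals_conflated_congeneric(self, icc):
        # at the boundaries one weighted sum vanishes, so squaring the sums
        # separately agrees with the congeneric formula on conflated loadings
        with pytest.warns(UserWarning):
            pop = mlcfa.with_icc(mlcfa.harter_population(), icc)
        via_conflated = composite_reliability(
            conflated_loadings(pop), pop.theta_between + pop.theta_within, 1.0)
        assert design_based_reliability(pop) == pytest.approx(via_conflated,
                                                              rel=1e-12)

    def test_interior_strictly_below_conflated_congeneric(self):
        pop = mlcfa.with_icc(mlcfa.harter_population(), 0.5)
        via_conflated = composite_reliability(
            conflated_loadings(pop), pop.theta_between + pop.theta_within, 1.0)
        assert design_based_reliability(pop) < via_conflated


class TestIndicatorR2:
    def test_half_split(self):
        values = np.concatenate(([0.0, 0.0, 0.0], [0.5], [0.5] * 4, [0.0] * 4))
        r2 = indicator_r2("1MLR", values)
        marker = r2[r2.indicator == "CPCSC"].r2.iloc[0]
        assert marker == pytest.approx(0.5)

    def test_marker_within_at_population(self, pop03):
        values = np.concatenate((
            pop03.within_loadings[1:], [pop03.psi_within], pop03.theta_within,
            pop03.between_loadings[1:], [pop03.psi_between],
            pop03.theta_between, pop03.intercepts))
        r2 = indicator_r2("2MLR", values)
        marker = r2[(r2.indicator == "CPCSC") & (r2.level == "within")]
        assert marker.r2.iloc[0] == pytest.approx(0.7 / 1.2, abs=1e-12)

    def test_zero_loading_zero_r2(self):
        values = np.concatenate(([0.0, 0.5, 0.5], [1.0], [0.5] * 4, [0.0] * 4))
        r2 = indicator_r2("1MLR", values)
        assert r2[r2.indicator == "CPCSA"].r2.iloc[0] == 0.0


class TestDerivedAndCurve:
    def test_derived_quantities_in_unit_interval(self, pop03):
        d = derived_quantities(pop03)
        for v in (d.reliability_within, d.reliability_between,
                  d.reliability_onelevel):
            assert 0 <= v <= 1
        assert np.all((d.r2_within >= 0) & (d.r2_within <= 1))
        assert np.all((d.indicator_icc >= 0) & (d.indicator_icc <= 1))
        assert d.conflated_loadings[0] == 1.0

    def test_pseudo_true_trajectory_monotone(self):
        """One-level loadings move monotonically from within to between truth."""
        pop = mlcfa.harter_population()
        curve = conflation_curve(pop, [0.0, 0.25, 0.5, 0.75, 1.0])
        for lab in ("CPCSA", "CPCAC", "CPCSW"):
            sub = curve[curve.indicator == lab]
            diffs = np.diff(sub.pseudo_true.to_numpy())
            w = sub.within_truth.iloc[0]
            b = sub.between_truth.iloc[0]
            assert np.all(diffs > 0) if b > w else np.all(diffs < 0)
            assert sub.pseudo_true.iloc[0] == pytest.approx(w, abs=1e-4)
            assert sub.pseudo_true.iloc[-1] == pytest.approx(b, abs=1e-4)
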