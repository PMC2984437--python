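"""Fitting the rate of the effect-size distribution."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq

from polyarch import (
    ConfigurationError,
    EffectDistribution,
    ESTIMATOR_NAMES,
    EstimationContext,
    SimulationScenario,
    delta_density,
    detected_vg_density,
    f1_density,
    fit_f1,
    fit_gamma_scale,
    fit_moment,
    get_ncp_map,
    n_variants,
    run_estimator,
    simulate_z,
    zcrit_from_fwer,
)

ZC = zcrit_from_fwer(0.05, 100_000)


class TestDetectedVgDensity:
    def test_full_power_reduces_to_plain_exponential(self, binary_design):
        # at a tiny threshold every variant is detected: pwr ~ 1
        v = np.array([1e-4, 1e-3, 5e-3])
        lam = 1500.0
        got = detected_vg_density(v, lam, binary_design, 1e-8)
        assert got == pytest.approx(lam * np.exp(-lam * v), rel=1e-6)

    def test_normalises_to_one(self, binary_design):
        total = quad(
            lambda v: detected_vg_density(v, 2000.0, binary_design, ZC), 0, 0.5,
            limit=200,
        )[0]
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_small_effects_suppressed_relative_to_exponential(self, binary_design):
        # limited power under-represents small Vg among detected variants
        lam = 2000.0
        v_small = 1e-4
        ratio = detected_vg_density(v_small, lam, binary_design, ZC) / (
            lam * np.exp(-lam * v_small)
        )
        assert ratio < 0.1


class TestFitMoment:
    def test_no_selection_is_closed_form_exponential_mle(self, binary_design):
        rng = np.random.default_rng(2)
        vgs = rng.exponential(1 / 2000, 5000)
        fit = fit_moment(vgs, None, binary_design, 1e-8)
        assert fit.lambda_hat == pytest.approx(1 / vgs.mean(), rel=1e-4)

    def test_moment_curve_strictly_decreasing_in_lambda(self, binary_design):
        from polyarch.lambda_fit import _power_at_nodes, _power_weighted_mean

        pwr = _power_at_nodes(get_ncp_map(binary_design), ZC)
        lams = np.geomspace(10, 1e5, 25)
        means = [_power_weighted_mean(l, pwr) for l in lams]
        assert np.all(np.diff(means) < 0)

    def test_moment_root_equals_ml_score_zero(self, binary_design):
        # method-of-moments and power-adjusted ML give the same estimate
        rng = np.random.default_rng(3)
        scen = SimulationScenario(lambda_true=1000.0, seed=1)
        z = simulate_z(scen, rng)
        sel = np.abs(z) >= ZC
        ncp_map = get_ncp_map(binary_design)
        vg = np.asarray(ncp_map.vg(np.abs(z[sel])))
        fit = fit_moment(vg, None, binary_design, ZC)

        def score(lam, h=1e-4):
            return (fit.loglik_at(lam * (1 + h)) - fit.loglik_at(lam * (1 - h))) / (
                2 * lam * h
            )

        lam_score = brentq(score, fit.lambda_hat * 0.5, fit.lambda_hat * 2, xtol=1e-8)
        assert lam_score == pytest.approx(fit.lambda_hat, rel=1e-6)

    def test_parameter_recovery_with_oracle_selection(self, binary_design):
        # true Vg of truly associated markers selected by their noisy z:
        # selection probability is exactly the power, so the moment fit is
        # consistent; median over replicates within 10% of truth
        lam = 2000.0
        ncp_map = get_ncp_map(binary_design)
        rng = np.random.default_rng(4)
        estimates = []
        for _ in range(50):
            vg = rng.exponential(1 / lam, 500)
            delta = np.asarray(ncp_map.delta(np.clip(vg, 0, ncp_map.vg_max)))
            z = delta + rng.standard_normal(500)
            sel = np.abs(z) >= ZC
            if sel.sum() < 3:
                continue
            estimates.append(fit_moment(vg[sel], None, binary_design, ZC).lambda_hat)
        assert np.median(estimates) == pytest.approx(lam, rel=0.10)


class TestDeltaAndF1Densities:
    def test_delta_density_symmetric(self, binary_design):
        assert delta_density(3.0, 1000.0, binary_design) == pytest.approx(
            delta_density(-3.0, 1000.0, binary_design)
        )

    def test_delta_density_normalises(self, binary_design):
        total = quad(
            lambda d: delta_density(d, 2000.0, binary_design), -40, 40, limit=400
        )[0]
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_continuous_closed_form_against_monte_carlo(self, continuous_design):
        # change of variables: Vg ~ Exp(lambda) -> delta histogram
        lam, n = 500.0, continuous_design.n_total
        rng = np.random.default_rng(6)
        vg = rng.exponential(1 / lam, 400_000)
        delta = np.sqrt(n * vg / (1 - vg))
        hist, edges = np.histogram(delta, bins=60, range=(0.1, 8), density=True)
        mids = 0.5 * (edges[:-1] + edges[1:])
        # positive-side density is twice the symmetrised density
        expected = 2 * np.asarray(delta_density(mids, lam, continuous_design))
        assert hist == pytest.approx(expected, rel=0.1, abs=0.01)

    def test_f1_symmetric_and_normalised(self, binary_design):
        assert f1_density(2.5, 2000.0, binary_design) == pytest.approx(
            f1_density(-2.5, 2000.0, binary_design)
        )
        total = quad(
            lambda z: f1_density(z, 2000.0, binary_design), -30, 30, limit=200
        )[0]
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_f1_matches_simulated_nonnull_z(self, binary_design):
        # Kolmogorov distance between simulated non-null z and the f1 CDF
        lam = 2000.0
        ncp_map = get_ncp_map(binary_design)
        rng = np.random.default_rng(8)
        vg = rng.exponential(1 / lam, 100_000)
        delta = np.asarray(ncp_map.delta(np.clip(vg, 0, ncp_map.vg_max)))
        z = delta * rng.choice([-1, 1], vg.size) + rng.standard_normal(vg.size)
        grid = np.linspace(-12, 12, 2001)
        pdf = np.asarray(f1_density(grid, lam, binary_design))
        cdf = np.concatenate([[0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(grid))])
        cdf /= cdf[-1]
        emp = np.searchsorted(np.sort(z), grid) / z.size
        assert np.max(np.abs(emp - cdf)) < 0.02


class TestFitF1:
    def test_truncated_density_normalises(self, binary_design):
        # the fitted object's internal truncated density integrates to 1
        from polyarch.lambda_fit import _TruncF1Loglik

        lam = 1000.0
        grid = np.linspace(ZC, ZC + 15, 3001)
        helper = _TruncF1Loglik(grid, np.ones_like(grid), binary_design, ZC)
        from scipy.stats import gamma as gamma_dist

        p = gamma_dist.pdf(helper.vg_d, 1.0, scale=1 / lam) * helper.dvg_d
        pw = p * helper.trapz_w
        dens = (helper.kernel @ pw) / float(helper.tail @ pw)
        total = 2 * np.trapezoid(dens, grid)  # both tails by symmetry
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_unit_weights_equal_unweighted(self, binary_design, scan1000):
        z = scan1000[np.abs(scan1000) >= ZC]
        a = fit_f1(z, None, binary_design, ZC)
        b = fit_f1(z, np.ones(z.size), binary_design, ZC)
        assert a.lambda_hat == pytest.approx(b.lambda_hat, rel=1e-9)

    def test_depends_only_on_magnitude_of_z(self, binary_design, scan1000):
        z = scan1000[np.abs(scan1000) >= ZC]
        a = fit_f1(z, None, binary_design, ZC)
        b = fit_f1(np.abs(z), None, binary_design, ZC)
        assert a.lambda_hat == b.lambda_hat

    def test_recovery_at_lambda_1000(self, binary_design, scenario1000):
        # Bonferroni-selected truncated-f1 fits cluster around the truth
        estimates = []
        for seed in range(15):
            z = simulate_z(scenario1000, np.random.default_rng(300 + seed))
            zsel = z[np.abs(z) >= ZC]
            estimates.append(fit_f1(zsel, None, binary_design, ZC).lambda_hat)
        assert np.median(estimates) == pytest.approx(1000.0, rel=0.15)


class TestGamma:
    def test_shape_one_equals_exponential_fit(self, binary_design, scan1000):
        z = scan1000[np.abs(scan1000) >= ZC]
        exp_fit = fit_f1(z, None, binary_design, ZC)
        gam_fit = fit_gamma_scale(z, None, 1.0, binary_design, ZC)
        assert gam_fit.lambda_hat == pytest.approx(exp_fit.lambda_hat, rel=1e-6)

    def test_gamma_recovery(self, binary_design):
        # data simulated from gamma(0.5, rate 1000); median recovery 15%
        shape, lam = 0.5, 1000.0
        ncp_map = get_ncp_map(binary_design)
        rng = np.random.default_rng(9)
        estimates = []
        for _ in range(20):
            vg = rng.gamma(shape, 1 / lam, 500)
            delta = np.asarray(ncp_map.delta(np.clip(vg, 0, ncp_map.vg_max)))
            z = delta + rng.standard_normal(500)
            zsel = z[np.abs(z) >= ZC]
            estimates.append(
                fit_gamma_scale(zsel, None, shape, binary_design, ZC).lambda_hat
            )
        assert np.median(estimates) == pytest.approx(lam, rel=0.15)

    def test_smaller_shape_means_more_variants(self, binary_design, scan1000):
        # a distribution more skewed to zero implies more variants at the
        # same heritability
        z = scan1000[np.abs(scan1000) >= ZC]
        counts = []
        for k in (1.0, 0.9, 0.7, 0.5, 0.3):
            fit = fit_gamma_scale(z, None, k, binary_design, ZC)
            counts.append(n_variants(fit.distribution, 0.5))
        assert np.all(np.diff(counts) > 0)


class TestNVariants:
    @pytest.mark.parametrize(
        "h2,lam,expected",
        [(0.55, 1787, 983), (0.63, 769, 484), (0.36, 1115, 401)],
    )
    def test_exponential_table_arithmetic(self, h2, lam, expected):
        dist = EffectDistribution("exponential", rate=lam)
        assert n_variants(dist, h2) == expected

    def test_gamma_mean_and_count(self):
        dist = EffectDistribution("gamma", rate=937.0, shape=0.9)
        assert dist.mean == pytest.approx(9.60e-4, rel=1e-3)
        assert n_variants(dist, 0.36) == 375

    def test_mean_equal_heritability_gives_one_variant(self):
        dist = EffectDistribution("exponential", rate=1 / 0.5)
        assert n_variants(dist, 0.5) == 1

    def test_linear_in_heritability(self):
        dist = EffectDistribution("exponential", rate=1000.0)
        assert n_variants(dist, 0.8, rounded=False) == pytest.approx(
            2 * n_variants(dist, 0.4, rounded=False)
        )


@pytest.fixture(scope="module")
def context(scan1000, binary_design):
    return EstimationContext(scan1000, binary_design, 0.3)


class TestRunEstimator:

    def test_all_fourteen_names_resolve_and_run(self, context):
        fits = {name: run_estimator(name, context=context) for name in ESTIMATOR_NAMES}
        assert len(fits) == 14
        assert all(f.lambda_hat > 0 for f in fits.values())

    def test_unknown_name_is_configuration_error(self, context):
        with pytest.raises(ConfigurationError):
            run_estimator("Bonf.bogus", context=context)

    def test_uncorrected_estimate_below_median_corrected(self, context):
        # winner's curse inflates observed Vg, so the uncorrected fit gives
        # a smaller lambda than the median-corrected one
        plain = run_estimator("Bonf", context=context)
        corrected = run_estimator("Bonf.corr.med", context=context)
        assert plain.lambda_hat < corrected.lambda_hat

    def test_fdr_mode_uses_more_markers_than_bonferroni(self, context):
        bonf = run_estimator("Bonf", context=context)
        fdr = run_estimator("truncfdr", context=context)
        assert fdr.n_markers_used > bonf.n_markers_used
        assert fdr.z_crit < bonf.z_crit
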