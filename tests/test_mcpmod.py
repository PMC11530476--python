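"""Dose-finding machinery: anchored candidate curves, optimal contrasts,
equicoordinate critical values, the contrast test, MED prediction, signal
criteria, and the contrast-ratio consistency criterion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from conftest import make_mcpmod_spec
from regionsizer.config import DoseResponseModelSpec
from regionsizer.mcpmod import (
    contrast_consistency,
    empirical_logit,
    fit_dose_response,
    mct_critical_value,
    med_from_curve,
    model_means,
    optimal_contrasts,
    region_n_per_dose,
    run_mct,
    signal_criterion,
    simulate_mcpmod,
)

DOSES = [0.0, 10.0, 25.0, 50.0, 100.0]
E0, EMAX = 1.25, 0.15

ALL_FAMILIES = [
    DoseResponseModelSpec(family="linear"),
    DoseResponseModelSpec(family="emax", ed50=2.6),
    DoseResponseModelSpec(family="emax", ed50=12.5),
    DoseResponseModelSpec(family="sigmoid_emax", ed50=25, hill=3),
    DoseResponseModelSpec(family="quadratic"),
    DoseResponseModelSpec(family="exponential", rate=40),
]


class TestModelMeans:
    @pytest.mark.parametrize("model", ALL_FAMILIES, ids=lambda m: m.family)
    def test_anchoring(self, model):
        mu = model_means(model, DOSES, E0, EMAX)
        assert mu[0] == pytest.approx(E0, abs=1e-10)
        assert mu[-1] == pytest.approx(E0 + EMAX, abs=1e-10)
        assert np.isfinite(mu).all()

    def test_emax_half_effect_at_ed50(self):
        # at d = ED50 the anchored curve sits at half its asymptotic
        # above-placebo effect
        ed50 = 2.6
        model = DoseResponseModelSpec(family="emax", ed50=ed50)
        mu = model_means(model, [0.0, ed50, 100.0], E0, EMAX)
        asymptote = EMAX / (100.0 / (ed50 + 100.0))  # scaled Emax parameter
        assert mu[1] - mu[0] == pytest.approx(asymptote / 2, abs=1e-10)


class TestOptimalContrasts:
    def test_linear_equal_n_reduces_to_centered_means(self):
        mu0 = np.array([0.0, 1, 2, 3, 4])
        c = optimal_contrasts([mu0], [10] * 5)[0]
        expected = np.array([-2.0, -1, 0, 1, 2]) / math.sqrt(10)
        np.testing.assert_allclose(c, expected, atol=1e-12)

    def test_zero_sum_and_unit_norm(self):
        mu0s = [model_means(m, DOSES, E0, EMAX) for m in ALL_FAMILIES]
        for n in ([60, 50, 40, 60, 70], [60] * 5):
            for c in optimal_contrasts(mu0s, n):
                assert abs(c.sum()) < 1e-9
                assert np.linalg.norm(c) == pytest.approx(1.0)

    def test_unequal_n_matches_numeric_maximizer(self):
        """The returned contrast maximizes the noncentrality
        c'mu0 / sqrt(c'Sc) over centered contrasts (brute-force oracle)."""
        mu0 = model_means(DoseResponseModelSpec(family="emax", ed50=12.5), DOSES, E0, EMAX)
        n = np.array([30, 45, 60, 75, 90], dtype=float)
        s = 1.0 / n

        def neg_ncp(free):
            c = np.append(free, -free.sum())  # enforce weighted-mean centering? no: plain
            denom = math.sqrt((c * c * s).sum())
            return -(c @ mu0) / denom

        best = None
        for seed in range(5):
            x0 = np.random.default_rng(seed).normal(size=4)
            r = optimize.minimize(neg_ncp, x0, method="Nelder-Mead",
                                  options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
            if best is None or r.fun < best.fun:
                best = r
        c_opt = optimal_contrasts([mu0], n)[0]
        ncp_ours = (c_opt @ mu0) / math.sqrt((c_opt * c_opt * s).sum())
        assert ncp_ours == pytest.approx(-best.fun, rel=1e-6)

    def test_shift_and_scale_invariance(self):
        mu0 = model_means(DoseResponseModelSpec(family="emax", ed50=2.6), DOSES, E0, EMAX)
        n = [60] * 5
        base = optimal_contrasts([mu0], n)[0]
        shifted = optimal_contrasts([mu0 + 7.3], n)[0]
        scaled = optimal_contrasts([mu0 * 4.2], n)[0]
        np.testing.assert_allclose(base, shifted, atol=1e-10)
        np.testing.assert_allclose(base, scaled, atol=1e-10)

    def test_constant_candidate_rejected(self):
        with pytest.raises(ValueError):
            optimal_contrasts([np.ones(5)], [60] * 5)


class TestCriticalValue:
    def test_single_contrast_is_t_quantile(self):
        c = optimal_contrasts([np.array([0.0, 1, 2])], [20, 20, 20])
        q = mct_critical_value(c, [20, 20, 20], 0.025, df=57)
        assert q == pytest.approx(stats.t.ppf(0.975, 57), abs=1e-9)

    def test_two_independent_contrasts_product_rule(self):
        # orthogonal contrasts with equal n -> independent t statistics in
        # the normal limit: P(max <= q) = Phi(q)^2
        c = np.array([[-0.5, -0.5, 0.5, 0.5], [-0.5, 0.5, -0.5, 0.5]])
        alpha = 0.05
        q = mct_critical_value(c, [30] * 4, alpha, df=None)
        expected = stats.norm.ppf(math.sqrt(1 - alpha))
        assert q == pytest.approx(expected, abs=1e-3)

    def test_duplicate_contrasts_collapse(self):
        c1 = optimal_contrasts([np.array([0.0, 1, 2])], [20] * 3)
        c_dup = np.vstack([c1, c1])
        q1 = mct_critical_value(c1, [20] * 3, 0.025, df=57)
        q2 = mct_critical_value(c_dup, [20] * 3, 0.025, df=57)
        assert q1 == pytest.approx(q2, abs=1e-9)

    def test_worked_candidate_set_bounds(self):
        """For correlated contrasts the critical value sits strictly between
        the unadjusted and Bonferroni t quantiles."""
        spec = make_mcpmod_spec()
        mu0 = [model_means(m, spec.doses, spec.e0, spec.emax_effect)
               for m in spec.candidate_models]
        c = optimal_contrasts(mu0, spec.n_per_dose)
        df = sum(spec.n_per_dose) - len(spec.doses)
        q = mct_critical_value(c, spec.n_per_dose, 0.025, df)
        assert stats.t.ppf(0.975, df) < q < stats.t.ppf(1 - 0.025 / 4, df)


class TestRunMct:
    def test_flat_data_no_poc(self):
        spec = make_mcpmod_spec()
        mu0 = [model_means(m, spec.doses, spec.e0, spec.emax_effect)
               for m in spec.candidate_models]
        c = optimal_contrasts(mu0, spec.n_per_dose)
        t, sig, sel = run_mct(np.full(5, 1.25), c, spec.n_per_dose, 2.2,
                              pooled_variance=0.1)
        np.testing.assert_allclose(t, 0.0, atol=1e-12)
        assert not sig.any() and sel is None

    def test_noiseless_candidate_selects_itself(self):
        spec = make_mcpmod_spec()
        mu0 = [model_means(m, spec.doses, spec.e0, spec.emax_effect)
               for m in spec.candidate_models]
        c = optimal_contrasts(mu0, spec.n_per_dose)
        for k, mu in enumerate(mu0):
            t, sig, sel = run_mct(np.asarray(mu), c, spec.n_per_dose, 2.2,
                                  pooled_variance=1e-6)
            assert sel == k, f"model {k} not selected on its own mean vector"


class TestFitAndMed:
    def test_noiseless_emax_med_at_half_asymptote(self):
        model = DoseResponseModelSpec(family="emax", ed50=12.5)
        mu = model_means(model, DOSES, E0, EMAX)
        params, ok = fit_dose_response("emax", np.array(DOSES), mu,
                                       np.full(5, 60.0), model)
        assert ok
        # recovered curve: e0 ~ E0, ED50 ~ 12.5
        assert params[0] == pytest.approx(E0, abs=1e-6)
        assert params[2] == pytest.approx(12.5, rel=1e-4)
        # delta = half the asymptotic Emax -> MED = ED50 by definition
        med = med_from_curve("emax", params, params[1] / 2, 100.0)
        assert med == pytest.approx(12.5, abs=0.01)

    def test_delta_beyond_range_gives_missing(self):
        model = DoseResponseModelSpec(family="emax", ed50=12.5)
        mu = model_means(model, DOSES, E0, EMAX)
        params, _ = fit_dose_response("emax", np.array(DOSES), mu,
                                      np.full(5, 60.0), model)
        assert med_from_curve("emax", params, 10.0, 100.0) is None

    def test_med_matches_grid_inversion(self, rng):
        """Fitted-curve MED agrees with a brute-force grid inversion to
        0.01 dose units on a noisy seeded dataset."""
        model = DoseResponseModelSpec(family="emax", ed50=12.5)
        mu = model_means(model, DOSES, E0, EMAX)
        y = mu + rng.normal(0, 0.01, len(mu))
        params, _ = fit_dose_response("emax", np.array(DOSES), y,
                                      np.full(5, 60.0), model)
        delta = 0.07
        med = med_from_curve("emax", params, delta, 100.0)
        from regionsizer.mcpmod import _curve

        grid = np.arange(0.0, 100.0 + 1e-9, 0.001)
        eff = _curve("emax", grid, params) - _curve("emax", np.array([0.0]), params)[0]
        hits = grid[(eff >= delta) & (grid > 0)]
        assert med == pytest.approx(hits[0], abs=0.01)

    def test_linear_and_quadratic_solved_exactly(self):
        d = np.array(DOSES)
        y = 1.0 + 0.02 * d - 0.0001 * d * d
        params, ok = fit_dose_response(
            "quadratic", d, y, np.full(5, 60.0), DoseResponseModelSpec(family="quadratic")
        )
        assert ok
        np.testing.assert_allclose(params, [1.0, 0.02, -0.0001], atol=1e-10)


class TestSignalCriterion:
    def test_type2_requires_observed_effect(self):
        means = np.array([1.25, 1.26, 1.27, 1.28, 1.30])
        assert signal_criterion(poc=True, means_all=means, signal_type=1,
                                delta=None, med=None, d_max=100)
        assert not signal_criterion(poc=True, means_all=means, signal_type=2,
                                    delta=0.1, med=None, d_max=100)

    def test_nesting_on_replicates(self):
        """Type 3 implies type 2 implies type 1, replicate by replicate."""
        spec = make_mcpmod_spec(delta=0.1)
        rng_master = np.random.default_rng(17)
        for _ in range(60):
            seed = int(rng_master.integers(2**31))
            reps = {}
            for stype in (1, 2, 3):
                s = make_mcpmod_spec(delta=0.1, signal_type=stype)
                r = simulate_mcpmod(s, "continuous", 0.15,
                                    np.random.default_rng(seed))
                reps[stype] = r.signal
            assert reps[3] <= reps[2] <= reps[1]

    def test_invalid_type_rejected(self):
        with pytest.raises(ValueError):
            signal_criterion(poc=True, means_all=np.zeros(3), signal_type=4,
                             delta=0.1, med=None, d_max=100)


class TestContrastConsistency:
    def test_identical_means_ratio_one(self):
        y = np.array([0.0, 1, 2])
        c = np.array([-1.0, 0, 1]) / math.sqrt(2)
        assert contrast_consistency(y, y, c, 0.5) is True

    def test_half_strength_region_strict(self):
        y = np.array([0.0, 1, 2])
        yr = np.array([0.0, 0.5, 1.0])
        c = np.array([-1.0, 0, 1]) / math.sqrt(2)
        # ratio exactly 0.5: strict inequality fails
        assert contrast_consistency(yr, y, c, 0.5) is False

    def test_zero_regional_contrast(self):
        y = np.array([0.0, 1, 2])
        c = np.array([-1.0, 0, 1]) / math.sqrt(2)
        assert contrast_consistency(np.zeros(3), y, c, 0.5) is False

    def test_zero_overall_contrast_not_evaluable(self):
        c = np.array([-1.0, 0, 1]) / math.sqrt(2)
        assert contrast_consistency(np.ones(3), np.ones(3), c, 0.5) is None


class TestSimulateMcpmod:
    def test_regional_sizes_ceiling(self):
        assert region_n_per_dose([60] * 5, 0.15) == [9] * 5

    def test_noiseless_replicate_is_fully_consistent(self):
        spec = make_mcpmod_spec(sd=0.0, delta=0.075)
        r = simulate_mcpmod(spec, "continuous", 0.15, np.random.default_rng(1))
        assert r.poc and r.signal
        assert r.selected == spec.true_model_index
        assert r.consistency is True
        assert r.med is not None

    def test_empirical_dose_means_within_clt_bound(self):
        spec = make_mcpmod_spec()
        mu = model_means(spec.candidate_models[0], spec.doses, spec.e0,
                         spec.emax_effect)
        reps = 4000
        rng = np.random.default_rng(23)
        acc = np.zeros(len(spec.doses))
        for _ in range(reps):
            r = simulate_mcpmod(spec, "continuous", 0.15, rng)
            acc += r.means_all
        se = spec.sd / np.sqrt(np.array(spec.n_per_dose) * reps)
        assert (np.abs(acc / reps - mu) < 4 * se).all()

    def test_binary_logit_pathway(self):
        spec = make_mcpmod_spec(e0=0.30, emax_effect=0.15, sd=None)
        r = simulate_mcpmod(spec, "binary", 0.15, np.random.default_rng(3))
        # analysis means are logits, not rates
        assert (np.abs(r.means_all) < 5).all()
        p_top = 0.45
        assert abs(r.means_all[-1] - math.log(p_top / (1 - p_top))) < 1.5

    def test_empirical_logit_shrinkage_finite_at_extremes(self):
        x = np.array([0, 9, 5])
        n = np.array([9, 9, 9])
        lg = empirical_logit(x, n)
        assert np.isfinite(lg).all()
        assert lg[0] == pytest.approx(math.log(0.5 / 9.5))
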