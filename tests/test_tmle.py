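import numpy as np
import pytest

from heatlmtp.learners import LearnerLibrary
from heatlmtp.ratios import DensityRatioPanel, estimate_ratios, truncate
from heatlmtp.tmle import (
    back_transform,
    natural_course_mean,
    tmle_contrast,
    tmle_policy_mean,
)


class TestBackTransform:
    @pytest.mark.parametrize(
        "log_value,expected",
        [(4.196, 65.4), (4.186, 64.8), (4.206, 66.1), (0.0, 0.0)],
    )
    def test_inverts_log_plus_one(self, log_value, expected):
        assert round(back_transform(log_value), 1) == expected


@pytest.fixture(scope="module")
def discrete_fit(discrete_instance, fast_library):
    """Shared TMLE fits on one 5,000-child discrete draw."""
    y, fact, cf, true_ratios, cov = discrete_instance.sample(5000, seed=3)
    shift = tmle_policy_mean(
        y, fact, cf, true_ratios, cov, fast_library, folds=3, seed=1,
        outcome_bounds=(0.0, 1.0),
    )
    natural = natural_course_mean(
        y, fact, cov, fast_library, folds=3, seed=2, outcome_bounds=(0.0, 1.0)
    )
    return y, fact, cf, true_ratios, cov, shift, natural


class TestPolicyMean:
    def test_matches_exhaustive_gcomputation(self, discrete_instance, discrete_fit):
        *_, shift, _ = discrete_fit
        truth = discrete_instance.true_shift_mean()
        assert abs(shift.psi - truth) <= 2 * shift.se

    def test_estimate_stays_inside_outcome_bounds(self, discrete_fit):
        *_, shift, natural = discrete_fit
        lo, hi = shift.outcome_bounds
        assert lo <= shift.psi <= hi
        assert lo <= natural.psi <= hi

    def test_bounded_even_under_extreme_weights(self, discrete_instance, fast_library):
        y, fact, cf, _, cov = discrete_instance.sample(400, seed=9)
        wild = DensityRatioPanel(
            ratios=np.random.default_rng(0).lognormal(2, 2, (400, 1))
        )
        res = tmle_policy_mean(
            y, fact, cf, wild, cov, fast_library, folds=3, seed=0,
            outcome_bounds=(0.0, 1.0),
        )
        assert 0.0 <= res.psi <= 1.0

    def test_eif_mean_is_zero_after_targeting(self, discrete_fit):
        *_, shift, natural = discrete_fit
        assert abs(shift.eif_values.mean()) < 1e-6
        assert abs(natural.eif_values.mean()) < 1e-6

    def test_identity_shift_equals_empirical_mean(self, discrete_fit):
        *_, natural = discrete_fit
        assert natural.psi == pytest.approx(natural.empirical_mean, abs=1e-3)

    def test_deterministic_under_fixed_seed(self, discrete_instance, fast_library):
        y, fact, cf, ratios, cov = discrete_instance.sample(800, seed=4)
        kwargs = dict(folds=3, seed=11, outcome_bounds=(0.0, 1.0))
        a = tmle_policy_mean(y, fact, cf, ratios, cov, fast_library, **kwargs)
        b = tmle_policy_mean(y, fact, cf, ratios, cov, fast_library, **kwargs)
        assert a.psi == b.psi
        np.testing.assert_array_equal(a.eif_values, b.eif_values)

    def test_mismatched_ratio_panel_raises(self, discrete_instance, fast_library):
        y, fact, cf, ratios, cov = discrete_instance.sample(100, seed=6)
        bad = DensityRatioPanel(ratios=np.ones((50, 1)))
        with pytest.raises(ValueError, match="ratio panel"):
            tmle_policy_mean(y, fact, cf, bad, cov, fast_library)

    def test_cross_fitted_variant_agrees_with_oracle(
        self, discrete_instance, fast_library
    ):
        y, fact, cf, true_ratios, cov = discrete_instance.sample(5000, seed=13)
        res = tmle_policy_mean(
            y, fact, cf, true_ratios, cov, fast_library, folds=3, seed=1,
            outcome_bounds=(0.0, 1.0), cross_fit=True,
        )
        assert abs(res.psi - discrete_instance.true_shift_mean()) <= 2 * res.se


class TestDoubleRobustness:
    def test_consistent_with_degraded_outcome_model(
        self, discrete_instance
    ):
        # outcome stack reduced to the constant-mean learner; analytic
        # ratios carry the full correction
        y, fact, cf, true_ratios, cov = discrete_instance.sample(5000, seed=23)
        res = tmle_policy_mean(
            y, fact, cf, true_ratios, cov, LearnerLibrary.mean_only(),
            folds=3, seed=0, outcome_bounds=(0.0, 1.0),
        )
        assert abs(res.psi - discrete_instance.true_shift_mean()) <= 2 * res.se

    def test_consistent_with_degraded_ratios(self, discrete_instance, fast_library):
        # ratios forced to 1; the outcome library contains the true
        # (linear) model class
        from heatlmtp.ratios import identity_ratios

        y, fact, cf, _, cov = discrete_instance.sample(5000, seed=29)
        res = tmle_policy_mean(
            y, fact, cf, identity_ratios(5000, 1), cov, fast_library,
            folds=3, seed=0, outcome_bounds=(0.0, 1.0),
        )
        assert abs(res.psi - discrete_instance.true_shift_mean()) <= 2 * res.se


class TestContrast:
    def test_identical_inputs_give_zero_theta_unit_p(self, discrete_fit):
        *_, natural = discrete_fit
        contrast = tmle_contrast(natural, natural)
        assert contrast.theta == 0.0
        assert contrast.p_value == 1.0

    def test_theta_and_ci_consistency(self, discrete_fit):
        *_, shift, natural = discrete_fit
        c = tmle_contrast(shift, natural)
        assert c.theta == pytest.approx(c.psi_shift - c.psi_natural)
        assert c.ci95[0] == pytest.approx(c.theta - 1.96 * c.se_theta)
        assert c.ci95[1] == pytest.approx(c.theta + 1.96 * c.se_theta)
        assert c.back_transformed_shift == pytest.approx(
            back_transform(c.psi_shift)
        )

    def test_eif_difference_variance_bound(self, discrete_fit):
        # Var(phi_s - phi_n) <= Var(phi_s) + Var(phi_n) + 2|Cov|
        *_, shift, natural = discrete_fit
        vs = shift.eif_values.var()
        vn = natural.eif_values.var()
        cov = np.cov(shift.eif_values, natural.eif_values)[0, 1]
        diff_var = (shift.eif_values - natural.eif_values).var()
        assert diff_var <= vs + vn + 2 * abs(cov) + 1e-12

    def test_mismatched_cohorts_raise(self, discrete_instance, fast_library):
        y, fact, cf, ratios, cov = discrete_instance.sample(200, seed=31)
        small = discrete_instance.sample(100, seed=31)
        shift = tmle_policy_mean(
            y, fact, cf, ratios, cov, fast_library, folds=3,
            outcome_bounds=(0.0, 1.0),
        )
        other = tmle_policy_mean(
            small[0], small[1], small[2], small[3], small[4], fast_library,
            folds=3, outcome_bounds=(0.0, 1.0),
        )
        with pytest.raises(ValueError, match="different sizes"):
            tmle_contrast(shift, other)


def test_null_policy_on_cohort_gives_zero_theta(small_cohort, fast_library):
    """k=0 end to end: the counterfactual equals the factual panel, so the
    targeted means coincide exactly."""
    from heatlmtp.exposure import Direction, ShiftPolicy, resolve_threshold
    from heatlmtp.pipeline import COLD_PERCENTILE, build_panels

    temps = small_cohort.overall
    thr = resolve_threshold(temps.ravel(), 0.9)
    cthr = resolve_threshold(temps.ravel(), COLD_PERCENTILE)
    cold = ShiftPolicy(
        threshold_percentile=COLD_PERCENTILE, threshold_value=cthr,
        direction=Direction.BELOW,
    )
    fact = build_panels(
        temps, small_cohort.child_ids, ShiftPolicy(k=0.0, threshold_value=thr), cold
    )
    ratios = truncate(
        estimate_ratios(
            fact, fact, small_cohort.covariates, fast_library, folds=3, seed=0
        ),
        0.999,
    )
    shift = tmle_policy_mean(
        small_cohort.log_outcome, fact, fact, ratios,
        small_cohort.covariates, fast_library, folds=3, seed=1,
    )
    natural = natural_course_mean(
        small_cohort.log_outcome, fact, small_cohort.covariates,
        fast_library, folds=3, seed=1,
    )
    assert abs(tmle_contrast(shift, natural).theta) < 1e-6
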