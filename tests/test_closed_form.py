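"""Closed-form bias expressions against the partial-regression oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from auxbias import (
    Scenario,
    ScenarioError,
    ScenarioSpec,
    amplification_from_observed,
    bias_s1_outcome,
    bias_s3_outcome,
    build_joint_covariance,
    imputation_coef_additional_bias_s3,
    imputation_coef_bias_s2,
    logistic_to_probit,
    oracle_equivalence_sweep,
    partial_regression_coef,
    probit_to_odds_ratio,
    random_spec,
    run_grid_closed_form,
)

NONZERO_EFFECT = st.floats(0.1, 1.5)


class TestS1Outcome:
    def test_null_exposure_effect_gives_no_bias(self):
        spec = ScenarioSpec(Scenario.S1, beta_YX=0, beta_RY=1, beta_RZ=1, pi_obs=0.5)
        b = bias_s1_outcome(spec)
        assert b.max_bias == 0 and b.max_additional_bias == 0
        assert b.max_relative_additional_bias is None

    def test_no_auxiliary_edge_gives_no_additional_bias(self):
        spec = ScenarioSpec(Scenario.S1, beta_YX=1, beta_RY=1, beta_RZ=0, pi_obs=0.5)
        b = bias_s1_outcome(spec)
        assert b.max_additional_bias == 0
        assert b.amplification_factor == 1.0

    def test_unit_parameters_match_oracle_fractions(self, s1_unit):
        b = bias_s1_outcome(s1_unit)
        assert b.coef_limit_no_aux == pytest.approx(2 / 3, abs=1e-12)
        assert b.coef_limit_with_aux == pytest.approx(1 / 2, abs=1e-12)
        assert b.max_additional_bias == pytest.approx(-1 / 6, abs=1e-12)
        assert b.amplification_factor == pytest.approx(1.5, abs=1e-12)

    def test_total_bias_is_sum_of_parts(self, s1_unit):
        b = bias_s1_outcome(s1_unit)
        assert b.max_total_bias == pytest.approx(b.max_bias + b.max_additional_bias)

    @settings(max_examples=100, deadline=None)
    @given(b_yx=NONZERO_EFFECT, b_ry=NONZERO_EFFECT, b_rz=NONZERO_EFFECT)
    def test_attenuation_ordering_when_all_edges_active(self, b_yx, b_ry, b_rz):
        spec = ScenarioSpec(
            Scenario.S1, beta_YX=b_yx, beta_RY=b_ry, beta_RZ=b_rz, pi_obs=0.5
        )
        b = bias_s1_outcome(spec)
        assert abs(b.coef_limit_with_aux) < abs(b.coef_limit_no_aux) < abs(b.beta_true)
        assert b.amplification_factor > 1.0

    @settings(max_examples=100, deadline=None)
    @given(b_yx=NONZERO_EFFECT, b_ry=NONZERO_EFFECT, b_rz=NONZERO_EFFECT)
    def test_sign_antisymmetry_in_exposure_effect(self, b_yx, b_ry, b_rz):
        pos = bias_s1_outcome(
            ScenarioSpec(Scenario.S1, beta_YX=b_yx, beta_RY=b_ry, beta_RZ=b_rz, pi_obs=0.5)
        )
        neg = bias_s1_outcome(
            ScenarioSpec(Scenario.S1, beta_YX=-b_yx, beta_RY=b_ry, beta_RZ=b_rz, pi_obs=0.5)
        )
        assert neg.max_bias == pytest.approx(-pos.max_bias, rel=1e-12)
        assert neg.max_additional_bias == pytest.approx(-pos.max_additional_bias, rel=1e-12)
        assert neg.max_total_bias == pytest.approx(-pos.max_total_bias, rel=1e-12)
        assert neg.amplification_factor == pytest.approx(pos.amplification_factor, rel=1e-12)
        assert neg.max_relative_additional_bias == pytest.approx(
            pos.max_relative_additional_bias, rel=1e-12
        )


class TestS3Outcome:
    def test_reduces_to_s1_when_exposure_missingness_edge_absent(self, s1_unit):
        s3 = ScenarioSpec(Scenario.S3_Y, beta_YX=1, beta_RY=1, beta_RX=0, beta_RZ=1, pi_obs=0.5)
        b3, b1 = bias_s3_outcome(s3), bias_s1_outcome(s1_unit)
        assert b3.max_bias == pytest.approx(b1.max_bias, rel=1e-12)
        assert b3.max_additional_bias == pytest.approx(b1.max_additional_bias, rel=1e-12)

    def test_unit_parameters_max_bias(self, s3y_unit):
        assert bias_s3_outcome(s3y_unit).max_bias == pytest.approx(-2 / 3, abs=1e-12)

    def test_amplification_is_ratio_of_biases(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            spec = random_spec(Scenario.S3_Y, rng)
            b = bias_s3_outcome(spec)
            if abs(b.max_bias) > 1e-9:
                assert b.max_total_bias / b.max_bias == pytest.approx(
                    b.amplification_factor, rel=1e-9
                )

    def test_bias_can_point_away_from_zero(self):
        spec = ScenarioSpec(
            Scenario.S3_Y, beta_YX=1, beta_RY=-0.25, beta_RX=1, beta_RZ=1, pi_obs=0.5
        )
        b = bias_s3_outcome(spec)
        assert b.max_bias > 0  # (beta_RY + beta_RX/beta_YX) < 0 flips the direction
        assert abs(b.coef_limit_no_aux) > abs(b.beta_true)


class TestS2ImputationCoefficient:
    @pytest.mark.parametrize("kwargs", [{"beta_YU": 0.0}, {"beta_RU": 0.0}])
    def test_severed_mnar_pathway_gives_no_bias(self, kwargs):
        spec = ScenarioSpec(
            Scenario.S2_X, beta_YX=1, beta_YU=1, beta_RU=1, beta_RZ=1, pi_obs=0.5
        ).to_dict()
        spec.update(kwargs)
        b = imputation_coef_bias_s2(ScenarioSpec.from_dict(spec))
        assert b.coef_limit_no_aux == pytest.approx(b.beta_true, abs=1e-14)
        assert b.coef_limit_with_aux == pytest.approx(b.beta_true, abs=1e-14)

    def test_no_auxiliary_edge_equalises_both_limits(self):
        spec = ScenarioSpec(
            Scenario.S2_X, beta_YX=1, beta_YU=1, beta_RU=1, beta_RZ=0, pi_obs=0.5
        )
        b = imputation_coef_bias_s2(spec)
        assert b.coef_limit_no_aux == pytest.approx(b.coef_limit_with_aux, abs=1e-14)

    def test_unit_parameters_exact_fractions(self, s2x_unit):
        b = imputation_coef_bias_s2(s2x_unit)
        assert b.beta_true == pytest.approx(1 / 3, abs=1e-12)
        assert b.coef_limit_no_aux == pytest.approx(3 / 8, abs=1e-12)
        assert b.coef_limit_with_aux == pytest.approx(2 / 5, abs=1e-12)

    def test_bias_points_away_from_zero(self, s2x_unit):
        b = imputation_coef_bias_s2(s2x_unit)
        assert abs(b.coef_limit_with_aux) > abs(b.coef_limit_no_aux) > abs(b.beta_true)


class TestS3ImputationCoefficient:
    @pytest.mark.parametrize("zeroed", ["beta_RZ", "beta_RX"])
    def test_vanishes_without_auxiliary_or_exposure_edge(self, zeroed):
        d = ScenarioSpec(
            Scenario.S3_X, beta_YX=1, beta_RY=1, beta_RX=1, beta_RZ=1, pi_obs=0.5
        ).to_dict()
        d[zeroed] = 0.0
        assert imputation_coef_additional_bias_s3(ScenarioSpec.from_dict(d)) == pytest.approx(
            0.0, abs=1e-14
        )

    def test_matches_oracle_difference_at_unit_parameters(self):
        spec = ScenarioSpec(
            Scenario.S3_X, beta_YX=1, beta_RY=1, beta_RX=1, beta_RZ=1, pi_obs=0.5
        )
        jc = build_joint_covariance(spec)
        oracle = (
            partial_regression_coef(jc, "X", ["Y", "Z", "R"])[0]
            - partial_regression_coef(jc, "X", ["Y", "R"])[0]
        )
        assert imputation_coef_additional_bias_s3(spec) == pytest.approx(oracle, rel=1e-12)


class TestOracleEquivalence:
    def test_random_sweep_agrees_to_algebraic_precision(self):
        table = oracle_equivalence_sweep(n_specs=200, seed=3)
        assert set(table["scenario"]) == {"S1", "S3_Y", "S2_X", "S3_X"}
        assert (table["max_rel_error"] < 1e-10).all()


@pytest.fixture(scope="module")
def grid():
    return run_grid_closed_form()


class TestFig2GridProperties:
    """Caption claims about the factorial effect-size grid, asserted exactly."""

    def test_grid_is_full_factorial(self, grid):
        assert len(grid) == 125

    def test_zero_exposure_effect_kills_every_bias_measure(self, grid):
        null = grid[grid.beta_YX == 0]
        assert (null.max_bias == 0).all()
        assert (null.max_additional_bias == 0).all()
        assert (null.max_total_bias == 0).all()

    @pytest.mark.parametrize("effect", ["beta_YX", "beta_RY", "beta_RZ"])
    def test_additional_bias_magnitude_nondecreasing_in_each_effect(self, grid, effect):
        others = [e for e in ("beta_YX", "beta_RY", "beta_RZ") if e != effect]
        for _, g in grid.groupby(others):
            mags = g.sort_values(effect).max_additional_bias.abs().to_numpy()
            assert (np.diff(mags) >= -1e-12).all()

    def test_total_bias_independent_of_auxiliary_edge(self, grid):
        for _, g in grid.groupby(["beta_YX", "beta_RY"]):
            assert g.max_total_bias.nunique() == 1

    def test_relative_additional_bias_independent_of_exposure_effect(self, grid):
        nonnull = grid[grid.beta_YX > 0]
        for _, g in nonnull.groupby(["beta_RY", "beta_RZ"]):
            vals = g.max_relative_additional_bias.to_numpy(dtype=float)
            np.testing.assert_allclose(vals, vals[0], atol=1e-12)


class TestScaleConversions:
    @pytest.mark.parametrize(
        "logit, probit_2dp", [(-0.39, -0.23), (0.44, 0.26), (0.0, 0.0)]
    )
    def test_logistic_to_probit_published_rule(self, logit, probit_2dp):
        assert round(logistic_to_probit(logit), 2) == pytest.approx(probit_2dp)

    @pytest.mark.parametrize(
        "probit, or_1dp",
        [(0.0, 1.0), (0.25, 1.5), (0.5, 2.3), (0.75, 3.5), (1.0, 5.3)],
    )
    def test_probit_to_odds_ratio_published_ladder(self, probit, or_1dp):
        assert round(probit_to_odds_ratio(probit), 1) == pytest.approx(or_1dp)


class TestAppliedAmplification:
    def test_cohort_worked_example_is_one_percent(self):
        factor = amplification_from_observed(-0.23, 0.18, 0.26, 0.25)
        assert factor == pytest.approx(1.0098, abs=5e-5)
        assert round((factor - 1) * 100) == 1

    def test_no_auxiliary_association_means_no_amplification(self):
        assert amplification_from_observed(0.0, 0.18, 0.26, 0.25) == 1.0

    def test_matches_rearranged_form(self):
        rng = np.random.default_rng(5)
        for _ in range(3):
            b_rz, prod = rng.uniform(0.05, 0.4, 2)
            v_z, v_x = rng.uniform(0.1, 0.5, 2)
            direct = amplification_from_observed(b_rz, v_z, prod, v_x)
            zz, xx = b_rz**2 * v_z, prod**2 * v_x
            rearranged = 1 + 1 / (1 / zz - 1 - xx / zz)
            assert direct == pytest.approx(rearranged, rel=1e-12)

    def test_violated_normalisation_raises(self):
        with pytest.raises(ScenarioError, match="normalisation"):
            amplification_from_observed(1.5, 1.0, 0.5, 1.0)
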