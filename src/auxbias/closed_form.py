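"""Exact limiting-bias expressions for the MI estimator under MNAR.

As the fraction of missing values tends to one, the expected value of the
multiple-imputation (MI) estimator of the exposure effect b_YX tends to the
population partial-regression coefficient of the incomplete variable's
imputation target conditional on the imputation predictors *and the latent
missingness score R*.  The functions here evaluate those limits — and the
derived maximum bias, maximum additional bias from adding an auxiliary
variable Z that predicts only missingness, and the bias-amplification factor
— directly in terms of the structural effects and error variances, for each
missingness DAG in :mod:`auxbias.scenarios`.

Every expression is independently checked in the test-suite against
:func:`auxbias.scenarios.partial_regression_coef` applied to the implied
joint covariance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .scenarios import (
    Scenario,
    ScenarioError,
    ScenarioSpec,
    build_joint_covariance,
)

#: Multiplier converting a logistic-regression coefficient to the
#: approximately-equivalent probit (latent-normal) coefficient.
LOGIT_TO_PROBIT = 0.6


@dataclass(frozen=True)
class BiasSummary:
    """Limiting coefficients and bias measures for one scenario spec.

    ``beta_true`` is the estimand (b_YX, or the reverse-regression slope
    b_XY for imputation-coefficient results).  ``coef_limit_no_aux`` and
    ``coef_limit_with_aux`` are the limits of the relevant estimator as the
    missing proportion tends to one, without and with the auxiliary variable
    Z in the conditioning set.  ``max_relative_additional_bias`` is a
    percentage of ``beta_true`` and is ``None`` (never NaN) when the estimand
    is zero.
    """

    beta_true: float
    coef_limit_no_aux: float
    coef_limit_with_aux: float
    max_bias: float
    max_additional_bias: float
    max_total_bias: float
    max_relative_additional_bias: float | None
    amplification_factor: float

    @classmethod
    def from_limits(
        cls,
        beta_true: float,
        coef_limit_no_aux: float,
        coef_limit_with_aux: float,
        amplification_factor: float,
    ) -> "BiasSummary":
        max_bias = coef_limit_no_aux - beta_true
        max_total = coef_limit_with_aux - beta_true
        additional = max_total - max_bias
        relative = None if beta_true == 0.0 else additional * 100.0 / beta_true
        return cls(
            beta_true=beta_true,
            coef_limit_no_aux=coef_limit_no_aux,
            coef_limit_with_aux=coef_limit_with_aux,
            max_bias=max_bias,
            max_additional_bias=additional,
            max_total_bias=max_total,
            max_relative_additional_bias=relative,
            amplification_factor=amplification_factor,
        )

    def to_dict(self) -> dict:
        return {
            "beta_true": self.beta_true,
            "coef_limit_no_aux": self.coef_limit_no_aux,
            "coef_limit_with_aux": self.coef_limit_with_aux,
            "max_bias": self.max_bias,
            "max_additional_bias": self.max_additional_bias,
            "max_total_bias": self.max_total_bias,
            "max_relative_additional_bias": self.max_relative_additional_bias,
            "amplification_factor": self.amplification_factor,
        }


def _require(spec: ScenarioSpec, *allowed: Scenario) -> None:
    if spec.scenario_id not in allowed:
        names = ", ".join(s.value for s in allowed)
        raise ScenarioError(
            f"this bias expression applies to scenario(s) {names}, "
            f"got {spec.scenario_id.value}"
        )


def bias_s1_outcome(spec: ScenarioSpec) -> BiasSummary:
    """Limiting bias when Y is incomplete and missingness is caused by Y.

    The MI estimator of b_YX is attenuated towards zero; conditioning on the
    auxiliary Z shrinks it further because Z explains part of the variance of
    the latent score R, making R a sharper proxy for Y.
    """
    _require(spec, Scenario.S1)
    s = spec
    ry2 = s.beta_RY**2 * s.var_Y
    rz2 = s.beta_RZ**2 * s.var_Z
    no_aux = s.beta_YX * (1.0 - ry2 / (ry2 + rz2 + s.var_R))
    with_aux = s.beta_YX * (1.0 - ry2 / (ry2 + s.var_R))
    amp = 1.0 + rz2 / (ry2 + s.var_R)
    return BiasSummary.from_limits(s.beta_YX, no_aux, with_aux, amp)


def bias_s3_outcome(spec: ScenarioSpec) -> BiasSummary:
    """Limiting bias when Y is incomplete and missingness is caused by Y and X.

    The direct X -> R edge means the bias need not attenuate towards zero: its
    sign follows b_RY*(b_RY + b_RX/b_YX).  The amplification factor from
    adding Z is nonetheless identical to the Y-only-missingness case.
    """
    _require(spec, Scenario.S3_Y)
    s = spec
    d = s.beta_RY**2 * s.var_Y + s.var_R
    rz2 = s.beta_RZ**2 * s.var_Z
    # numerator written as b_RY*(b_YX*b_RY + b_RX) so b_YX = 0 stays finite
    core = s.beta_RY * s.var_Y * (s.beta_YX * s.beta_RY + s.beta_RX)
    max_bias = -core / (d + rz2)
    max_additional = -core * rz2 / ((d + rz2) * d)
    amp = 1.0 + rz2 / d
    return BiasSummary.from_limits(
        s.beta_YX, s.beta_YX + max_bias, s.beta_YX + max_bias + max_additional, amp
    )


def imputation_coef_bias_s2(spec: ScenarioSpec) -> BiasSummary:
    """Limiting bias of the Y coefficient in the imputation model for X.

    When X is incomplete and missingness is linked to Y only through an
    unmeasured U, conditioning on R (being observed) opens the collider path
    X -> Y <- U -> R, inflating the reverse-regression slope b_XY *away* from
    its true value — the opposite orientation to the outcome-missingness case:
    |b_XY|R,Z| > |b_XY|R| > |b_XY|.
    """
    _require(spec, Scenario.S2_X)
    s = spec
    var_y_marg = s.beta_YX**2 * s.var_X + s.beta_YU**2 * s.var_U + s.var_Y
    # true reverse-regression slope, derived from the implied joint moments
    beta_xy = s.beta_YX * s.var_X / var_y_marg
    coupling = s.beta_YU**2 * s.beta_RU**2 * s.var_U**2
    # marginal Var(R) appears in the no-Z limit; conditioning on Z removes
    # Z's contribution and so tightens the shrink factor
    var_r_marg = s.beta_RZ**2 * s.var_Z + s.beta_RU**2 * s.var_U + s.var_R
    var_r_given_z = s.beta_RU**2 * s.var_U + s.var_R
    for name, den in (("marginal", var_r_marg), ("Z-conditional", var_r_given_z)):
        if var_y_marg * den <= coupling:
            raise ScenarioError(
                f"degenerate variances: {name} shrink factor is not positive"
            )
    no_aux = beta_xy / (1.0 - coupling / (var_y_marg * var_r_marg))
    with_aux = beta_xy / (1.0 - coupling / (var_y_marg * var_r_given_z))
    bias_no = no_aux - beta_xy
    bias_with = with_aux - beta_xy
    amp = bias_with / bias_no if bias_no != 0.0 else 1.0
    return BiasSummary.from_limits(beta_xy, no_aux, with_aux, amp)


def imputation_coef_additional_bias_s3(spec: ScenarioSpec) -> float:
    """Maximum additional bias of the Y coefficient imputing X, missingness by Y and X.

    The expression does not simplify; it is evaluated as printed, with the
    b_XY/b_YX ratio expanded so the b_YX = 0 boundary stays finite.
    """
    _require(spec, Scenario.S3_X)
    s = spec
    var_y_marg = s.beta_YX**2 * s.var_X + s.var_Y
    beta_xy = s.beta_YX * s.var_X / var_y_marg
    # beta_xy * beta_RY * var_Y / beta_YX, with beta_YX cancelled exactly
    first = s.beta_RX * (
        s.var_X * s.beta_RY * s.var_Y / var_y_marg
        + beta_xy * s.beta_RX * s.var_X * (1.0 - s.beta_YX**2 * s.var_X / var_y_marg)
    )
    shrink = s.beta_YX**2 * s.beta_RX**2 * s.var_X**2 / var_y_marg
    den_with_z = s.beta_RX**2 * s.var_X + s.beta_RZ**2 * s.var_Z + s.var_R - shrink
    den_no_z = s.beta_RX**2 * s.var_X + s.var_R - shrink
    if den_with_z <= 0 or den_no_z <= 0:
        raise ScenarioError("degenerate variance combination: conditional variance of R <= 0")
    return first * (1.0 / den_with_z - 1.0 / den_no_z)


def bias_summary(spec: ScenarioSpec) -> BiasSummary:
    """Dispatch to the closed form matching ``spec.scenario_id``."""
    if spec.scenario_id is Scenario.S1:
        return bias_s1_outcome(spec)
    if spec.scenario_id is Scenario.S3_Y:
        return bias_s3_outcome(spec)
    if spec.scenario_id is Scenario.S2_X:
        return imputation_coef_bias_s2(spec)
    raise ScenarioError(
        f"no closed-form bias summary for scenario {spec.scenario_id.value}"
    )


def true_beta_yx(spec: ScenarioSpec) -> float:
    """Population slope of the substantive regression of Y on X."""
    jc = build_joint_covariance(spec)
    ix, iy = jc.index("X"), jc.index("Y")
    return float(jc.cov[ix, iy] / jc.cov[ix, ix])


# ---------------------------------------------------------------------------
# scale conversions and the applied amplification estimator
# ---------------------------------------------------------------------------

def logistic_to_probit(coef: float) -> float:
    """Approximate probit-scale coefficient for a logistic coefficient (x 0.6)."""
    return LOGIT_TO_PROBIT * coef


def probit_to_odds_ratio(coef: float) -> float:
    """Odds ratio implied by a probit-scale coefficient, exp(coef / 0.6)."""
    return math.exp(coef / LOGIT_TO_PROBIT)


def amplification_from_observed(
    beta_RZ: float,
    var_Z: float,
    beta_RY_times_beta_YX: float,
    var_X: float,
) -> float:
    """Maximum bias amplification from observable quantities.

    Working version of the Y-missingness amplification factor for applied
    use, normalising the latent score R to mean 0 and variance 1 (without
    loss of generality):

        1 + b_RZ^2 s2_Z / (1 - b_RZ^2 s2_Z - (b_RY b_YX)^2 s2_X)

    ``beta_RZ`` and ``beta_RY_times_beta_YX`` are probit-scale coefficients
    (in practice 0.6 x the logistic coefficients of Z and X from a regression
    of the missingness indicator on Z, X and confounders); ``var_Z`` and
    ``var_X`` are the marginal variances of Z and X.  The two squared terms
    are the squared correlations of Z and X with the latent missingness
    score, so their sum must stay below one.
    """
    z_term = beta_RZ**2 * var_Z
    x_term = beta_RY_times_beta_YX**2 * var_X
    denom = 1.0 - z_term - x_term
    if denom <= 0:
        raise ScenarioError(
            "squared correlations with the latent missingness score sum to >= 1; "
            "the Var(R)=1 normalisation is violated — check the inputs' scale"
        )
    return 1.0 + z_term / denom
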