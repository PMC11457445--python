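"""Proper multiple imputation, Rubin's-rules pooling, and the CRA comparator.

Missing values of the single incomplete variable are replaced by draws from
a fitted regression model — linear for a continuous variable, logistic for a
binary one — after first perturbing the fitted parameters (linear: scaled
inverse-chi-square draw of the residual variance, then a normal draw of the
coefficients; logistic: a normal draw from the asymptotic posterior
approximation).  With exactly one incomplete variable this single
conditional draw is a valid draw from the joint distribution, so no
chained-equations iteration is needed.  The M completed-data analysis
estimates are pooled with Rubin's rules:

    pooled estimate = mean of the M estimates
    pooled variance = W + (1 + 1/M) B

with W the mean within-imputation variance and B the between-imputation
variance of the estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .scenarios import ScenarioError
from .simulate import SimDataset

_ALLOWED_PREDICTORS = {"X", "Y", "Z"}


class MIError(RuntimeError):
    """Failure inside the imputation engine (separation, rank deficiency...)."""


@dataclass(frozen=True)
class ImputationModelFit:
    """Imputation model fitted to the complete records only."""

    coefficients: np.ndarray          # intercept first, then `predictors`
    residual_variance: float | None   # linear family only
    coef_covariance: np.ndarray
    family: str                       # "linear" | "logistic"
    predictors: tuple[str, ...]
    target: str
    n_obs: int

    @property
    def n_params(self) -> int:
        return len(self.coefficients)


@dataclass(frozen=True)
class MIPooledEstimate:
    """Per-imputation slopes and their Rubin's-rules pool."""

    m: int
    estimates: np.ndarray
    within_variance: float
    between_variance: float
    pooled_estimate: float
    pooled_variance: float

    @property
    def pooled_se(self) -> float:
        return float(np.sqrt(self.pooled_variance))


def _design(data: SimDataset, predictors: Sequence[str]) -> np.ndarray:
    cols = [np.ones(data.n)]
    cols.extend(data.column(p) for p in predictors)
    return np.column_stack(cols)


def _ols(design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least squares returning (coef, coef covariance, residual variance)."""
    n, p = design.shape
    if n < p + 2:
        raise MIError(f"too few records ({n}) to fit {p} coefficients")
    xtx = design.T @ design
    if np.linalg.cond(xtx) > 1e12:
        raise MIError("rank-deficient design matrix in regression fit")
    xtx_inv = np.linalg.inv(xtx)
    coef = xtx_inv @ (design.T @ y)
    resid = y - design @ coef
    sigma2 = float(resid @ resid) / (n - p)
    return coef, sigma2 * xtx_inv, sigma2


def _logit(design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Logit(y, design).fit(disp=0)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise MIError(
                "perfect separation in the logistic fit: a predictor splits the "
                "outcome exactly, so maximum-likelihood estimates do not exist"
            ) from exc
        except np.linalg.LinAlgError as exc:
            raise MIError("rank-deficient design matrix in logistic fit") from exc
    return np.asarray(res.params), np.asarray(res.cov_params())


def fit_imputation_model(
    data: SimDataset, predictors: Sequence[str]
) -> ImputationModelFit:
    """Fit the imputation model for the incomplete variable on complete records.

    The regression family follows the incomplete variable's type: ordinary
    least squares when continuous, maximum-likelihood logistic when binary.
    U (and the latent missingness score) can never appear as predictors.
    """
    preds = tuple(p.upper() for p in predictors)
    bad = set(preds) - _ALLOWED_PREDICTORS
    if bad:
        raise ScenarioError(f"predictors must come from X, Y, Z; got {sorted(bad)}")
    target = data.incomplete_var
    if target in preds:
        raise ScenarioError(f"incomplete variable {target} cannot predict itself")
    obs = data.r_ind == 1
    n_obs = int(obs.sum())
    if n_obs < len(preds) + 2:
        raise MIError(f"only {n_obs} observed records for {len(preds)} predictors")

    spec = data.spec
    target_type = spec.y_type if target == "Y" else spec.x_type
    design = _design(data, preds)[obs]
    y = data.column(target)[obs]
    if target_type == "binary":
        coef, cov = _logit(design, y)
        return ImputationModelFit(coef, None, cov, "logistic", preds, target, n_obs)
    coef, cov, sigma2 = _ols(design, y)
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny  # exact-fit toy data
    return ImputationModelFit(coef, sigma2, cov, "linear", preds, target, n_obs)


def draw_and_impute(
    fit: ImputationModelFit,
    data: SimDataset,
    seed: int | np.random.Generator,
    *,
    perturb: bool = True,
    noise: bool = True,
) -> np.ndarray:
    """One proper imputation pass; returns the completed target vector.

    Linear family: draw sigma*^2 = sigma_hat^2 nu / chi2_nu with
    nu = n_obs - p, then beta* ~ N(beta_hat, (sigma*^2/sigma_hat^2) V_hat),
    and impute each missing value as its linear predictor under beta* plus
    N(0, sigma*^2) noise.  Logistic family: beta* ~ N(beta_hat, V_hat), then
    Bernoulli draws at the inverse-logit probabilities.  ``perturb`` and
    ``noise`` are test hooks that collapse the respective draw to its mean.
    """
    if fit.target != data.incomplete_var:
        raise ScenarioError("fit and dataset disagree about the incomplete variable")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    completed = data.column(fit.target).astype(float).copy()
    missing = data.r_ind == 0
    if not missing.any():
        return completed
    design_mis = _design(data, fit.predictors)[missing]

    if fit.family == "linear":
        nu = fit.n_obs - fit.n_params
        if perturb:
            sigma2_star = fit.residual_variance * nu / rng.chisquare(nu)
            scale = sigma2_star / fit.residual_variance
            beta_star = rng.multivariate_normal(
                fit.coefficients, scale * fit.coef_covariance, method="svd"
            )
        else:
            sigma2_star = fit.residual_variance
            beta_star = fit.coefficients
        mean = design_mis @ beta_star
        if noise:
            mean = mean + rng.normal(0.0, np.sqrt(sigma2_star), size=mean.shape)
        completed[missing] = mean
    else:
        if perturb:
            beta_star = rng.multivariate_normal(
                fit.coefficients, fit.coef_covariance, method="svd"
            )
        else:
            beta_star = fit.coefficients
        prob = 1.0 / (1.0 + np.exp(-(design_mis @ beta_star)))
        if noise:
            completed[missing] = (rng.random(prob.shape) < prob).astype(float)
        else:
            completed[missing] = (prob > 0.5).astype(float)
    return completed


def _analysis_fit(
    y: np.ndarray, x: np.ndarray, family: str
) -> tuple[float, float]:
    """Slope of Y on X (with intercept) and its conventional variance."""
    design = np.column_stack([np.ones_like(x), x])
    if family == "logistic":
        coef, cov = _logit(design, y)
        return float(coef[1]), float(cov[1, 1])
    coef, cov, _ = _ols(design, y)
    return float(coef[1]), float(cov[1, 1])


def pool_rubin(estimates: Sequence[float], variances: Sequence[float]) -> MIPooledEstimate:
    """Rubin's rules for a scalar estimand."""
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    m = len(est)
    if m < 2:
        raise ScenarioError("Rubin pooling requires m >= 2 imputations")
    w = float(var.mean())
    b = float(est.var(ddof=1))
    return MIPooledEstimate(
        m=m,
        estimates=est,
        within_variance=w,
        between_variance=b,
        pooled_estimate=float(est.mean()),
        pooled_variance=w + (1.0 + 1.0 / m) * b,
    )


def mi_estimate(
    data: SimDataset,
    imputation_predictors: Sequence[str],
    m: int,
    seed: int,
    analysis_family: str = "linear",
) -> MIPooledEstimate:
    """Multiply impute, analyse each completed dataset, pool by Rubin's rules.

    The substantive analysis is the regression of Y on X; its slope is the
    estimand.  One imputation-model fit feeds m independent draw-and-impute
    passes (valid here because exactly one variable is incomplete).
    """
    if m < 2:
        raise ScenarioError("m must be at least 2")
    fit = fit_imputation_model(data, imputation_predictors)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1000,)))
    estimates, variances = [], []
    for _ in range(m):
        completed = draw_and_impute(fit, data, rng)
        y = completed if fit.target == "Y" else data.y
        x = completed if fit.target == "X" else data.x
        slope, var = _analysis_fit(y, x, analysis_family)
        estimates.append(slope)
        variances.append(var)
    return pool_rubin(estimates, variances)


def cra_estimate(
    data: SimDataset, analysis_family: str = "linear"
) -> tuple[float, float]:
    """Complete-records slope of Y on X and its standard error."""
    obs = data.r_ind == 1
    if int(obs.sum()) < 3:
        raise MIError("complete-records analysis needs at least 3 complete records")
    slope, var = _analysis_fit(data.y[obs], data.x[obs], analysis_family)
    return slope, float(np.sqrt(var))
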