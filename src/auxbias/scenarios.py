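"""Scenario parameterisation and implied joint moments.

Three directed acyclic graphs (DAGs) describe how a continuous outcome Y,
exposure X, auxiliary variable Z, optional unmeasured variable U, and a
latent-normal missingness score R relate:

* ``S1``   — missingness caused by Y itself (Y partially observed):
             Y = b_YX X + e_Y,  R = b_RY Y + b_RZ Z + e_R.
* ``S2_Y`` / ``S2_X`` — missingness related to Y only through unmeasured U
             (Y or X partially observed):
             Y = b_YX X + b_YU U + e_Y,  R = b_RZ Z + b_RU U + e_R.
* ``S3_Y`` / ``S3_X`` — missingness caused by both Y and X
             (Y or X partially observed):
             Y = b_YX X + e_Y,  R = b_RY Y + b_RX X + b_RZ Z + e_R.

X, Z, U are exogenous normals; all structural errors are independent.  Every
scenario is represented over the full variable set (X, Z, U, Y, R) with the
coefficients absent from its DAG pinned to zero, so a single covariance
constructor — and a single partial-regression oracle built on it — serves all
three models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

VARIABLES: tuple[str, ...] = ("X", "Z", "U", "Y", "R")

# relative floor for the smallest covariance eigenvalue
_PSD_RTOL = 1e-8


class Scenario(str, Enum):
    """Which DAG, and which analysis variable is partially observed."""

    S1 = "S1"        # missingness caused by Y; Y incomplete
    S2_Y = "S2_Y"    # missingness via unmeasured U; Y incomplete
    S2_X = "S2_X"    # missingness via unmeasured U; X incomplete
    S3_Y = "S3_Y"    # missingness caused by Y and X; Y incomplete
    S3_X = "S3_X"    # missingness caused by Y and X; X incomplete

    @property
    def incomplete_variable(self) -> str:
        return "X" if self.value.endswith("_X") else "Y"

    @property
    def has_u(self) -> bool:
        return self.value.startswith("S2")


# coefficients a scenario's DAG forces to zero
_FORCED_ZERO: dict[Scenario, tuple[str, ...]] = {
    Scenario.S1: ("beta_YU", "beta_RX", "beta_RU"),
    Scenario.S2_Y: ("beta_RY", "beta_RX"),
    Scenario.S2_X: ("beta_RY", "beta_RX"),
    Scenario.S3_Y: ("beta_YU", "beta_RU"),
    Scenario.S3_X: ("beta_YU", "beta_RU"),
}


class ScenarioError(ValueError):
    """Invalid scenario parameterisation."""


@dataclass(frozen=True)
class ScenarioSpec:
    """Complete parameterisation of one missingness DAG.

    Direct effects ``beta_AB`` read "effect of B on A"; ``var_*`` are the
    structural *error* variances (for exogenous X, Z, U this is the marginal
    variance); ``pi_obs`` is the marginal probability that the incomplete
    variable is observed, P(R_ind = 1) = P(R <= r).
    """

    scenario_id: Scenario
    beta_YX: float = 0.0
    beta_YU: float = 0.0
    beta_RY: float = 0.0
    beta_RX: float = 0.0
    beta_RZ: float = 0.0
    beta_RU: float = 0.0
    var_Y: float = 1.0
    var_X: float = 1.0
    var_Z: float = 1.0
    var_U: float = 1.0
    var_R: float = 1.0
    mu_X: float = 0.0
    mu_Z: float = 0.0
    mu_U: float = 0.0
    pi_obs: float = 1.0
    y_type: str = "continuous"
    x_type: str = "continuous"
    y_prevalence: float = 0.5
    x_prevalence: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "scenario_id", Scenario(self.scenario_id))
        for name in ("var_Y", "var_X", "var_Z", "var_U", "var_R"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ScenarioError(f"{name} must be strictly positive, got {v!r}")
        if not 0.0 < self.pi_obs <= 1.0:
            raise ScenarioError(f"pi_obs must lie in (0, 1], got {self.pi_obs!r}")
        for name in ("y_type", "x_type"):
            if getattr(self, name) not in ("continuous", "binary"):
                raise ScenarioError(f"{name} must be 'continuous' or 'binary'")
        for name in ("y_prevalence", "x_prevalence"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ScenarioError(f"{name} must lie in (0, 1), got {p!r}")
        for name in _FORCED_ZERO[self.scenario_id]:
            if getattr(self, name) != 0.0:
                raise ScenarioError(
                    f"{name} must be zero under scenario {self.scenario_id.value}: "
                    f"the DAG has no such edge"
                )

    # -- serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scenario_id"] = self.scenario_id.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ScenarioError(f"unknown ScenarioSpec keys: {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ScenarioSpec":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class JointCovariance:
    """Model-implied mean vector and covariance of (X, Z, U, Y, R)."""

    means: np.ndarray
    cov: np.ndarray
    order: tuple[str, ...] = VARIABLES

    def __post_init__(self) -> None:
        means = np.asarray(self.means, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        if means.shape != (5,) or cov.shape != (5, 5):
            raise ScenarioError("JointCovariance requires a length-5 mean and 5x5 cov")
        if not np.allclose(cov, cov.T, atol=1e-12):
            raise ScenarioError("covariance matrix is not symmetric")
        eig = np.linalg.eigvalsh(cov)
        if eig[0] < -_PSD_RTOL * max(eig[-1], 1.0):
            raise ScenarioError(f"covariance not positive semidefinite (min eig {eig[0]:g})")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "cov", cov)

    def index(self, name: str) -> int:
        try:
            return self.order.index(name)
        except ValueError:
            raise ScenarioError(f"unknown variable {name!r}; choose from {self.order}") from None

    def mean_of(self, name: str) -> float:
        return float(self.means[self.index(name)])

    def var_of(self, name: str) -> float:
        i = self.index(name)
        return float(self.cov[i, i])


def build_joint_covariance(spec: ScenarioSpec) -> JointCovariance:
    """Implied second-moment structure of (X, Z, U, Y, R).

    Each variable is written as a linear map of the independent sources
    (X, Z, U, e_Y, e_R); the covariance is then A diag(source variances) Aᵀ,
    which is path-tracing in matrix form and exact for any coefficient values.
    """
    s = spec
    # rows: X, Z, U, Y, R; columns: sources X, Z, U, e_Y, e_R
    a = np.array(
        [
            [1.0, 0.0, 0.0, 0.0, 0.0],
            [0.0, 1.0, 0.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.0, 0.0],
            [s.beta_YX, 0.0, s.beta_YU, 1.0, 0.0],
            [
                s.beta_RY * s.beta_YX + s.beta_RX,
                s.beta_RZ,
                s.beta_RY * s.beta_YU + s.beta_RU,
                s.beta_RY,
                1.0,
            ],
        ]
    )
    src_var = np.array([s.var_X, s.var_Z, s.var_U, s.var_Y, s.var_R])
    cov = (a * src_var) @ a.T
    mu_Y = s.beta_YX * s.mu_X + s.beta_YU * s.mu_U
    mu_R = s.beta_RY * mu_Y + s.beta_RX * s.mu_X + s.beta_RZ * s.mu_Z + s.beta_RU * s.mu_U
    means = np.array([s.mu_X, s.mu_Z, s.mu_U, mu_Y, mu_R])
    return JointCovariance(means=means, cov=cov)


def partial_regression_coef(
    jc: JointCovariance, target: str, predictors: Sequence[str]
) -> np.ndarray:
    """Population least-squares slopes of ``target`` on ``predictors``.

    Solves Sigma_pp b = sigma_pt, the normal equations in the model-implied
    moments.  This is the independent oracle for every closed-form limiting
    coefficient: e.g. the S1 limit "Y on X given R" is
    ``partial_regression_coef(jc, "Y", ["X", "R"])[0]``.
    """
    names = list(predictors)
    if target in names or len(set(names)) != len(names):
        raise ScenarioError("target and predictors must be distinct variable names")
    ti = jc.index(target)
    pi = [jc.index(p) for p in names]
    spp = jc.cov[np.ix_(pi, pi)]
    spt = jc.cov[pi, ti]
    # reject numerically singular predictor blocks with the offending set named
    cond = np.linalg.cond(spp)
    if not np.isfinite(cond) or cond > 1e12:
        raise ScenarioError(f"collinear / degenerate predictor set {names} (cond={cond:.3g})")
    return np.linalg.solve(spp, spt)
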