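"""Synthetic datasets from the missingness DAGs.

Data are drawn from the structural equations of a :class:`ScenarioSpec`:
exogenous X, Z, U ~ normal, Y from its linear structural equation, and the
latent missingness score R from its own.  A value is *observed* when
R <= r, where the threshold r = mu_R + sqrt(V_R) * Phi^{-1}(pi_obs) is taken
from the model-implied moments of R, so P(observed) = pi_obs exactly in the
population (no per-sample calibration).

Binary Y or X is produced by thresholding the latent continuous variable at
the population quantile matching the target prevalence, *after* the
structural equations and missingness score have been formed on the latent
scale.  U is generated (where the DAG has it) but is never handed to any
imputation or analysis model — it plays the "unmeasured" role.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .scenarios import (
    ScenarioError,
    ScenarioSpec,
    build_joint_covariance,
)

_MIN_N = 10


@dataclass(frozen=True)
class SimDataset:
    """One generated sample plus its missingness mask.

    ``r_ind`` is 1 where the incomplete variable is observed.  ``u`` and
    ``r_latent`` are retained for diagnostics only and must never enter an
    imputation or analysis model.
    """

    n: int
    y: np.ndarray
    x: np.ndarray
    z: np.ndarray
    u: np.ndarray
    r_latent: np.ndarray
    r_ind: np.ndarray
    incomplete_var: str
    seed: int
    spec: ScenarioSpec

    def column(self, name: str) -> np.ndarray:
        return {"Y": self.y, "X": self.x, "Z": self.z, "U": self.u}[name.upper()]

    @property
    def n_observed(self) -> int:
        return int(self.r_ind.sum())

    def to_frame(self, debug: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(
            {"y": self.y, "x": self.x, "z": self.z, "r_ind": self.r_ind}
        )
        if debug:
            df["u"] = self.u
            df["r_latent"] = self.r_latent
        return df

    def to_csv(self, path: str | Path, debug: bool = False) -> None:
        self.to_frame(debug=debug).to_csv(path, index=False)


def _substream(seed: int, *key: int) -> np.random.Generator:
    """Independent generator for (seed, key...) via SeedSequence spawn keys."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def dichotomize(
    values: np.ndarray,
    prevalence: float,
    *,
    mean: float = 0.0,
    sd: float = 1.0,
) -> np.ndarray:
    """Threshold a latent-normal variable to 0/1 with a target prevalence.

    The cut is the population (1 - prevalence) quantile of the variable's
    marginal normal law N(mean, sd^2) — not a sample quantile — so the
    expected prevalence is exact and independent of n.
    """
    if not 0.0 < prevalence < 1.0:
        raise ScenarioError(f"prevalence must lie in (0, 1), got {prevalence!r}")
    if sd <= 0 or not np.isfinite(sd):
        raise ScenarioError("degenerate (zero-variance) variable cannot be dichotomised")
    cut = stats.norm.ppf(1.0 - prevalence, loc=mean, scale=sd)
    return (np.asarray(values, dtype=float) > cut).astype(np.int64)


def generate(spec: ScenarioSpec, n: int, seed: int) -> SimDataset:
    """Draw one dataset of size ``n`` from the scenario's structural model.

    Deterministic given (spec, n, seed); the five random sources use
    independent substreams of ``seed`` so that e.g. enlarging n or switching
    a variable to binary does not reshuffle the others.
    """
    if n < _MIN_N:
        raise ScenarioError(f"n must be at least {_MIN_N}, got {n}")
    s = spec
    x = s.mu_X + np.sqrt(s.var_X) * _substream(seed, 0).standard_normal(n)
    z = s.mu_Z + np.sqrt(s.var_Z) * _substream(seed, 1).standard_normal(n)
    if s.scenario_id.has_u:
        u = s.mu_U + np.sqrt(s.var_U) * _substream(seed, 2).standard_normal(n)
    else:
        u = np.zeros(n)
    e_y = np.sqrt(s.var_Y) * _substream(seed, 3).standard_normal(n)
    e_r = np.sqrt(s.var_R) * _substream(seed, 4).standard_normal(n)

    y = s.beta_YX * x + s.beta_YU * u + e_y
    r = s.beta_RY * y + s.beta_RX * x + s.beta_RZ * z + s.beta_RU * u + e_r

    jc = build_joint_covariance(s)
    if s.pi_obs >= 1.0:
        r_ind = np.ones(n, dtype=np.int64)
    else:
        cut = jc.mean_of("R") + np.sqrt(jc.var_of("R")) * stats.norm.ppf(s.pi_obs)
        r_ind = (r <= cut).astype(np.int64)

    # dichotomisation happens last: structure and missingness live on the
    # latent scale, imputation only ever sees the binary version
    if s.y_type == "binary":
        y = dichotomize(
            y, s.y_prevalence, mean=jc.mean_of("Y"), sd=np.sqrt(jc.var_of("Y"))
        ).astype(float)
    if s.x_type == "binary":
        x = dichotomize(
            x, s.x_prevalence, mean=jc.mean_of("X"), sd=np.sqrt(jc.var_of("X"))
        ).astype(float)

    return SimDataset(
        n=n,
        y=y,
        x=x,
        z=z,
        u=u,
        r_latent=r,
        r_ind=r_ind,
        incomplete_var=s.scenario_id.incomplete_variable,
        seed=seed,
        spec=s,
    )


def dataset_from_frame(
    df: pd.DataFrame,
    incomplete_var: str = "Y",
    var_type: str = "continuous",
) -> SimDataset:
    """Wrap an external table (columns y, x, z, r_ind) as a SimDataset.

    Used by the command-line ``impute`` path; the attached stub spec only
    records which variable is incomplete and whether it is binary, which is
    all the imputation engine consults.
    """
    required = {"y", "x", "z", "r_ind"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ScenarioError(f"dataset is missing columns {sorted(missing_cols)}")
    incomplete_var = incomplete_var.upper()
    if incomplete_var not in ("Y", "X"):
        raise ScenarioError("incomplete_var must be 'Y' or 'X'")
    from .scenarios import Scenario

    stub = ScenarioSpec(
        scenario_id=Scenario.S1 if incomplete_var == "Y" else Scenario.S3_X,
        y_type=var_type if incomplete_var == "Y" else "continuous",
        x_type=var_type if incomplete_var == "X" else "continuous",
    )
    n = len(df)
    return SimDataset(
        n=n,
        y=df["y"].to_numpy(dtype=float),
        x=df["x"].to_numpy(dtype=float),
        z=df["z"].to_numpy(dtype=float),
        u=np.zeros(n),
        r_latent=np.zeros(n),
        r_ind=df["r_ind"].to_numpy(dtype=np.int64),
        incomplete_var=incomplete_var,
        seed=-1,
        spec=stub,
    )


def true_structural_params(spec: ScenarioSpec) -> dict[str, float]:
    """Generating values needed downstream, keyed by field name."""
    return {
        "beta_YX": spec.beta_YX,
        "beta_YU": spec.beta_YU,
        "beta_RY": spec.beta_RY,
        "beta_RX": spec.beta_RX,
        "beta_RZ": spec.beta_RZ,
        "beta_RU": spec.beta_RU,
        "var_Y": spec.var_Y,
        "var_X": spec.var_X,
        "var_Z": spec.var_Z,
        "var_U": spec.var_U,
        "var_R": spec.var_R,
        "pi_obs": spec.pi_obs,
    }
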