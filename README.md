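# auxbias

Quantify how much **extra** bias a multiple-imputation (MI) estimator picks up
when the imputation model includes an auxiliary variable that predicts
*missingness* but not the missing *values*, and the data are missing not at
random (MNAR).

## The problem

Epidemiological practice often recommends an "inclusive" strategy for
imputation models: add every variable thought to predict the missing values
and/or their missingness. When data are MNAR, that advice can backfire. If an
auxiliary variable Z causes missingness but is independent of the partially
observed variable, conditioning on Z in the imputation model makes the latent
missingness mechanism a *sharper* proxy for the unobserved values, and the MI
estimate moves further from the truth — bias amplification, the missing-data
analogue of bias amplification by instruments in unmeasured confounding.

`auxbias` makes this precise for three latent-normal missingness DAGs over an
outcome Y, exposure X, auxiliary Z, optional unmeasured U, and a latent
missingness score R (a value is observed when R ≤ r, with
π₁ = P(R ≤ r) the observed fraction):

| scenario | structural model | incomplete |
|---|---|---|
| `S1`   | Y = β_YX X + ε_Y;  R = β_RY Y + β_RZ Z + ε_R | Y |
| `S2_Y` / `S2_X` | Y = β_YX X + β_YU U + ε_Y;  R = β_RZ Z + β_RU U + ε_R | Y or X |
| `S3_Y` / `S3_X` | Y = β_YX X + ε_Y;  R = β_RY Y + β_RX X + β_RZ Z + ε_R | Y or X |

The package provides, for each scenario:

* **Closed forms** for the limiting value of the MI estimator of β_YX as the
  missing fraction tends to one, with and without Z in the imputation model —
  e.g. for `S1`

      β_YX|R   = β_YX · {1 − β²_RY σ²_Y / (β²_RY σ²_Y + β²_RZ σ²_Z + σ²_R)}
      β_YX|Z,R = β_YX · {1 − β²_RY σ²_Y / (β²_RY σ²_Y + σ²_R)}

  and the amplification factor 1 + β²_RZ σ²_Z / (β²_RY σ²_Y + σ²_R), plus the
  analogous reverse-regression (imputation-coefficient) results when X is the
  incomplete variable.
* **An independent oracle**: the implied joint covariance of (X, Z, U, Y, R)
  by path tracing, and population partial-regression coefficients from it.
  Every closed form is tested against this oracle to 1e-10 relative error.
* **A simulation engine**: latent-normal data generation (optionally
  dichotomised Y or X), proper multiple imputation (posterior-perturbed
  linear or logistic draws), Rubin's-rules pooling, complete-records analysis
  (CRA), and Monte-Carlo study orchestration.
* **An applied estimator**: the amplification factor from four observable
  scalars (probit-scale missingness-model coefficients and two variances),
  for use with real cohort data.

## Worked example

The canonical unit-parameter `S1` configuration (all active effects and error
variances 1, half the outcome values missing):

```python
import auxbias as ab

spec = ab.ScenarioSpec("S1", beta_YX=1, beta_RY=1, beta_RZ=1, pi_obs=0.5)
print(ab.bias_s1_outcome(spec).to_dict())
```

prints (exact fractions):

```
beta_true                       1
coef_limit_no_aux               0.6666666666666667
coef_limit_with_aux             0.5
max_bias                       -0.33333333333333326
max_additional_bias            -0.16666666666666674
max_total_bias                 -0.5
max_relative_additional_bias  -16.666666666666675
amplification_factor            1.5
```

Read: with only the exposure X in the imputation model, the worst-case MI
estimate of β_YX = 1 is 2/3 (bias −1/3, towards the null); adding the
missingness-only auxiliary Z drags it to 1/2 — an extra −1/6, i.e. the MNAR
bias is amplified by a factor 1.5. At 50% missingness the Monte-Carlo study

```python
res = ab.run_mc_study(spec, n=5000, replicates=200, m=10, seed=7)
print(res.mi_bias_no_aux, res.mi_bias_with_aux, res.additional_bias)
```

gives `-0.187  -0.232  -0.0446` (Monte-Carlo SE ≈ 0.0015): the finite-missingness
additional bias sits between zero and the −1/6 supremum, as it must.

The applied estimator, with the published cohort inputs (probit-scale
coefficients −0.23 for the auxiliary and 0.26 for the exposure, variances
0.18 and 0.25):

```
$ auxbias amplify --beta-rz -0.23 --var-z 0.18 --prod-ryx 0.26 --var-x 0.25
maximum bias amplification factor: 1.0098
bias amplified by 0.98% towards the direction of the existing bias
```

— about a 1% amplification: in that setting the auxiliary is roughly as
predictive of missingness as the exposure, so including it is nearly harmless.

Other CLI subcommands: `bias` (closed-form summary for a JSON scenario
config), `impute` (MI over a CSV), `study` (Monte-Carlo bias study), `verify`
(oracle-equivalence sweep), `limits` (convergence along a decreasing-π₁
path), `fixtures` (deterministic example datasets).

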