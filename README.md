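# lnireg

Bayesian multivariate regression for **positive, skewed, heavy-tailed
response vectors with missing values**, with marginal quantile (growth
curve) estimation.

`lnireg` is aimed at biostatisticians and epidemiologists who need to
relate several correlated positive outcomes — e.g. a child's arm
circumference, weight and length — to covariates such as age, gender and
breastfeeding duration, when any response cell may be missing and the
data carry outliers. It fits the multivariate
**log-normal/independent (LNI)** family of linear regression models

```
Y_i | B, Ψ, w_i ~ LN_p( exp(B′x_i), Ψ / w_i ),   w_i ~ H(w | ν),
```

where the latent positive weight `w_i` selects the member: degenerate
(log-normal), `Gamma(ν/2, ν/2)` (log-*t*), or `Beta(ν, 1)` (log-slash).
On the log scale this is a normal/independent (scale-mixture-of-normals)
regression, so outlying cases are automatically down-weighted when ν is
small. Posterior inference uses a **monotone data augmentation (MDA)
Gibbs sampler**: the response matrix is arranged into a monotone missing
pattern, only the minimal *fill-in* cells are ever imputed, and (B, Ψ)
are drawn jointly and exactly from the factorized
normal–inverse-Wishart-type posterior.

The payoff is direct quantile modelling: the α quantile of response *k*
at covariates *x* is

```
ŷ_{k,α} = exp( Σ_j β̂_jk x_j + √ψ̂_kk · q̂_α ),
```

with `q̂_α` the standard NI quantile at the fitted ν̂ — medians depend on
covariates alone, and a unit covariate increase multiplies every
quantile by `exp(β̂_jk)`, so fitted percentile curves never cross.

## Worked example

Simulate a 173-child anthropometric dataset from the package's default
study design (trivariate log-slash responses; realized missing cells
59/11/6 across arm circumference, weight, length) and fit it:

```python
import numpy as np
from lnireg import (SimulationDesign, make_dataset, run_mda, ModelSpec,
                    Parameters, quantile_curves)

design = SimulationDesign(n=173, family="log-slash", seed=42)
data = make_dataset(design, np.random.default_rng(42))
draws = run_mda(data, ModelSpec("log-slash"),
                iterations=3000, burn_in=500, seed=7)
s = draws.summarize()
print(s.coefficient_table().round(4))
```

```
         response     covariate  estimate   lower  upper
arm_circumference     intercept    2.4628  2.4105 2.5122
arm_circumference           age    0.0362  0.0196 0.0520
...
           weight           age    0.2275  0.2060 0.2491
           weight breastfeeding    0.0045  0.0008 0.0081
           length           age    0.1230  0.1124 0.1341
           length breastfeeding    0.0020  0.0002 0.0038
```

Each row is a posterior median with its equal-tail 95% credible
interval; an interval excluding zero (e.g. age on weight: 0.2275,
interval (0.2060, 0.2491)) signals a credible effect —
`exp(0.2275) ≈ 1.26`, i.e. each additional year of age raises every
weight quantile by about 26%. The fitted tail parameter
`ν̂ = 1.98 (1.33, 3.54)` is small: the fit is consistent with a
heavy-tailed, outlier-prone population. Growth curves come from the
fitted medians:

```python
p = Parameters(B=s.B_median, Psi=s.Psi_median, nu=s.nu_median)
curve = quantile_curves(p, "log-slash", k=1, varying=1,
                        grid=[1.0, 2.0, 3.0],
                        fixed=np.array([1.0, 0.0, 0.0, 9.18]),
                        alphas=(0.05, 0.5, 0.95))
print(curve.to_frame().round(2))
```

```
 grid  alpha  quantile
  1.0   0.05      5.52
  1.0   0.50      7.23
  1.0   0.95      9.48
  2.0   0.50      9.08
  3.0   0.50     11.40
```

— the 5th/50th/95th weight percentiles (kg) for girls at ages 1–3 years
with breastfeeding fixed at 9.18 weeks.

The same operations are available from the shell:

```
lnireg fit data.csv --responses arm,weight,length \
    --covariates age,gender,breastfeeding --family log-slash --seed 1
lnireg quantiles summary.json --response 1 --varying 1 \
    --grid 0.5,1,2,3,4 --fixed 1,1,0,9.18 --stratify-gender 2
lnireg simulate --n 150 --seed 1
lnireg study --n 150 -M 200 --iterations 2000 --seed 1
```

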