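# sdnam1 — serum soluble DNAM-1 dynamics after allogeneic HSCT

Soluble DNAM-1 (sDNAM-1, shed CD226) circulates in serum after allogeneic
hematopoietic stem-cell transplantation (allo-HSCT), and its dynamics carry
information about acute graft-versus-host disease (aGVHD).  This package
implements a three-source compartment model of the serum concentration,
fits it to sparse longitudinal patient series, and evaluates the derived
biomarker `R_day_n` — the transient (alloreactive) share of donor-derived
sDNAM-1 exposure — against GVHD outcomes.  It is aimed at biostatisticians
and modellers working with longitudinal transplant biomarkers; since no
patient-level sera data are publicly deposited, a synthetic-cohort
generator with known ground truth drives every analysis stage.

## Model

Total serum sDNAM-1 (pM) is `x1(t) + x2(t) + x3(t)`, with `t` in days
since transplantation:

```
dx1/dt = λ t^(k−1) e^(−t/θ) / (Γ(k) θ^k) − μ x1      transient donor source
dx2/dt = (r − μ) x2 (1 − x2/N)                        persistent donor source
dx3/dt = −μ x3                                        recipient residual
```

* `x1` — sDNAM-1 released transiently by alloreactive donor lymphocytes:
  gamma-kernel production (total mass λ pM, shape `k`, scale `θ` days) with
  first-order clearance `μ` (per day); `x1(0) = 0`.
* `x2` — persistent release by non-alloreactive donor lymphocytes: logistic
  growth with effective rate `r − μ` and carrying capacity `N` pM.
* `x3` — residual recipient-derived sDNAM-1, decaying exponentially from
  `x3(0)`; serum half-life is `ln 2 / μ`.

All three components have exact solutions (the x1 convolution reduces to
incomplete-gamma / confluent-hypergeometric form), so trajectories need no
numerical integration.

Two nested variants are fitted per patient by bounded multistart least
squares: **model 1** (two sources, λ ≡ 0, 5 free parameters) and **model 2**
(three sources, 8 free parameters), compared by the least-squares AIC
`n ln(RSS/n) + 2p`.  The biomarker at horizon `n` days is

```
R_day_n = 100 · ∫₀ⁿ x1 dt / (∫₀ⁿ x1 dt + ∫₀ⁿ x2 dt)   (percent)
```

Cohort-level machinery: Welch t and Wilcoxon rank-sum comparisons of
`R_day_n` between GVHD(+)/GVHD(−) with a Welch 95% CI, an exact binomial
test (with Clopper-Pearson CI) on model-preference counts, 2×2 Fisher tests
for covariates, and ROC analysis with a DeLong AUC interval and the
closest-to-(0,1) cutoff.

## Worked example

Fit one simulated patient and read off the biomarker:

```python
import numpy as np
from sdnam1 import (ModelParameters, PatientSeries, FitOptions,
                    select_model, compute_rday, half_life, solve_trajectories)

params = ModelParameters(lam=600, k=3, theta=4, mu=0.08, r=0.25, N=25,
                         x2_0=3, x3_0=15)
days = np.array([1., 3, 5, 8, 12, 17, 23, 30, 40, 55, 75, 100])
rng = np.random.default_rng(7)
conc = (solve_trajectories(params, days).total
        * np.exp(0.05 * rng.standard_normal(days.size)))
series = PatientSeries("PT01", days, conc)

cmp_ = select_model(series, FitOptions(seed=0))
fit = cmp_.fit2 if cmp_.preferred == "model-2" else cmp_.fit1
print(f"preferred variant : {cmp_.preferred}")
print(f"AIC model-1/2     : {cmp_.fit1.aic:.1f} / {cmp_.fit2.aic:.1f}")
print(f"clearance mu      : {fit.params.mu:.3f} /day "
      f"(half-life {half_life(fit.params.mu):.1f} days)")
rv = compute_rday(fit.params, 30)
print(f"R_day_30          : {rv.r_day_n:.1f}% "
      f"(AUC x1 = {rv.auc_x1:.0f}, AUC x2 = {rv.auc_x2:.0f} pM*day)")
```

prints

```
preferred variant : model-2
AIC model-1/2     : 114.1 / 39.2
clearance mu      : 0.103 /day (half-life 6.8 days)
R_day_30          : 96.7% (AUC x1 = 5608, AUC x2 = 193 pM*day)
```

The three-source model wins the AIC comparison by a wide margin (the series
has a pronounced early peak), the recovered clearance corresponds to a
~7-day serum half-life, and 96.7% of this patient's donor-derived exposure
over the first 30 days is attributed to the transient (alloreactive)
source — the profile the model associates with GVHD risk.

The same pipeline is available from the shell:

```sh
sdnam1 simulate --n-patients 67 --seed 0 --out cohort/
sdnam1 run cohort/measurements.csv cohort/metadata.csv --out results/
```

which writes per-patient fits, `R_day_n` tables, group comparisons, ROC
summaries, covariate Fisher tests and a disposition log.

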