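# sleeproutine

Does *when* you sleep matter beyond *how much* you sleep?  This package
implements an end-to-end pipeline for quantifying how consistent sleep
routines relate to the hazard of developing a mental disorder, built for
epidemiologists and sleep researchers working with one-week wrist-actigraphy
studies and linked clinical follow-up.

The central exposure is **routine sleep hours (RSH)**: the number of fixed
clock-hour brackets (midnight-1 am, ..., 11 pm-midnight) in which a
participant was asleep at least 95% of the time, aggregated over the seven
study nights.  RSH unifies sufficient duration, consistent duration, sleep
continuity and regular onset times in a single integer-valued metric, and
is paired with the average sleep duration (ASD).  The hazard model is a
penalized Cox proportional-hazards regression with a smooth 2D interaction
surface over the two:

    h_i(t) = h0(t) * exp( f(ASD_i, RSH_i) + SUM_j s_j(x_ij) + x_i' beta )

where `f` is a tensor-product cubic B-spline surface with difference
penalties (fitted by penalized Breslow partial likelihood, implemented here
from first principles), the `s_j` are penalized smooths of continuous
controls, and categorical controls enter linearly with backward elimination
at p <= 0.1.  Around the model sit a validation battery (10-fold
cross-validated Harrell/Uno concordance, the VanderWeele E-value,
sex/age-stratified refits, 2-year landmark exclusion, a Schoenfeld-residual
proportional-hazards check) and counterfactual incidence standardization
(g-formula-style substitution of sleep behavior under the fitted model).

Because the motivating cohort data are access-restricted, the package ships
a calibrated synthetic actigraphy cohort generator whose emergent
statistics match the study conditions (mean ASD ~ 8.9 h, mean RSH ~ 4.8 h,
Spearman 0.4, weekend-behavior subtypes at 26.6/17.6/55.8%, ~3.4% incident
events over 8 years, and a known true hazard surface with its optimum at
8 h ASD / 7 RSH and an average-to-optimum hazard ratio of 0.79).  Every
stage of the pipeline is exercised against it; `docs/methods.md` documents
the models, defaults and their uncertainty in detail.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
from sleeproutine import GeneratorConfig, generate_cohort
from sleeproutine import smoothcox as sx
from sleeproutine.counterfactual import optimal_routine_cf
from sleeproutine.validation import evalue

cfg = GeneratorConfig(n_participants=10_000, seed=7)
cohort = generate_cohort(cfg)
df = cohort.frame()   # covariates + sleep metrics + outcomes

print(f"mean ASD  {df['asd'].mean():.2f} h   mean RSH {df['rsh'].mean():.2f} h")
print(f"Spearman(ASD, RSH) = {spearmanr(df['asd'], df['rsh']).statistic:.3f}")
print(f"incident events: {df.loc[df.prior_diagnosis == 0, 'event'].mean() * 100:.2f}%")

model = sx.fit(df)                      # penalized 2D-smooth Cox model
am = sx.surface_argmin(model)
print(f"fitted optimum: ASD {am.asd:.1f} h, RSH {am.rsh:.1f}")
hr, p = sx.hazard_ratio(model, {"asd": 8.0, "rsh": 7.0}, {"asd": 8.9, "rsh": 5.0})
print(f"HR optimum vs average sleeper: {hr:.3f} (Wald p = {p:.3f})")
print(f"E-value for HR 0.79: {evalue(0.79).evalue:.3f}")
opt = optimal_routine_cf(model, df)
print(f"counterfactual incidence reduction at 8 y: {opt.reduction_pct:.1f}%")
```

prints

```
mean ASD  8.90 h   mean RSH 4.83 h
Spearman(ASD, RSH) = 0.386
incident events: 3.39%
fitted optimum: ASD 7.7 h, RSH 7.3
HR optimum vs average sleeper: 0.794 (Wald p = 0.107)
E-value for HR 0.79: 1.846
counterfactual incidence reduction at 8 y: 23.8%
```

The cohort sleeps 8.9 hours a day on average yet keeps a routine covering
only the same ~4.8 hours; the fitted surface locates the lowest-risk
behavior near 8 hours of sleep integrated into a 7-hour routine; moving the
average sleeper there corresponds to a ~21% hazard reduction (HR 0.79), and
standardizing the whole population to the fitted optimum lowers the modeled
8-year incidence by roughly a quarter.  At ~270 events the optimum's
location and the derived percentages carry substantial sampling spread —
`docs/methods.md` quantifies it replicate-by-replicate.

A command-line pipeline wraps the same stages:

```
sleeproutine all --n 10000 --seed 7 --out runs/demo
sleeproutine simulate | metrics | fit | validate | counterfactual | report
```

Stages exchange plain CSV files (schemas in `sleeproutine/io.py`).

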