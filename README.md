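# sulapop

Age-structured demography for a long-lived tropical seabird under a
decadal diet-regime shift.  The package estimates vital rates from
longitudinal records of individually banded females, assembles annual
projection matrices, and asks whether the population can sustain itself
under each diet regime — the workflow a population ecologist needs when a
qualitative change in prey availability (here, sardines giving way to
flying fish in the Galápagos Nazca booby's diet) serves as a natural
experiment for future ocean warming.

## What it computes

**Vital rates.**  Annual Breeding Success (ABS, the probability a living
female fledges an independent offspring) and juvenile survival are fitted
as binomial logit mixed models — adaptive Gauss–Hermite quadrature for a
single random intercept, joint Laplace for crossed individual × year
intercepts — via `BinomialMixedModel.fit()`, a statsmodels-style
model/results pair with `summary()`, Wald and parametric-bootstrap CIs,
and AICc.  Adult survival Φ and resighting probability p come from
Cormack–Jolly–Seber mark-resight models (`CJSModel.fit()`), with year,
diet-period or constant time structure, an age factor (22+ pooled) nested
in banding group, likelihood-ratio tests, AICc ranking, and a
parametric-bootstrap overdispersion factor ĉ.

**Projection.**  Annual 22-class, female-only, pre-breeding-census Leslie
matrices with fertility

    F_i = (ABS_i / 2) · s_juv,female,i      (i = 3..21; F_1 = F_2 = F_22 = 0)

and P_1..P_3 = 1 (juvenile mortality is folded into fertility).
Deterministic λ is the dominant eigenvalue, with a 95% CI from 1,000
beta-resampled matrices (bias-corrected percentiles); phase-specific
stochastic λ is the long-run growth rate over 10,000 year-long intervals
of i.i.d. draws from that phase's annual matrices; a counterfactual
search finds the proportional fertility increase needed to reach λ = 1.

**Environment.**  Seasonal SSTA covariates (DJF and AMJ means) and a
thermal-threshold projection: monthly SST + 4.5 °C against the sardine
spawning limit (25.0 °C) and upper incipient lethal temperature (25.6 °C).

**Synthetic data.**  `simulate_population(SimConfig())` generates a full
study — breeding records, juvenile fates, encounter histories, SST/SSTA —
under known ground truth, with the regime contrast built in (pre-change
λ ≈ 1.000, post-change λ ≈ 0.94).  Every estimation stage is validated by
recovering that truth.

## Worked example

```python
from sulapop.pipeline import demo_config, run_pipeline

cfg = demo_config(seed=1, scale=0.4)     # reduced cohorts; ~30 s
res = run_pipeline(cfg, "runs/demo")

lam = res["lambda"]
print(lam["stochastic_sardine"].value,    lam["stochastic_sardine"].ci_low,
      lam["stochastic_sardine"].ci_high)
print(lam["stochastic_flyingfish"].value, lam["stochastic_flyingfish"].ci_low,
      lam["stochastic_flyingfish"].ci_high)
print(lam["counterfactual"]["increase"])
print(lam["autocorrelation"])
```

Output from that exact run:

```
0.9975883347691248 0.9969599296073182 0.9982171360281423
0.951921471444924 0.9516655153754511 0.9521774963552957
0.967315673828125
{'r': 0.29761532894836384, 'df': 18, 'p_value': 0.20252503912101516}
```

Read: under the sardine-phase vital rates the simulated population is
stationary (stochastic λ = 0.998, CI brackets ~1); under the flying-fish
phase it declines ~4.8% per year (λ = 0.952).  Lifting the post-change
stochastic λ back to 1.0 would require a ~97% increase in the
breeding-success component of fertility in this realization, and the
year-to-year deterministic λs show no lag-1 autocorrelation (r = 0.30,
df = 18, P = 0.20), supporting the i.i.d.-environment treatment.  The run
directory contains the tidy vital-rate tables, per-year matrices, the λ
table (year, λ, lcl, ucl), CJS model-selection and LRT tables, SSTA
covariates, threshold summaries, and a manifest with the seed and config
hash.

The same pipeline runs from a shell, stage by stage or end to end:

```bash
sulapop run --seed 1 --out runs/demo        # full pipeline, demo config
sulapop simulate --seed 1 --out runs/d      # stages compose identically
sulapop fit-glmm --seed 1 --out runs/d
sulapop build-matrices --seed 1 --out runs/d
sulapop lambda --seed 1 --out runs/d
```

See `docs/methods.md` for the model assumptions, the generator's design
(what it emulates and what it deliberately does not), numerical choices,
and known limitations.

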