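# Methods

`sulapop` re-implements, as a tested pipeline, the demographic analysis
linking a decadal diet regime ("fish phase") to the vital rates and
population growth of a long-lived tropical seabird (the Nazca booby,
*Sula granti*).  The study population is observed through annual breeding
surveys of individually banded females; the analysis turns those
longitudinal records into age-structured projection matrices and asks
whether the population can sustain itself under each diet regime.  The
original long-term dataset is not public, so the package ships an
individual-based generator that emulates its statistical structure under
known ground truth; every estimation stage is validated by recovering
that truth.

## Vital-rate models

**Annual Breeding Success (ABS)** — the probability that a living female
produces an independent offspring in a season — and **juvenile survival**
(independence to recruitment) are modelled as Bernoulli GLMMs with a
logit link.  The marginal likelihood with a single Gaussian random
intercept (female or maternal identity) is computed by *adaptive
Gauss-Hermite quadrature* (AGQ): each group's integral is re-centered at
its conditional mode and re-scaled by the conditional curvature, so the
default 15 nodes give near-exact likelihoods (the unit tests show
agreement with dense-grid integration to 1e-9; the pipeline uses 7 nodes,
which agree to ~1e-5, to keep many-parameter fits fast).  Crossed random
intercepts (individual x year, used in the breeding-parameter analyses)
are handled by a joint Laplace approximation over the stacked intercept
vector — AGQ does not extend to crossed designs — with an exact
reduction to single-group Laplace when one variance is zero, checked in
tests.  The optimizer is L-BFGS-B on `(beta, log sigma)` with
finite-difference gradients; the coefficient covariance is the inverse
observed information (central-difference Hessian).  `|beta| > 15` logits
is flagged as quasi-separation and the fit marked non-converged rather
than silently reported.  Confidence intervals for reported coefficients
can also be obtained by a parametric bootstrap (default 1,000 refits on
responses simulated from the fitted model).

Late-life senescence analyses use *years before death* (YBD) in place of
unknown chronological age: a bird is declared dead in the first of two or
more consecutive absent seasons, only birds dying at age >= 13 qualify,
and their final five seasons are retained.

**Adult survival** comes from Cormack-Jolly-Seber (CJS) mark-resight
models.  The likelihood conditions on first release and multiplies
survival, detection and never-seen-again (chi) terms; survival Phi and
recapture p are logit-linear in year (factor), a 3- or 4-level diet
period, or a constant, plus an age factor (ages pooled at 22+) nested
within banding group (known-age nestling-banded vs adults assigned age 4
at banding).  Year never interacts with age or group.  Detections before
age 4 are deleted and histories re-anchored (survival at ages 2-3 is
essentially one in this population).  When both Phi and p carry full time
dependence the final survival interval and final recapture are
confounded; those cells are flagged and excluded from the projection.
Goodness of fit uses a parametric-bootstrap overdispersion factor:
c-hat = observed deviance / mean bootstrap deviance, where the deviance
is taken relative to the saturated per-cohort multinomial (the absolute
-2 log-likelihood scales with sample size in a way that cannot detect
overdispersion, so the saturated reference is essential; a unit test
demonstrates both the null calibration near 1 and sensitivity to
duplicated-history overdispersion).  This deviance-ratio bootstrap is a
deliberate substitute for simulation-regression "median c-hat"
procedures tied to external software.

**Model selection** uses AICc (`-2 logLik + 2k + 2k(k+1)/(n-k-1)`), with
candidate sets generated as all additive term combinations under
marginality (quadratics require their linear term, interactions their
main effects).  Models within 2 AICc units of the top model are flagged
strongly supported; models more than 7 units away are dropped from
report tables; a more complex model nested over a better one is flagged,
since its apparent support comes only from the ~2-unit penalty per extra
parameter.  The effective n for AICc is the number of Bernoulli
observations (GLMM) or released individuals (CJS); the convention is
recorded in output metadata because no standard exists.

**Imputation.**  Years without direct estimates are filled by ordinary
least squares on the logit scale (both variables standardized at the
age-10 level): ABS for a partially monitored season is predicted from
annual adult survival, and juvenile survival for recent cohorts (whose
members have not all had time to recruit) from ABS, after a-priori
exclusion of the El Niño-like change season and leverage screening
(points above 3x the mean hat value are flagged).  Imputed cells carry
OLS prediction variance transformed by the delta method and an
``imputed`` provenance flag; imputation never overwrites an estimated
cell.

**Sex adjustment.**  Juvenile survival is estimated on mixed-sex cohorts.
With a 50/50 sex ratio at independence and male survival r = 1.33 times
female survival, the female rate is `s_f = 2c/(1+r)`.  The alternative
reading of "33% higher" (`s_f = c/r`) is available via a configuration
switch; the default follows the explicit-ratio interpretation.

## Projection matrices and growth rates

Annual matrices are single-sex, pre-breeding-census, birth-pulse Leslie
matrices with 22 age classes (class 22 pools ages >= 22 and receives a
survival self-loop — the standard pooled-class convention; the choice
matters most in years whose uncertainty is dominated by old-age
survival).  Fertility is `F_i = (ABS_i / 2) * s_juv_female,i` (daughters
only), zero for classes 1, 2 and 22; survival coefficients P_1..P_3 are
one because juvenile mortality is folded into fertility, and P_i for
i >= 4 comes from the CJS estimates.  Variances of fertility products use
the first-order delta method.

*Deterministic lambda* is the dominant eigenvalue.  Its 95% CI comes from
1,000 matrices resampled at the component level: ABS, female juvenile
survival and adult survival are drawn independently from beta
distributions matched to each estimate's mean and variance (variance at
or above the feasible bound m(1-m) is clipped to 99% of the bound with a
warning; zero variance gives a degenerate draw), fertilities recombined
by the F formula, and the lambda distribution shifted additively so its
mean equals the exact asymptotic lambda before taking the 2.5/97.5
percentiles.  The additive shift and the independent component sampling
are the package's own reading of the bias-correction and
variance-partition steps, which admit several implementations.

*Stochastic lambda* per diet phase draws annual matrices i.i.d. from that
phase's pool and averages log growth increments over 10,000 year-long
intervals after a 1,000-step burn-in (sum norm, renormalized each step);
the 95% CI is `exp(log lambda_s +/- 1.96 sd(log increments)/sqrt(T))`
(increment-variance formula, labelled as such in outputs).  The
change-year matrix is excluded from both phase pools by default, and the
pre-change pool uses the last five fully observed pre-change seasons.
A lag-1 Pearson autocorrelation check (df = n_pairs - 2) supports
treating years as independent environments.

The *counterfactual* asks what proportional increase in the
breeding-success component of all fertilities would lift the post-change
stochastic lambda to 1.0.  It bisects on the multiplier with common
random numbers across evaluations (probabilities capped at 1); an
unreachable target is reported with a `cap_limited` flag rather than an
error.

## Environmental covariates and thresholds

Monthly sea-surface-temperature anomalies are averaged into SSTA_DJF
(December of the season's label year through February of the next
calendar year — the El Niño peak) and SSTA_AMJ (April-June of the next
calendar year, late in the breeding season; the breeding season spans
two calendar years and is labelled by the first).  The thermal-threshold
projection adds a fixed +4.5 °C offset (the expected regional warming
over the next century) to monthly SST per 2°x2°-like block and counts
exceedances of the sardine spawning limit (25.0 °C) and upper incipient
lethal temperature (25.6 °C); the cross-block climatology reports the
mean ± 2 SD over all block-year values within each calendar month (the
pooling order is stated because alternatives exist).

## The synthetic-data generator

The generator is first-class, tested code, not a fixture.  It emulates:
22 breeding seasons with the regime change at season index 5
(1992-2013-like, changing at 1997); recruitment into the breeding pool
at age 4 with 100 new females per season (about 2,200 marked birds),
a quarter of them "banded as adults" and assigned age 4; an
age-quadratic logit of breeding success peaking near age 8
(`0.6 - 0.02 (age-8)^2`), shifted by -1.34 logits after the change
(exactly halving age-8 success, matching the observed ~50% decline);
age-structured annual survival of 0.92 through mid-life with a mild
senescent decline after 14, +0.55 logits after the change (survival
typically >= 0.90, slightly higher under the poorer diet); near-total
breeding failure in two El Niño-like seasons (year-intercept overrides
of -4 logits); resighting probability 0.90 per season; juvenile survival
with a maternal-age quadratic and a 1.33x male advantage under a 50/50
sex ratio; and monthly SST/SSTA as a seasonal cycle plus AR(1) anomalies.

Stage outcomes (initiate -> hatch -> fledge) are generated by drawing
overall season success first and attributing failures to a stage
(15/50/35% at initiation/hatching/rearing), so unconditional success
matches the generating quadratic exactly while conditional stage rates
remain available.  Recruits enter as an exogenous stream, so marked
offspring do not feed back into the adult pool; this controls the marked
population's size without affecting any estimand.

The pre-change generating rates were set by eigen-analysis of the
generating matrices so the pre-change phase sits at lambda ~= 1.000 and
the post-change phase clearly below 1 (truth 0.9997 and 0.938),
reproducing the qualitative contrast the analysis is designed to detect.
Quantities the study system does not pin down numerically are free
design parameters, chosen once at plausible values and documented here:
logit-scale random-intercept SDs sigma_id = 0.5 and sigma_year = 0.3 for
breeding success, sigma_id_juv = 0.1 and sigma_year_juv = 0.12 for
juvenile survival; a 0.6 correlation share between the breeding-success
and juvenile-survival year effects (which makes the juvenile-vs-ABS
imputation regression informative); and the stage-failure split.

What the generator does *not* emulate: diet composition itself, spatial
foraging, pairing dynamics or a male population (the male-biased sex
ratio enters only through the female-only projection), band loss,
age-dependent detection, or trends in detection effort.  Passing
recovery tests therefore show that the estimation machinery is correct
under the stated generating assumptions, not that those assumptions hold
for any particular field system.

## Problem sizes in tests and the acceptance script

Recovery experiments are sized to keep the full test suite and the
acceptance script fast while leaving Monte-Carlo error well inside the
asserted tolerances: the mixed-model recovery uses 200 replicates of 500
groups x 6 observations; the CJS recovery 200 replicates of 2,000 birds
x 20 occasions; the end-to-end lambda recovery 20 replicate studies of
16 seasons x 120 recruits with year random effects set to zero and an
age-constant survival schedule, so the generating matrices are the exact
truth and the fitted period-level CJS design is correctly specified
(truth-vs-estimate error SD ~= 0.006, asserted within ±0.02 per
replicate).  The acceptance script runs the demonstration pipeline at
the full default scale and smaller replicate counts (60) for the
coverage experiments.

## Numerical choices and degenerate inputs

- Bernoulli log-likelihoods via `y*eta - log1p(exp(eta))` forms; inverse
  logit via `tanh` for symmetry at extreme eta.
- AGQ mode finding: damped Newton (steps clipped at 4), tolerance 1e-10;
  crossed-Laplace mode finding: Newton with dense Cholesky solves.
- Optimizer tolerances: `ftol = 1e-11`, `gtol = 1e-7`; CJS starting
  values at logit(0.8); ridge fallback (1e-6) on a singular information
  matrix.
- AICc ties break by smaller k, then model id.
- Collapsed cohorts (zero estimated juvenile survival after a failure
  season) contribute zero fertility instead of tripping the sex
  adjustment's domain check; separated season levels are reported via
  `separated_terms` metadata.
- The final study season has no outgoing survival interval; its column
  is flagged `extrapolated` and excluded from matrix assembly, alongside
  `confounded` final-interval cells under fully time-dependent designs.

## Known limitations

- Crossed-design likelihoods are Laplace-approximate; with few year
  levels the year variance is noticeably shrunk (a known property of
  Laplace GLMM fits at small cluster counts).
- The CJS likelihood handles no individual covariates, multistate
  structure, or band recovery; p is always estimated freely.
- Wald intervals back-transformed through the logit are used for the
  survival tables; profile intervals are not implemented.
- The fertility counterfactual scales the breeding-success component
  only; scaling juvenile survival instead would give a slightly
  different multiplier because the caps bind differently.
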