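# Methods

## Data model

The unit of analysis is one spontaneous report: demographics (DEMO),
drug records (DRUG), coded adverse events (REAC), linked by a report
identifier; HIST is parsed for schema completeness but carries no
linkage used by any stage. The canonical schema uses English column
names and value tokens; `srs_signal.jader_io` documents an alias map so
a raw Japanese-distribution extract can be ingested after header
translation. Dates are 8-digit `YYYYMMDD` strings; 6-digit `YYYYMM` and
other short forms are retained but flagged partial, and only fully
dated records enter time-to-onset analysis.

Drug roles (suspected/concomitant/interacting) are read but not
filtered on by default: SRS screening practice varies, and restricting
to suspected drugs is a one-line configuration (`drug_roles`) rather
than a baked-in choice.

## Cohort construction

Exclusions run in a fixed order, each counted: (1) reports missing sex,
age band, height band or weight band; (2) eBMI outliers. The estimated
BMI uses band intermediate values defined as the band's lower bound
plus 5 (160‒169 → 165), not the arithmetic midpoint — the established
convention for this banded format — and is reported at one decimal, the
resolution the bands support; classification uses the half-open
intervals [18.5, 25.0).

Outlier bounds are Q1 − 1.5·IQR and Q3 + 1.5·IQR, computed once on the
pooled post-exclusion eBMI distribution (not per subgroup). Quantiles
everywhere in the package use linear interpolation between order
statistics at positions (n+1)p (R type 6, `numpy` method `"weibull"`);
the rule is configurable because lifetime-analysis software differs
here, and differences show up in the third decimal of small-sample
quartiles.

The elderly stratum is age band lower bound ≥ 60. Event presence is at
least one REAC row bearing the target PT code (default 10056979);
duplicate target rows are permitted and the first non-missing outcome
is carried.

Time-to-onset durations are onset minus drug start in days, shortest
per (case, drug) pair. Negative durations are data errors (dropped,
counted); zero-day durations map to 0.5 days so same-day onsets remain
in the strictly positive Weibull domain rather than being discarded.

Drugs of interest are those administered in at least five event cases,
binned into frequency strata (5‒9, 10‒19, 20‒100, >100).

## Disproportionality

ROR = ad/bc with the Woolf (log-normal) 95% interval and the
lower-bound-above-1 signal rule. Zero cells leave the estimate
undefined by default — the ≥5-case threshold guarantees a ≥ 5 for every
screened drug, so a zero cell signals a degenerate analysis rather than
something to patch — with the Haldane–Anscombe +0.5 correction
available by configuration for reuse on other events. No
multiple-testing adjustment is applied, matching standard
signal-screening practice where the screen is hypothesis-generating.

## Weibull onset model

The two-parameter Weibull MLE reduces exactly to a one-dimensional
problem: the profile score in the shape β,

    g(β) = 1/β + mean(log t) − Σ tᵢ^β log tᵢ / Σ tᵢ^β,

is strictly decreasing (g′ = −1/β² − Var_w(log t)), so a safeguarded
Newton iteration (bracketed bisection fallback, tolerance 1e-10, ≤ 200
iterations) finds the unique root and the scale follows in closed form,
α̂ = (Σ tᵢ^β̂ / n)^(1/β̂). Durations are scaled by their maximum inside
the weight computation for overflow safety. Zero-variance samples have
no finite MLE and return `converged=False`.

Confidence intervals are Wald on (log α, log β) from the analytic
observed information at the MLE, exponentiated — positive bounds are
guaranteed and this is the standard approach in lifetime software; a
package computing β CIs by another method may differ in the third
decimal. All durations are treated as observed events; right- or
interval-censoring is out of scope. Per-drug profiling requires
strictly more than `min_tto_cases` (default 10) onset records.

## Logistic signal model

Fitting is Newton–Raphson/IRLS with step-halving, which makes the
log-likelihood provably non-decreasing per iteration (the per-iteration
path is exposed for verification); convergence is a 1e-8 coefficient
change, and any coefficient magnitude crossing 30 during iteration is
reported as perfect separation naming the covariate (an odds ratio of
e³⁰ is not estimable from report counts). Standard errors come from the
inverse observed information; aROR CIs use z = 1.96.

Stepwise selection starts from the forced confounders (female, age
≥ 60, obese, underweight — the eBMI class enters as two indicators
against the normal reference) and alternates forward entry of the
candidate with the smallest likelihood-ratio p-value below 0.05 with
backward removal of the included term with the largest p-value at or
above 0.05; forced terms are never removed, ties break
lexicographically, and a repeated term-set stops the loop. Likelihood
ratio rather than Wald tests drive the steps because they are invariant
to parameterization; stepwise software using Wald or score tests can
differ on borderline candidates. Drugs used to treat the outcome
(default: albumin tannate, prednisolone, loperamide) are barred from
selection because their exposure follows the event.

By-sex subset models use a fixed term list (age ≥ 60, the two eBMI
indicators, and either configured drugs or the two selected drugs most
frequent among event cases) with no stepwise — the subset analysis
tests effect modification of a pre-specified model, not a new search.

VIF is computed on the linear design matrix, 1/(1 − R²) of each term
regressed on the rest, with exact collinearity reported as an infinite
sentinel.

## Synthetic registry generator

The generator is the package's test bed: it emits tables in the exact
input format with a known latent state. Conditions emulated:

- **Banded demographics with missingness.** Continuous heights and
  weights are drawn per sex (Japanese adult means: 165/152 cm, 62/51 kg)
  and banded afterwards, so the banded eBMI class — the covariate both
  the generator's event model and the pipeline use — is well defined,
  and banding error is realistic (~15% of cases change eBMI class
  relative to their latent BMI; class agreement is tested at > 80%).
  Per-field missingness (sex 5%, age 10%, height and weight 35% each)
  retains roughly a third of reports with complete demographics,
  mirroring the severe attrition typical of registry height/weight
  fields. Missingness is applied to emitted fields only; latent values
  keep driving event and onset mechanics.
- **Event model.** A logistic model with baseline log-odds logit(0.02),
  covariate effects (female OR 3.26, age ≥ 60 OR 3.94, obese and
  underweight OR 1.2) and per-drug log odds ratios (defaults: 35 for
  lansoprazole at 9.1% exposure, 2 for aspirin at 8.3%, among twenty
  null drugs). The baseline is set well above real-SRS event rarity so
  a 20,000-report draw yields ~1,200 analyzable events; absolute case
  counts from a multi-hundred-thousand-report registry are not a target
  at desk scale.
- **Onset latencies.** Weibull per effect drug (defaults α = 107.5,
  β = 0.93 and α = 220.6, β = 0.57 — scales back-derived from ~72.5- and
  ~116-day medians at those shapes), anchored at the exposing drug's
  latent start date, rounded up to whole days; events without an
  exposed effect drug get a background latency (α = 180, β = 1).
- **Outcome profile.** Six-category clinical outcomes dominated by
  recovered/improved, with sequelae and death absent.

Features of real SRS data deliberately not emulated: drug
co-prescription correlation, duplicate patient reports, notoriety and
competition biases, dose information, and multi-event cases beyond one
target PT plus a noise reaction per non-event report. Passing
recovery tests therefore demonstrates statistical correctness of the
machinery under a faithful-but-clean generating process, not robustness
to reporting biases.

One known interaction worth noting: the pipeline's per-drug onset fits
pool every dated drug record of an event case, so a drug's duration
sample includes cases whose onset was anchored on the *other* effect
drug or on background latency. This contamination flattens the duration
distribution and biases the fitted shape downward relative to the
injected per-drug shape (e.g. ~0.7 fitted vs 0.93 injected for the
high-OR drug at default conditions). The same mechanism operates in
real registries — onset attribution across co-medication is ambiguous —
so the generator reproduces it rather than hiding it; shape-recovery
tests use direct Weibull samples.

## Problem sizes and calibration checks

The test suite runs the full pipeline at 20,000 reports per replicate,
50 replicates for parameter recovery (both injected drugs stepwise-
selected and each true coefficient inside its 95% CI in ≥ 90% of
replicates), 200 replicates at 3,000 reports for null stepwise
calibration, 200 small-registry replicates for Woolf-CI signal-rate
calibration, and 500 replicates of n = 100 for Weibull CI coverage
(95% ± 3%). Under the global null with 20 candidates at the 0.05 level
the per-replicate selected-drug count is approximately Binomial(20,
0.05); the calibration test asserts the 200-replicate mean lies in
[0.7, 1.3], a ±4σ band under that model with slack for the sequential-
selection approximation.

## Limitations

- No censoring or latency-mixture modelling of onsets; durations are
  taken as exact event times.
- Crude and adjusted RORs quantify reporting disproportionality, not
  incidence or risk; nothing here supports causal inference.
- The stepwise procedure inherits the usual caveats: selected null
  drugs at the nominal error rate, and post-selection p-values are not
  adjusted for the search.
- PT codes are opaque strings; no MedDRA hierarchy resolution is
  attempted.
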