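# Methods

This note documents the models and procedures implemented in
`bpscreen`, the defaults chosen where the design was genuinely open,
and what the synthetic-data tests do and do not establish.

## Screening rules and concordance

The standard rule diagnoses hypertension when the mean of the second
and third BP readings is ≥ 140 mm Hg systolic **or** ≥ 90 mm Hg
diastolic. The nine simplified rules are: (i) first reading; (ii)
second reading; (iii) mean of the first two; (iv)–(vi) second reading
if the first is ≥ 130/80, ≥ 135/85, ≥ 140/90 (else the first reading);
(vii)–(ix) second reading if the first is inside 130–145/80–95,
130–150/80–100, 130–155/80–105 (else the first reading).

Conventions, fixed once and applied everywhere:

- all thresholds and both window endpoints are **inclusive**
  (130 ≤ SBP ≤ 145), matching the ≥-convention of the diagnostic
  cut-offs; the source definitions do not state endpoint handling, so
  this is a package choice;
- trigger conditions combine the SBP and DBP parts with OR;
- effective BP is kept at full floating precision — the mean of
  readings at 139 and 140 is 139.5 and is *not* hypertensive; whether
  rounded or unrounded means were used originally is unknowable from
  the published definitions, and unrounded is the cleaner contract;
- a missing reading raises an error; readings are never imputed.

Missed % and over-diagnosed % follow the definitional formulas (see
README). A country with a zero denominator is reported missing, never
as 0. Region and global summaries are the **unweighted** mean, SD
(n − 1 denominator), median, min and max of country-level proportions;
pooled individual-level proportions are also emitted, labelled
`pooled_*`, because the two conventions can differ materially when
country sizes vary (a property one unit test exercises directly).

Useful provable structure, used as test invariants: for the threshold
family, missed(second) ⊆ missed(≥130/80) ⊆ missed(≥135/85) ⊆
missed(≥140/90) and the over-diagnosed sets nest the opposite way; the
window family nests by window width. These are per-person set
inclusions, so they hold on every cohort, not just in expectation.

## Eligibility

The analysis population is adults aged 18–69 (inclusive) free of known
hypertension (no self-reported diagnosis or antihypertensive
medication). A record with a missing known-hypertension flag cannot be
confirmed eligible and is excluded, with per-reason counts reported.
The filter is idempotent.

## 10-year cardiovascular risk

Risk is used as a continuous summary of cardiometabolic burden in
[0, 1], not as a categorical prediction. The engine implements the
structural form shared by chart-based scores:

    lp     = Σ_k β_k x_k        (age, male, smoker, SBP, TC, diabetes)
    risk   = 1 − (1 − r₀) ^ exp(lp − lp_ref)

with `r₀` the 10-year risk at a configured reference profile
(optionally region-specific) and `lp_ref` the linear predictor at that
profile. The transform saturates, so risk stays in [0, 1] for any
finite covariates, and is monotone in each covariate with the sign of
its coefficient. The SBP entering the score defaults to the
standard-rule effective SBP (mean of readings 2–3); which reading a
given study fed its score is typically unreported, so the choice is a
documented, switchable assumption.

Diabetes uses the expanded definition: self-reported history OR
fasting plasma glucose ≥ 7.0 mmol/L (126 mg/dl; the unit conversion is
exactly 18 mg/dl per mmol/L, so the two cutoffs flag identical sets).

The packaged coefficient set (`SYNTHETIC_RISK_MODEL`) is synthetic:
plausible log-hazard magnitudes chosen for simulation and testing, not
fitted to any published chart. Coefficient tables for real scores load
from YAML without code changes; countries a score does not cover are
configured in `countries_without_model` and get missing risk.

## Group comparisons

Within each country × approach, mean risk in the missed,
over-diagnosed and consistent-non-hypertension groups is compared to
the consistent-hypertension group with two-sided t tests. Welch's
unequal-variance variant is the default — the concordance groups have
very different sizes and there is no reason to assume equal variances —
with Student's pooled variant behind a flag. Bonferroni adjustment uses
family size m = 3 (the three comparisons within one country ×
approach); the family is configurable because the appropriate family
is a judgement call. Groups with n < 2, or comparisons where both
groups are constant, are flagged rather than tested. The relative mean
is reported as `100 · mean(group) / mean(reference)` %.

## Misdiagnosis-correlate model

One model per simplified rule: individual-level Poisson regression
with log link of missed (yes/no, all eligible individuals with a risk
value) on female sex, age (years), BMI (kg/m²) and 10-year risk on its
native 0–1 scale (its PR is per absolute risk unit), with random
intercepts for countries nested within regions. Poisson — not
logistic — is deliberate: exponentiated coefficients are prevalence
ratios, the effect measure of interest for a common outcome. CIs are
Wald-type, conditional on the estimated variance components; robust
(sandwich) errors are not applied.

Estimation is Laplace-approximate maximum likelihood, implemented in
the package: for candidate variance components (log-SD scale, one for
country-within-region, one for region) the penalized log-likelihood is
maximized jointly over fixed effects and random intercepts by Newton's
method with step halving, and the profiled Laplace marginal likelihood

    ℓ(θ) = ℓ_pen(β̂, û) − ½ log|Z'WZ + D⁻¹| − ½ log|D|

is optimized over the two log-SDs by bounded Powell search (bounds
[−6, 2], the lower bound an effective zero). The fit is fully
deterministic; covariates are standardized internally for conditioning
and estimates transformed back. This routine exists because the
general-purpose joint-MAP fitter available off the shelf collapses
into the well-known variance-spike ("funnel") degeneracy at the
~2·10⁵-row scale of a full cohort; at small n the two routes agree to
a fraction of a percent, and that agreement is a test. A second,
structurally independent oracle: with zero random-effect variance the
PRs must match an ordinary Poisson GLM to 2 significant figures.

Preconditions are enforced, not papered over: ≥ 2 regions, ≥ 2
countries per region (otherwise a degenerate-design error), at least
one event, and a convergence check on the final gradient.

## Protocol time

Per-person time is `(n − 1)·wait + n·measurement` minutes with a
3-minute default wait and measurement time defaulting to 0 ("a
measurement takes seconds"); throughput is `60/minutes`. Hence 3
measurements → 6 min → 10 persons/hour, 2 measurements → 3 min → 20
persons/hour, and the 2-vs-3 saving is exactly 50% for any positive
wait when measurement time is 0 (with nonzero measurement time the
saving is smaller — both accountings are available). For triggered
rules the expected reading count on a cohort is 1 + P(first reading
meets the trigger). A second-reading-only protocol counts as 2
readings by default, since a second measurement presupposes a first;
the discard-first accounting (1 reading) is behind a flag.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, per person
i in country c:

    latent_sbp = μ_c + β_age(age−43.5) + β_bmi(bmi−25.5)
                 + β_male·male + β_smoker·smoker + e_i
    reading_k  = latent_sbp + offset_k + ε_ik,   ε iid N(0, σ_noise²)

with (e_sbp, e_dbp) bivariate Gaussian (default correlation 0.7) and
DBP effects scaled by 0.5. Per-country offsets default to
(t_c, +0.7, −0.7) with t_c ~ U(0.70, 5.75) mm Hg, so the expected
excess of reading 1 over the mean of readings 2–3 is exactly t_c —
reproducing both the first-reading elevation and the small decline
from reading 2 to 3 seen in serial survey measurements. The default
layout is 6 regions × 10 countries with per-country sizes uniform on
[215, 7431] and latent SBP means uniform on [118, 139] mm Hg; ages are
uniform on [18, 69]; covariates (BMI, waist, FPG, TC, smoking, sex)
have fixed plausible marginals and are mutually independent except
through their configured effects on latent BP, which keeps
parameter-recovery tests interpretable. Known-hypertension status
(prevalence 0.12) and diabetes history (0.04) are independent flags.
Readings are clipped to sanity bands (SBP 50–300, DBP 30–200 mm Hg).

Everything is driven by one seed; the same config and seed reproduce
the cohort bit-identically, and the pipeline records the seed and a
config hash in its manifest.

What the generator does **not** emulate: survey sampling weights and
multi-stage design (deliberately out of scope — the analyses are
unweighted group comparisons), within-person reading-to-reading
correlation structure beyond the shared latent (the Gaussian serial
model is a stand-in, not an estimate), age-structure skew, covariate
co-dependence (e.g. BMI–smoking), and country-level covariate
profiles. Passing tests therefore establish that the *pipeline*
computes its quantities correctly and that structural invariants hold;
they do not establish that any particular country's misdiagnosis rate
takes any particular value.

## Numerical and testing choices

- Proportions and effective BPs are never rounded internally; report
  tables round to 2 decimals.
- Monte-Carlo calibration tests use closed-form standard errors
  (Var[r1 − (r2+r3)/2] = 1.5 σ_noise²) with 3·SE tolerance at
  n = 50,000.
- Rule-engine correctness is checked against an independently written
  scalar re-statement of every rule over an exhaustive first-reading
  grid (SBP 118–162 × DBP 72–108, step 1) crossed with probe values
  for readings 2 and 3 that straddle every trigger and diagnostic
  boundary; the first reading is the only one any trigger inspects, so
  sweeping it exhaustively while probing the others covers every
  decision path.
- GLMM recovery is tested at 200 replicates × n = 5,000 (CI coverage
  within 95 ± 4 points) and 10 replicates × n = 50,000 (mean BMI-PR
  within ±0.005 of truth); the t-test type-I error is checked over
  3,000 null replicates at the 3·binomial-SE tolerance. These sizes
  keep the suite's runtime modest while leaving the Monte-Carlo error
  well inside the asserted tolerances.
- Test cohorts are small (hundreds to a few thousand rows per country)
  except where a stated calibration requires n = 50,000.

## Known limitations

- The Laplace approximation can bias variance-component estimates for
  rare outcomes with few clusters; fixed-effect PRs are robust to this
  in the tested regimes, and CI coverage is verified by simulation
  only there.
- The risk engine ships synthetic coefficients; substantive risk
  numbers require loading a real coefficient table.
- Sensitivity/specificity against a latent "true" BP is intentionally
  absent: the reference is the standard rule, not truth.
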