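# Methods

## Data model and conventions

A diary is three tables: a participant roster (cohort, age group, inhibitor
status, regimen, study phase, efficacy period), bleed records (onset,
location, cause, symptoms), and medication records (time, agent, dose, stated
purpose). Bleeds and doses are recorded independently; the pipeline, not the
instrument, decides which bleeds were treated.

* **Efficacy period** is half-open `[start, end)`; its length in days is the
  ABR denominator and the exposure offset. Events outside the owner's period
  are retained and flagged but excluded from analyses.
* **Timestamps** are ISO-8601 with day resolution as the floor. A timestamp at
  midnight is treated as date-only. Windows are evaluated exactly when either
  endpoint carries a time of day; with two date-only stamps, "within 72 h"
  means a calendar-day difference ≤ 3 and "within 24 h" means ≤ 1. This makes
  behavior deterministic across mixed-resolution diaries.
* **Location vocabularies** differ by cohort: adults/adolescents with
  inhibitors (cohort A) may record soft-tissue, bruise/hematoma and
  miscellaneous bleeds; the pediatric inhibitor cohort (B) and the
  non-inhibitor cohort (C) use a single "other" category. Vocabulary is
  enforced per cohort; `coarse_location` maps everything onto
  joint / muscle / other_nonjoint for cross-cohort comparisons.

## Linkage

Per participant, bleeds are scanned in onset order; each links to the earliest
treat-purpose dose at or after its onset (a dose on the bleed's calendar day
counts as "thereafter" even at day resolution — same-stamp pairs are common
and treating them as linkable matches the same-day exception's intent). A
consumed dose is unavailable to later bleeds unless those bleeds share the
consuming bleed's calendar day, in which case they share the dose. Sharing
takes precedence over later unconsumed doses: every same-day bleed's "first
treatment thereafter" is the same dose. There is no time limit between bleed
and treatment. Only doses whose stated purpose is to treat a bleed
participate; prophylaxis doses never make a bleed treated (they feed only the
24-h follow flag). Treat-purpose doses that end up linked to no bleed are
returned as a side list of orphans and excluded from all bleed counts.

When two bleeds at different locations on different days precede one dose,
the chronologically earlier bleed takes it — the greedy rule, verified against
an exhaustive-search oracle on small diaries.

## 72-hour collapsing

Off by default: every bleed counts individually, which is the right convention
when untreated bleeds are in scope (for them the window could only be measured
from the previous bleed, not from treatment). When enabled, bleeds of the same
participant, cause category and anatomic location merge transitively if the
later onset falls within the window (default 72 h) after the reference point:
the previous member's linked dose time (`after_treatment_stop`; the onset for
untreated members) or the previous member's onset (`after_previous_bleed`).
"Type" means the cause category (spontaneous / traumatic / surgery), the only
type axis the diary carries; "stopping treatment" is the single linked dose's
time, since the data model links one dose per bleed.

## Joint bleeds

Cohort A: joint-site location, aura, and at least one further joint symptom
(pain, swelling, reduced motion, warmth). Cohort C: joint-site location and at
least one of those symptoms, aura not required. Cohort B: the reported joint
location decides (either the location category or the caregiver's joint flag —
children are not expected to identify symptoms; both inputs are accepted
because the instrument's exact field is not knowable from outside).

## ABR estimation

Calculated ABR is `n / days × 365.25`; cohort summaries are medians with
quartiles by linear interpolation. The model-based ABR is the intercept of an
NB2 regression, `y_i ~ NB(mean μ_i = λ T_i, var μ_i + α μ_i²)` with exposure
`T_i` in years entering as a log offset, so `exp(intercept)` is directly
events/participant-year. Maximization is quasi-Newton (L-BFGS-B) on
`(log λ, log α)` with analytic gradients from fixed, data-derived starting
values (pooled rate; α = 1), hence seed-independent. `log α` is bounded in
[−15, 10]; hitting the lower bound is reported as the Poisson boundary with
the Poisson-limit standard error `1/√Σy`. The 95% CI is Wald on `log λ` from
the numerically differentiated observed information, exponentiated
(profile-likelihood CIs were considered and not implemented; the Wald form is
cheap, reproducible, and its ≥ 85% empirical coverage at n = 200 is checked in
the test suite, measuring 90+/100 at the default operating point). All-zero
counts return rate 0 with the Poisson-exact upper bound `χ²₀.₉₅(2)/2 / ΣT`
instead of failing. With `fix_alpha=0` the closed-form Poisson MLE `Σy/ΣT` is
used.

### Paired intraindividual model

`log μ_ij = log T_ij + β₀ + β₁·period_ij + b_i`, `b_i ~ N(0, σ²)`, NB2
dispersion α shared across periods. The marginal likelihood integrates `b_i`
by adaptive Gauss–Hermite quadrature with 15 nodes: per participant the
conditional log-joint (strictly concave in `b`) is maximized by safeguarded
Newton, and the node grid is centered and scaled at the mode. The outer
optimization is Nelder-Mead over `(β₀, β₁, log α, log σ)` with `log σ`
bounded below (σ ≥ 10⁻³) so that homogeneous-participant data land on a
boundary rather than diverging; parameters at a bound are dropped from the
curvature block used for the Wald SE of `β₁`. `exp(β₁)` is the within-person
rate ratio (comparison vs reference period); period rates are reported
conditional on `b = 0`. Participants missing a period are dropped with a
warning.

## Synthetic data

The simulator draws, per participant: follow-up uniform in the cohort's
stated range; a latent rate from Gamma(1/α, λα) (mean λ, so counts are NB2
with dispersion α — matching the analysis model makes parameter recovery
well-posed); Poisson bleed onsets over the period; location and cause from
cohort multinomials; a treat-purpose dose with probability
`treat_probability`, delayed 0–2 days (exercising the unlimited-gap rule);
and scheduled prophylaxis doses every 1–3 days for prophylactic participants.
One RNG stream per participant is derived from `(seed, crc32(participant_id))`
so growing a cohort never perturbs existing participants.

Default operating points are the published cohort descriptions: sizes
103/24/94, follow-up ranges 4.1–69.6, 8.7–44.1 and 12.4–47.7 weeks,
dispersion 1.0, and all-bleed rates (34, 37, 27 per year) and treatment
probabilities (0.60, 0.60, 0.74) chosen once so the implied untreated ABRs
and untreated proportions sit near the reported values (~40% untreated in the
inhibitor cohorts, ~26% without inhibitors). Prophylactic fractions
(0.40/0.60/0.55) are plausible values; the source populations' regimen splits
are not printed anywhere usable. What the generator does **not** emulate:
under-reporting and recall error, seasonal or activity covariates,
multi-dose treatment courses, pharmacokinetic structure in breakthrough
bleeding, and informative dropout. A green recovery test therefore
establishes estimator correctness under the stated model, not robustness to
those real-data features.

The exact-count fixture builder places treated bleeds in the first half of a
one-year period with same-day doses and untreated bleeds in the second half
(after every treat dose, so linkage cannot reach them), distributing bleeds
round-robin over the requested number of untreated reporters; optional
per-cause routing concentrates bleeds on one participant for
dominant-participant sensitivity designs. Requested prophylaxis-follow flags
use a 3-day lattice so day-resolution 24-h windows hit exactly the intended
bleeds; this caps per-participant untreated bleeds (~62 flagged + 61
unflagged) and the builder rejects infeasible requests.

## Numerical and rounding choices

* Percentages print at 1 decimal with half-up rounding, as clinical tables do;
  raw fractions are kept alongside. Empty strata report NaN, never 0.
* Linkage tie-breaks: bleeds sort by (onset, location); a dose with exactly a
  bleed's timestamp is linkable.
* The paired fit's quadrature defaults to 15 nodes (`n_quad` parameter); the
  per-participant Newton mode search is capped at 50 iterations with step
  clipping at ±5 on the log scale.

## Known limitations

* The single-dose linkage means "stopping treatment" for the 72-h rule cannot
  see multi-dose treatment courses.
* Wald intervals on the rate ratio can be anticonservative at small n with
  large σ; no profile or bootstrap alternative is built in.
* The intraindividual model supports exactly two periods.
* No covariate-adjusted ABR models, zero-inflation, or Bayesian estimation.
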