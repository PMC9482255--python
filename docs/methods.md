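# Methods

## Problem and scope

After radical hysterectomy for cervical adenocarcinoma, patients with
none of the high-risk factors (nodal metastasis, positive surgical
margin, parametrial involvement) form the *intermediate-risk* group,
whose adjuvant-therapy decision traditionally rests on the Sedlis
criteria — a fixed rule over lymphovascular space invasion (LVSI),
depth of stromal invasion (DSI) in thirds, and tumor size.  The Silva
pattern (A/B/C morphology of stromal invasion) carries prognostic
information that the Sedlis rule ignores.  `silvarisk` implements, as
reusable and tested components, the methodology of building and
evaluating Silva-based *k-of-m* rule models against the Sedlis
criteria on censored recurrence outcomes: dichotomize candidate
factors, enumerate the rule families exhaustively, evaluate each rule
by univariate Cox regression, the log-rank test and Harrell's C, rank,
and drill the winning rule down into its subset combinations.

Patient-level data of this kind are generally not deposited, so the
package includes a first-class synthetic cohort generator; all
quantitative claims made by the test suite are claims about recovery
of known generative truth, not about any clinical dataset.

## Data model and dichotomization

A patient record carries: Silva pattern (A/B/C), tumor size (cm), DSI
as a fraction of stromal thickness in [0, 1] (0 = no invasion), LVSI
grade (none < mild < substantial), nodal site (none/pelvic/common
iliac/para-aortic, furthest station kept), margin / parametrial / PNI
flags, FIGO stage (1/2), adjuvant-treatment flag, and censored RFS/OS
times in months.  Validation enforces: DSI in [0, 1], strictly
positive times, RFS ≤ OS, and the definitional constraint that Silva
pattern A carries no LVSI.  Records with missing modeled fields are
rejected at read time rather than imputed.

Candidate dichotomizations (16 by default): age at 40/50/60; Silva
B+C and Silva C; size at 2–5 cm by 0.5 (inclusive "≥"); DSI strictly
above 1/3 and 2/3; LVSI at "any" (≥ mild) and "substantial only"
(> mild).  Conventions chosen where the clinical wording is ambiguous:

- **"> mild LVSI" means substantial only.**  The grading is ordinal
  (none/mild/substantial) and the rule labels use a strict ">".  The
  any-LVSI variant stays in the candidate set and is selectable.
- **DSI thresholds are strict** (("> 2/3") so the boundary value 2/3 is
  negative), matching the model labels; DSI thirds are accordingly
  left-open/right-closed: 0 → none, (0, 1/3] → superficial,
  (1/3, 2/3] → middle, (2/3, 1] → deep.
- **Size thresholds are inclusive** ("≥ 3 cm").

## Rule families and the Sedlis reference

A `RuleModel` is a set of variables (at most one variant per factor)
plus a count k: positive iff ≥ k variables hold.  The families, built
from the six retained variables (Silva B+C, Silva C, ≥3 cm, ≥3.5 cm,
DSI > 2/3, > mild LVSI):

- **four-factor** — one variant each of Silva/size/DSI/LVSI,
  k ∈ {2, 3, 4}: 2·2·3 = 12 models;
- **three-factor** — Silva replaces exactly one of size/DSI/LVSI,
  k ∈ {1, 2, 3}: (2 + 4 + 4)·3 = 30 models;
- **two-factor** — Silva plus one other factor, k ∈ {1, 2}:
  (4 + 2 + 2)·2 = 16 models.

The four-factor k range is explicit in the family's definition; the
smaller families' ranges are the unique uniform choices reproducing
the 30/16 counts from the replace-with-Silva construction, and are
config-overridable.  The pure {size, DSI, LVSI} triple is excluded:
the smaller families are Silva-based by construction.

The Sedlis criteria are implemented clause for clause ((a) LVSI +
deep third; (b) LVSI + middle third + ≥2 cm; (c) LVSI + superficial
third + ≥5 cm; (d) no LVSI + middle/deep third + ≥4 cm), with
inclusive size comparisons and any-grade LVSI (the criteria predate
graded LVSI).  Zero invasion never triggers.

## Survival statistics

These are implemented from first principles because every evaluation
rests on them; an independent library (lifelines) serves only as a
cross-check oracle in the test suite.

- **Kaplan–Meier**: product-limit over distinct event times;
  evaluation is right-continuous; the 3-year rate is S(36 months).
- **Log-rank** (two groups): Σ(O − E) with hypergeometric variance per
  event time, χ² with 1 df; zero usable events yield a flagged
  degenerate result (χ² = 0, p = 1) instead of a crash.
- **Cox regression**: Newton–Raphson on the partial likelihood,
  starting at 0, tolerance 1e-9 on the score max-norm, 50-iteration
  cap, step-halving when a step would decrease the likelihood.
  Efron tie handling by default (months-resolution follow-up produces
  ties); Breslow selectable; the two coincide exactly on tie-free
  data.  Wald SEs come from the inverse observed information.
  A monotone likelihood (separation, e.g. an event-free group) is
  reported with `degenerate=True` and the diverging coefficient capped
  at |β| = 15 — surfaced, never silently truncated to a plausible
  number.  Zero-variance covariates are flagged degenerate with HR 1
  and infinite SE.  All p-values are two-sided; significance is 0.05.
- **Harrell's C**: over comparable pairs (the strictly smaller time
  has an event), score ties count half.  Binary scores (every rule
  indicator) use an exact O(n log n) counting path; arbitrary scores
  use vectorized pair enumeration.  The CI is a percentile bootstrap
  over subjects (1,000 replicates by default in the statistic; the
  pipeline uses 200 per evaluation, seeded per model so reports are
  reproducible).  "Discrimination" and "AUC" both refer to this C
  throughout; no time-dependent ROC is computed.

## Pipeline

`run_full_analysis`: high-risk exclusion → candidate dichotomization →
univariate Cox screen on RFS at α = 0.05 (Silva B+C force-included as
a documented prior choice; constant variables excluded with a logged
warning) → exhaustive enumeration of the three families → evaluation
of all 58 models plus the Sedlis reference (59 evaluations) → ranking
→ drill-down of the winner.  Ranking is by descending C-index with χ²
as tiebreak, then model id; degenerate evaluations rank last; when the
C-index and χ² winners differ the report flags it.  Screening uses
RFS; OS evaluation is available but never drives selection.  Models
are evaluated on the intermediate-risk cohort; a config switch permits
full-cohort evaluation as a sensitivity analysis.  Drill-down uses
all-of-subset semantics: each size-k subset of the winner's variables
becomes an "all present" rule.  No multiple-testing correction is
applied anywhere; the report records the number of screening tests so
a reader can judge.

The enumeration is fixed by configuration rather than by the screen
outcome, so a run always produces 59 evaluations regardless of which
variables the screen retains on a particular cohort.

## Synthetic cohort generator

One latent severity variable induces the joint dependence through a
Gaussian copula: factor f's uniform quantile is Φ(ρ_f Z + √(1−ρ_f²) ε),
so marginals are exact and any positive ρ produces the monotone
cross-factor gradients (worse Silva pattern ⇒ larger tumors, deeper
invasion, more LVSI and nodal disease) that make naive single-factor
rules partially confounded, as in real series.  Defaults: Silva
probabilities (0.278, 0.261, 0.461); log-normal size (median ≈ 2.2 cm,
log-scale 0.55); Beta(1.5, 1) DSI fraction; LVSI ordinal probabilities
(0.655, 0.226, 0.119) with pattern A forced to none; nodal/margin/
parametrial base probabilities 16.5%/4.1%/5.8% with the furthest-station
site drawn at (0.684, 0.263, 0.053); age ≈ N(46.4, 10²) truncated at
20; couplings ρ between 0.15 (age) and 0.65 (Silva).  These marginals
follow published cross-tabulations of this disease setting; couplings
are free parameters chosen once to give clear but not deterministic
gradients.

Recurrence times follow Weibull proportional hazards with shape 1.2
(non-constant hazard; shape 1 recovers the exponential) and a linear
predictor summing per-factor log hazard ratios over the *true* four
risk indicators (Silva C: log 2.5, ≥3 cm: log 2, DSI > 2/3: log 3,
substantial LVSI: log 2.5).  The baseline scale (2950 months) was
calibrated once so that, under the default mix and administrative
censoring uniform on 36–168 months, the marginal recurrence fraction
sits near 9%.  Overall survival is recurrence time plus an exponential
post-recurrence survival draw (mean 20 months), censored at the same
administrative time, which guarantees RFS ≤ OS; patients without
recurrence die only by censoring.  Each field group has its own named
RNG stream keyed by (seed, fixed stream id), so adding a field never
shifts existing draws.

What the generator does **not** emulate: loss to follow-up, competing
risks, adjuvant-treatment effects on outcome, cancer death without
recurrence, inter-rater variability in pathology reads, or any joint
distribution beyond the single-latent-factor structure.  Passing tests
therefore demonstrate correctness of the machinery and recovery of
known truth under these conditions — not clinical performance.

## Numerical and design notes

- Times are continuous months in generated data; the Cox machinery
  handles ties (Efron) for real-world month-resolution inputs.
- Report writing uses fixed float formatting and sorted JSON keys, so
  a repeated run on the same cohort/config/seed is byte-identical.
- Per-model bootstrap seeds derive deterministically from the run seed
  and the model id (CRC32 mix, kept below 2³¹).
- Under the default generative conditions the top-ranked rule is
  usually an "any 2" rule over the true factors rather than an
  any-3-of-4 rule: the C-index of a binary indicator rewards the
  larger positive group those rules carve out.  The head-to-head
  property that is stable, and tested, is that the winning Silva-based
  rule out-discriminates the Sedlis criteria in the majority of
  replicates, and that winners are built from the true risk factors.
- The Monte-Carlo calibration experiments (`silvarisk.validation`)
  use 200 replicates at n = 2,000 (Wald coverage of a true HR of 2)
  and 200 null cohorts at n = 300 (screen type-I error); these sizes
  give binomial standard errors of ~1.5% and ~0.35% respectively.

## Known limitations

- The Cox solver targets the small-p regime of this analysis (≤ 6
  binary covariates); it makes no attempt at penalization, stratified
  baselines, time-varying effects or robust variance.
- The C-index bootstrap is a simple subject-resampling percentile
  interval; it is not bias-corrected.
- Exact collinearity in the multivariate fit is detected by rank; the
  near-collinear case is only logged (condition number), not refused.
- The generator's severity couplings are not identified by marginal
  tables alone; they are documented defaults, not estimates.
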