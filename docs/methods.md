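# Methods

## The triage rule

The engine reproduces the decision sequence of computerized five-level
pediatric triage: (i) a **critical shortcut** — a patient in overt
respiratory/cardiac failure at the door is assigned Level 1 and structured
triage stops; (ii) **item aggregation** — the nurse selects every complaint
item that applies, each item carries a base level in {1..5}, and the most
severe (numeric minimum) determines the suggested level; (iii)
**moderation** — configured risk conditions (each forcing an assigned
level, default 2) and any recorded vital sign outside its age-banded
reference range upgrade the level to the range's escalation level;
moderation and the nurse override are strictly upgrade-only, so
`final_level ≤ suggested_level` numerically and every departure from the
aggregate is flagged in an audit trail; (iv) **fractile mapping** — levels
1..5 map to 0/15/60/120/240 target minutes-to-physician.

Two conventions the engine fixes explicitly:

* **Missing vitals are normal.** Absence is a first-class state (`None` /
  empty cell, never 0); an unrecorded vital can never trigger escalation.
  The same convention applies to warning-score observations.
* **The newborn condition is matched from age.** Any visit with
  `age_days < 28` matches the configured `newborn` risk condition whether
  or not it was recorded.

Age bands are half-open on the day scale — [0, 28 d), [28 d, 3 m),
[3 m, 1 y), [1, 3 y), [3, 7 y), [7, 12 y), [12, 18 y) with 1 month =
30.44 d and 1 year = 365.25 d — a boundary convention that must be fixed
somewhere and is used consistently by the engine, the stratifier and the
generator.

The item table, risk conditions, vital ranges and scoring rubric are one
schema-validated YAML document. The shipped default is a synthetic
fixture (≥ 2 items per complaint category, levels 1–5 covered in both the
medical and surgical groups) so that all pathways are exercised; it makes
no claim of clinical fidelity. The critical shortcut assigns Level 1
("life-threatening emergency" by definition); high-risk profiles keep
their configured assigned level (default 2).

## The reference standard

The Pediatric Early Warning Score sums three components — behavior/early
shock signs, cardiovascular (skin tone, capillary refill), respiratory
(rate, oxygen dependence) — each rated 0–3 through a configurable,
Monaghan-style rubric (a documented stand-in: the pipeline itself consumes
only the component integers). A total ≥ 4 of 9 classifies the visit as a
high-level emergency. The cutoff is a parameter so its sensitivity can be
explored by a sweep, but every primary analysis uses 4.

## Accuracy statistics

The 5-level triage result is cross-tabulated against binary PEWS acuity
and dichotomized at levels {1,2} vs {3,4,5}: TP = high∩{1,2},
FN = high∩{3,4,5}, FP = low∩{1,2}, TN = low∩{3,4,5}. Over- and
under-triage are defined on this dichotomized scale (test high/reference
low and test low/reference high), so agreement + over + under partitions
the cohort exactly; an ordinal per-level reading is not used.

Interval estimation:

* **Proportions** — exact (Clopper–Pearson) 95% intervals by default.
  The method choice was validated empirically: the exact interval
  reproduces all printed intervals of the reference validation study at
  one-decimal rounding, whereas the Wilson score interval (also available
  by name, as is Wald) differs in the last decimal for two of them. This
  is documented as verified-compatible, not known-identical.
* **Likelihood ratios** — the log-method (Simel): for LR+,
  `exp(ln LR ± z·sqrt(1/TP − 1/(TP+FN) + 1/FP − 1/(FP+TN)))`, mirrored
  for LR−. A zero cell makes the variance undefined and yields NA.
* **NA semantics** — every zero-denominator statistic is NA in reports
  (never 0 or ∞); internal values keep full precision and rounding to one
  decimal happens only in the report layer.

Categorical comparisons use the Pearson chi-squared test (no continuity
correction) with a 0.001 study-wide significance level divided across the
declared comparison family (Bonferroni); the conservative level reflects
the very large sample the pipeline is designed for. LOS is compared
across levels by one-way ANOVA computed from the between/within
sum-of-squares decomposition with df (k−1, N−k) — the classical F — with
Scheffé post hoc contrasts: pair (i,j) is referred to
`F = Δ²/((k−1)·MSW·(1/nᵢ+1/nⱼ))` on (k−1, N−k) df, and the simultaneous
interval is `Δ ± sqrt((k−1)·F₀.₉₉₉)·SE(Δ)`. Levels with fewer than two
LOS observations are dropped with a warning. Scheffé needs raw values, so
the module always operates on per-visit LOS, never on summary moments.

## The synthetic cohort generator

The generator emulates the validation-study population whose raw data are
not deposited. Its default parameters encode the published tables
cell-for-cell: the 5-level marginal (217 / 16,575 / 34,832 / 41,302 /
7,580 of 100,506), the per-level probability of PEWS-high (82/217,
1,628/16,575, 489/34,832, 38/41,302, 1/7,580), per-level sex, age-band,
complaint-type, diagnosis and disposition conditionals, and LOS mean ± SD
per level (176 ± 124.4 … 96.5 ± 63.1 min).

Sampling is level-first, then per-level conditionals. Design choices:

* **Acuity | level uses systematic (quota) sampling with a random
  phase**: the j-th visit of level ℓ is high iff
  `frac(φℓ + j·qℓ) < qℓ` with `φℓ ~ U(0,1)`. Among any k consecutive
  same-level visits the high count is within 1 of k·qℓ, so recovered
  sensitivity/specificity track their targets tightly for *every* seed
  while the draw remains random; all attributes other than acuity are
  iid.
* **LOS** is truncated-normal at 0, sampled by inverse CDF. Truncation
  shifts the moments slightly (at level 4, mean 107 → ≈ 116 min); tests
  compare against the truncated moments.
* **PEWS totals** are uniform on {cutoff..9} (high) or {0..cutoff−1}
  (low) and split uniformly over the valid component compositions — the
  total-score distribution is not published, and only the class matters
  downstream.
* **Round-trip by construction**: each visit's complaint item is drawn
  from the items whose base level equals the intended level; recorded
  vitals (half of visits) are drawn inside their age-band range; half the
  level-1 visits enter through the critical shortcut. Consequently the
  engine reproduces `intended_level` for 100% of visits — a verified
  invariant, not an approximation.
* **Newborn consistency**: visits intended for levels 3–5 never sample
  the 0–28 d band (the row is renormalized), because the automatic
  newborn override would force them to level 2. The published cohort has
  ≤ 0.4% newborns in those levels, so the distortion is negligible.
* **Determinism and extension**: each attribute has its own stream
  derived from one seed and consumes exactly one draw per visit, so the
  same (n, params, seed) is byte-identical and increasing n extends the
  cohort without reshuffling earlier visits.

Joint structure the source does not publish (e.g. age × complaint within
a level) is modeled as conditionally independent given the level. The
generator therefore supports pipeline validation and power/sensitivity
exploration; passing tests on synthetic cohorts demonstrate the
*software's* correctness and the statistics' calibration, not clinical
properties of any real triage tool — real data remain necessary for
clinical claims. Abnormal vital signs and oxygen support are not
simulated (the engine's escalation pathways are covered by unit and
property tests instead).

## Problem sizes and numerics

The default test run generates cohorts of 5,000–100,000 visits and one
200,000-visit cohort for the parameter-recovery check, chosen so the
binomial standard errors on the recovered statistics are a fraction of the
reporting precision. Recovery is asserted within 3 standard errors of the
closed-form expectations computed from the parameters (no sampling).
Statistical kernels are verified against independent brute-force
implementations at 1e-10 relative tolerance; interval backends are
cross-checked against a numeric root-finder for the Wilson equations.
Ties in item aggregation need no tie-break (the minimum is well-defined);
degenerate inputs (empty tables, zero margins, single-group ANOVA) raise
typed errors rather than returning silent zeros.

## Known limitations

* The shipped item table, vital ranges and rubric are synthetic stand-ins;
  swap in a site's real configuration for any clinical use.
* Subgroup accuracy values of the original study are not reproducible
  desk-side (per-stratum raw counts are not published); subgroup code
  paths are validated by pooling/consistency properties instead.
* The generator does not emulate secular changes (e.g. a later cohort's
  longer LOS) beyond accepting alternative parameter files.
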