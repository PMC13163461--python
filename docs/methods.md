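# Methods

## The scoring model

BioAGE is an additive heuristic on the content of one structured
coronary CTA report. The base component maps coronary calcium linearly
to age, `39 + 0.1 · CAC` years (CAC in Agatston units), and rule-based
increments stack on top: +5/+10/+15/+20/+20 years for CAD-RADS
2/3/4a/4b/5, +15 for three-vessel disease (LAD, RCA and CX all with a
>50% stenosis), +10 for a ≥70% proximal-LAD lesion, +5 for
non-calcified plaque confined to RCA/CX, +10 (once) for impaired LV
function (LVEF < 50%, or EDV > 200 mL, or ESV > 90 mL), and +5 (once)
for any extracoronary vascular-aging finding such as ascending aortic
ectasia or aneurysm.

Choices the published rule list leaves open, resolved here and
configurable in `ScoringConfig`:

- **Additive composition.** The rule list could be read as averaging
  ("pooling") components, but only the additive reading reproduces the
  canonical worked example (CAC 215.3 + CAD-RADS 3 → 39 + 21.53 + 10 =
  70.53 ≈ 71 displayed). Averaging cannot produce it.
- **CAD-RADS 4a/4b stated as a +15–20 range** → resolved to 4a = +15,
  4b = +20; category 5 (occlusion, unstated) = +20, keeping the mapping
  monotone. Categories 0 and 1 add nothing.
- **Functional increment applies once** even when several criteria hold
  (an "or" rule); absent volumes never trigger it. The LVEF threshold is
  a strict `<` at 50%. The volume thresholds (200/90 mL) are package
  defaults, not published values.
- **Extracoronary increment** magnitude is unstated; default +5, applied
  once regardless of the number of findings.
- **Increments stack across rule families** (category + multivessel +
  proximal LAD + soft plaque); the itemized ledger makes the policy
  auditable, and `total_years = base_years + Σ ledger` holds exactly.
- **Display rounding** is nearest integer, half away from zero; all
  statistics use the continuous total so rounding never moves an AUC.
- **Plausibility window** defaults to [25, 105] years: it excludes the
  canonical failure examples (17 and 123 years) and contains the
  plausible clinical range of the score. Out-of-window totals carry
  `implausible_low`/`implausible_high` and are excluded from evaluation
  while remaining in the per-patient table.

A known irreproducibility: the zero-finding example patient (CAC 0,
CAD-RADS 0, LVEF 77%) is sometimes quoted with a biological age of
42.5 years; the stated framework can only produce 39.0 for those
inputs, and this package returns 39.0.

## Report parsing

The extractor is a deterministic lexicon, chosen over any learned model
so the analysis is exactly reproducible: the downstream statistics
depend on the extracted metrics, not on the extractor's identity. It
handles German and English reports (keyword-voting locale detection),
decimal commas and thousands separators ("1.204,5" → 1204.5 under
`de`), stenosis bands mapped by their lower bound (50–69.9% counts as
>50%, not >70%), per-vessel clauses (LAD/RIVA, RCA, CX/RCX), occlusion
wording as 100%, a negation-guarded high-risk-plaque lexicon, and the
patient-level maximum when several CAD-RADS tokens appear (per-vessel
reporting conventions). Failures are typed and prioritized CAC →
CAD-RADS → function, reporting the first missing key metric; stenosis
described only in synonym vocabulary ("Einengung", "narrowing") with no
CAD-RADS token is classified `ambiguous_phrasing`. Matched character
spans are returned for audit; they always reference substrings of the
input.

## The synthetic cohort

The generator emulates a symptomatic chest-pain population referred to
CTA; the defaults are the study conditions of the analysis:

| quantity | default | note |
| --- | --- | --- |
| n | 346 | cohort size |
| chronological age | N(58.5, 10.8²) truncated [25, 81] y | parent parameters; truncation pulls the realized mean ≈ 0.5 y lower |
| women | 39.6% | Bernoulli |
| CAD-RADS marginal | 20.2 / 15.9 / 31.2 / 16.7 / 8.1 / 4.5 / 3.4 % | pooled 4/5 mass (15.9%) split monotonically over 4a/4b/5 |
| age–severity coupling | Gaussian copula, ρ = 0.4 | marginal preserved exactly; older patients draw higher categories |
| CAC | zero-inflated log-normal per category | see calibration below; capped at 24,328 AU |
| LVEF | N(69.7, 9.7²) truncated [23, 86] % | optional shift for CAD-RADS ≥ 4, default 0 |
| HRP prevalence | 25.4% | category-weighted (0 for CAD-RADS 0), marginal exact by construction |
| follow-up | N(4.2, 1.0²) truncated [2, 6] y | SD shrunk to fit the window |
| MACE | logistic on true BioAGE, slope 0.06/y | intercept auto-calibrated to rate 8.7% |
| event types | 2 : 5 : 22 | death : MI : late revascularization |
| parse-hostile reports | 8.8% | three modes, see below |

**CAC calibration.** Reference marginals for CAC (mean 108.6, SD 263,
range 0–24,328 at n = 346) are internally inconsistent, so the tail
shape is a package choice. The stratum log-means rise with CAD-RADS
(coronary calcium and stenosis are mechanistically correlated) and were
set once so that (i) the cohort CAC mean is ≈ 86 AU with P99 ≈ 570,
and (ii) the implausible-high rate of the score is ≈ 1.8% — because a
CAC of 660 already drives the base formula past the 105-year
plausibility cap, a much heavier tail would make implausibility, not
parsing, the dominant failure mode. Severe categories draw relatively
more non-calcified disease (lower log-means than a pure
severity-monotone tail would suggest), which is also clinically
sensible for 4a/4b/5 lesions.

**Outcome model.** Binary, not time-to-event: the analysis design is a
binary ROC on right-censored follow-up, so the simulator draws one
Bernoulli per patient from `expit(a + 0.06 · BioAGE)` with `a` solved
by root-finding so the mean predicted probability equals the target
rate on the realized BioAGE distribution. Event times (uniform on
(0, follow-up]) exist only to exercise the censoring logic. The slope
0.06/year was fixed once so that, at large n, AUC(BioAGE) on
plausibility-included patients ≈ 0.77 and AUC(chronological age)
≈ 0.58 — the intended operating point of the analysis. The event-type
composition 2:5:22 sums to 29, not the often-quoted 30; the
normalized proportions are used.

**Parse-hostile rewrites.** A seeded Bernoulli(0.088) subset of reports
is rewritten with one of three modes: CAD-RADS token deleted
(→ `missing_cadrads`), stenosis wording replaced by synonym vocabulary
with the token dropped ("Einengung"/"narrowing" → `ambiguous_phrasing`),
or the calcium-score line deleted (→ `missing_cac`). Together with the
≈ 1.8% implausible scores this yields an end-to-end processing success
rate near 89.6% under defaults.

**What the generator does not emulate.** Real report language is far
more varied than two template styles per locale; real CAC has a heavier
tail than the calibrated one; severity, function and HRP are coupled to
age only through the single copula; outcomes carry no competing risks
or hazard structure. Passing tests therefore demonstrate the internal
correctness and calibration of the pipeline, not clinical performance
on real reports.

## Evaluation

- **AUC** by the Mann–Whitney estimator (ties 0.5), identical to the
  trapezoidal ROC area; undefined with a single class (typed error).
- **CI and p-value** from the DeLong structural-components variance:
  Wald 95% CI truncated to [0, 1], two-sided normal test of AUC = 0.5
  (the p-values reported alongside each AUC test that null, not the
  difference between the two scores). An exact Mann–Whitney p-value is
  available via `method="mannwhitney_exact"`. With zero variance
  (perfect separation) the CI collapses to the point estimate and the
  p-value is 0 unless AUC = 0.5.
- **Deviation statistics** are computed on |BioAGE − chronological age|
  (mean, SD with n−1, median, IQR = Q3 − Q1 with linear-interpolation
  quantiles); the signed split (fraction above/below/equal) and the
  signed mean are reported separately, since a mean absolute deviation
  plus a sign split is the only coherent reading of deviation summaries
  of this kind.
- **Batch consistency**: nominal batch sizes (94, 149, 252, 346) are
  treated as cumulative prefixes in cohort order — the printed Ns of
  such tables are cumulative even when described as separate groups —
  so event counts are non-decreasing and the final row equals the
  full-cohort analysis exactly; a disjoint-group mode exists behind a
  flag. Prefixes with fewer than two observations in a class are
  flagged `undefined` rather than erroring the table. In the pipeline,
  batch sizes are capped at the included-record count, since exclusions
  shrink synthetic cohorts below the nominal Ns.

## Pipeline accounting and determinism

Excluded records are retained with a typed exclusion reason
(`parse:<reason>` or `score:<reason>`); the manifest identity
`included = uploaded − parse failures − implausible` is asserted on
every run. All randomness flows from a single integer seed
(sub-streams for generation, outcomes and failure injection), and two
runs with the same config and seed produce byte-identical CSV/JSON
outputs — for that reason the manifest carries a config hash, seed and
version rather than wall-clock timestamps. The deterministic analogue
of interactive re-querying for missing metrics is the typed failure
plus audit spans: a human reviewer can see exactly which field was not
found and where the matched ones came from.

## Problem sizes used in the test suite

Marginal-calibration checks run on one shared 50,000-patient cohort;
signal-recovery runs 100 seeded cohorts of n = 346; the null
(type-I-error) check re-simulates outcomes 1000 times on a fixed
n = 346 cohort; parser round-trip checks 1000 random metric sets in
both locales and all template styles; the scoring oracle compares
10,000 random metric sets against an independently coded rule
evaluator. These sizes keep each Monte-Carlo tolerance at 3+ standard
errors while the whole suite stays in the tens of seconds.

## Known limitations

The lexicon covers the package's template grammar plus common phrasing
variants, not the full space of clinical German/English; negation
handling is clause-local. The plausibility filter bounds only the
total, not component-wise sanity. The binary endpoint discards event
timing. Sex enters only through LV volume means; no sex-specific
scoring is attempted, and group comparisons are limited to a
Mann–Whitney utility on deviations.
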