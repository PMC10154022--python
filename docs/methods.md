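# Methods

## Model structure

The package simulates individual adenoma–carcinoma life courses and replays
them against screening schedules. A person's latent history is generated once
per (preset, seed) and is immutable; screening scenarios only decide which
lesions are removed and when a cancer is found. All stochastic draws come
from per-person substreams derived from one root seed with
`numpy.random.SeedSequence` spawn keys, in disjoint domains for natural
history and screening, so person *i*'s history is bit-identical across
scenarios and population sizes (common random numbers), and the first *k*
persons of an *n*-person run equal a *k*-person run.

### Natural history

- **Other-cause death.** Sampled from a bundled cohort life table by
  inverting the discrete annual-probability CDF, with a uniform within-year
  offset. The table is generated from a Gompertz–Makeham hazard
  `a + b·exp(c·age)` with `a = 5·10⁻⁴`, `b = 2.2·10⁻⁵`, `c = 0.095`, capped
  at age 100 (terminal probability 1). These values give remaining life
  expectancies of about 32.7 y at 50, 24.1 y at 60 and 16.3 y at 70 —
  representative of a present-day average-risk US cohort.
- **Adenoma onset.** Non-homogeneous Poisson process with a
  piecewise-constant baseline age hazard (zero before 30, rising by decade)
  multiplied by a mean-1 person-level frailty: lognormal with variance 1.0 in
  preset-A, gamma with variance 1.3 in preset-B. Onsets are drawn with the
  order-statistics construction on [0, other-cause death age]; lesions that
  could only matter after that age are never needed, because screening cannot
  extend life past other-cause death.
- **Growth.** Each lesion grows linearly in diameter from 1 mm with a
  per-lesion lognormal rate (median 0.55 mm/y in preset-A, 0.45 in preset-B),
  crossing the 6 mm and 10 mm thresholds that define the three size classes.
  Size class is therefore monotone non-decreasing in age.
- **Transformation and sojourn.** Adenoma → preclinical-cancer transformation
  is a piecewise-constant hazard in time, obtained from size-class-specific
  annual probabilities (preset-A: 0.0003/0.0018/0.026 for small/medium/large;
  preset-B: 0.00025/0.0015/0.033) by `h = −ln(1−p)`, inverted against a
  single Exp(1) draw per lesion. A transformed lesion surfaces clinically
  after a lognormal sojourn (mean 3.5 y, sd 2.0 in preset-A; mean 5.0 y,
  sd 2.5 in preset-B).
- **Survival after diagnosis.** Cure-mixture exponential, by detection mode.
  Screen-detected parameters dominate clinically detected ones
  component-wise (preset-A: cure 0.72 vs 0.40, mean 6.0 vs 4.5 y), and both
  modes share one per-person uniform inverted through the quantile function
  with the cure mass at the top, so screen-detected survival dominates
  clinically detected survival *pathwise*, not just in distribution.

Preset parameters are not calibrated to any registry; they were fixed at
design time so that lifetime unscreened CRC incidence lands in a 4–7% band
(reference runs: ≈6.6% for preset-A, ≈6.1% for preset-B) and the two presets
differ structurally (frailty family, growth, sojourn, FIT positivity mode),
so that cross-preset ranges are a meaningful stand-in for cross-model
structural uncertainty. All parameters live in `crc_disrupt/data/*.yaml`.

### Detection

Colonoscopy detects each prevalent within-reach adenoma independently with
its size-class sensitivity (high scenario 0.75/0.85/0.95, low scenario
0.55/0.70/0.90) and preclinical cancer with sensitivity 0.95; detected
adenomas are removed in that scenario only. Colonoscopy specificity (0.86) is
carried in the profile but unused: false-positive colonoscopies affect burden
outcomes only, which are out of scope. FIT positivity has two modes: the
per-person mode is positive with the sensitivity of the most advanced lesion
(0.05/0.15/0.22, preclinical 0.74), or 1 − specificity = 0.03 when
lesion-free; the per-lesion mode ORs independent per-lesion draws
(0/0.114/0.159; preclinical 0.62565 in the first half of the sojourn, 0.886
in the second) with an other-cause-bleeding draw at 0.03 that is independent
of lesion status. The early/late preclinical split at the sojourn midpoint is
an interpretation choice: the source convention prints a single "x/y" pair
without defining the split, and the midpoint is the simplest symmetric
reading. A positive FIT triggers a same-age diagnostic colonoscopy.

### Scheduling

Routine regimens are explicit planned-exam grids (decennial colonoscopy
50–70; annual FIT 50–75). Any colonoscopy that finds adenomas moves the
person onto the surveillance track: the next colonoscopy follows the MSTF
interval looked up from the findings at the two most recent colonoscopies
(shortest interval wherever the guidelines give a range), and the routine
grid is permanently superseded — including for FIT users, a deliberate
resolution of an ambiguity (surveillance exit rules take precedence over any
return to the original modality). A normal first or diagnostic colonoscopy
outside surveillance instead imposes a 10-year blackout on the routine grid
(a person with a normal diagnostic colonoscopy at 60 under annual FIT resumes
FIT at 70). Surveillance stops after age 85 unless the most recent exam found
adenomas: adenomas at 83 schedule an exam at 90; a negative exam at 83 whose
next interval lands at 93 ends surveillance.

### Disruptions

Disruptions apply from April 2020 (calendar 2020.25; cohort ages are exact at
that date). Short delays of 3/9/18 months shift the first post-pandemic
planned exam and carry the shift forward to all later planned exams;
surveillance exams triggered after the pandemic follow their own intervals
from the (delayed) actual exam dates, with only a person's first
post-pandemic surveillance exam shifted. Long-term delays replace the
post-pandemic plan with explicit colonoscopies at 65 and 75 (50- and
60-year-old cohorts) or at 75 (70-year-old cohorts), deliberately scheduling
past the usual stopping age. Switching replaces the post-pandemic plan with
annual FIT to age 75 shifted by the switch's own delay, permanently.
Discontinuation cancels everything from April 2020 on, surveillance included
— the worst-case boundary. Only the cohort × disruption combinations defined
by the study grammar are constructible; anything else raises a configuration
error before simulation starts.

### Outcome accounting

Life-years accrue from the beginning of 2020 (anchor age = cohort age −
0.25), truncated at zero; pandemic effects start at 2020.25. The 0.25-year
offset is common to all arms of a contrast and cancels in every difference.
The cohort at risk is defined once per (cohort, preset, sensitivity): persons
alive at April 2020 and not diagnosed before it under the no-disruption
replay; the same mask applies to the no-screening and disrupted arms, so the
identities `LYND = LY + LYL` and `LYND = LYNS + LYG` hold exactly by
construction at full precision. Monte-Carlo standard errors are person-level
(per-arm and for the paired differences). Rounding (integers for LY columns,
nearest integer for percentages, half-up) happens only at report time.

## Synthetic data: what it does and does not emulate

The generator emulates an average-risk US cohort of a given birth year with
heterogeneous adenoma risk, realistic old-age mortality, and two structurally
different natural-history models. It does **not** emulate: serrated-pathway
cancers, stage-specific treatment, calibrated incidence/mortality curves of
any real model or registry, adherence behaviour beyond the scenario
definitions, within-year exam jitter, or COVID-attributable non-CRC
mortality. Passing tests therefore demonstrate correctness of the mechanism
and the qualitative structure of disruption losses (ordering, ranges,
accounting), not quantitative agreement with any published absolute
life-year projection, which depends on calibrations that are intentionally
out of scope.

## Numerical choices

- Exams occur at exact scheduled continuous ages; ties between a scheduled
  exam and a latent clinical diagnosis at the same instant resolve in favour
  of the diagnosis only when strictly earlier (measure-zero otherwise).
- Age comparisons in the scheduler use a 1e-9-year tolerance.
- Population digests hash event ages quantised to 1e-9 years to avoid
  platform float-formatting drift.
- Lesion-free persons skip the replay loop entirely: false-positive FITs and
  their diagnostic colonoscopies cannot change their life-years, cases or
  deaths, so outcomes are unaffected (burden outcomes are out of scope).
- Degenerate inputs are contracts: negative hazards, probabilities outside
  [0,1], non-terminal life tables, undefined surveillance pairs and undefined
  cohort × disruption combinations raise configuration errors.

## Scale and runtime

Test-suite property checks (accounting conservation, zero-disruption
identity, delay-severity dominance, sensitivity-scenario comparisons) run on
100,000-person populations per preset — about 40 s on one CPU — with
3-standard-error Monte-Carlo tolerances on every stochastic assertion. The
full 49-scenario grid at n=800 per cohort runs in a few seconds and is
audited for exact accounting in the test suite. Default experiment sizes are
the user's choice; standard errors are always reported so any n is
interpretable.

## Known limitations

- The two presets bound structural uncertainty only in the dimensions they
  vary; they are not fitted models, and absolute life-year levels should not
  be compared against calibrated-model publications.
- Short-delay effects are small relative to Monte-Carlo noise below roughly
  n=10⁵; at small n their point estimates can be slightly negative (delayed
  exams catch marginally larger, more detectable lesions), as also happens in
  published comparative tables.
- FIT bleeding draws are independent across exams (no persistent bleeder
  trait), and per-lesion FIT draws are independent across lesions.
- Discontinuation cancels surveillance of previously detected adenomas too;
  this is the stated upper-bound reading of the worst-case scenario.
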