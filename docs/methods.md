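# Methods

This note documents the statistical procedure `moodews` implements, the
synthetic data it is validated on, and the design decisions taken where
the procedure was genuinely open.  Nothing here reports an empirical
number that the test suite or `scripts/acceptance.py` does not itself
compute.

## Data model

**Scheduled beep grid.** All analyses are anchored to the *scheduled*
assessment grid: `days × beeps_per_day` slots (default 119 × 5),
0-based, ranges half-open.  A slot exists whether or not the beep was
answered; missing beeps are NaN and are never imputed.  Calendar
structure (day, weekday) is carried explicitly so that overnight lags
and weekend composition are well defined even on segment slices.

**Weekly scales.** ASRM (0–20) and QIDS-SR (0–48) sum scores per week.
A transition at week *w* requires `score[w] − score[w−1] ≥ 6` and no
difference ≥ 6 ending at weeks *w−1* or *w−2*.  Differences that would
reach before the first recorded week are treated as stable (nothing
rose); an antecedent week recorded as missing disqualifies the
candidate, because stability cannot be verified, and is logged.  The
threshold (6), the week-to-beep alignment (completion slot when
recorded, else `week × 7 × beeps_per_day`) and the control-stability
threshold (4) are configuration, not constants.

**Segments.** Each transition yields a pre-transition segment from the
study start (or the previous transition's aligned beep, so segments
never overlap) up to, excluding, the aligned beep.  Non-transitioning
patients contribute at most one control segment: the earliest run of
weeks with all |week-to-week changes| < 4 on both instruments covering
≥ 245 scheduled beeps — the mean pre-transition length, so controls are
compared on an equal footing.  Absence of such a run is a valid outcome.

## Preprocessing

Per segment and momentary state, observed values are winsorized to the
segment's [P5, P95].  The quantile convention defaults to linear
interpolation between order statistics and is configurable; note that
only order-statistic conventions make winsorization exactly idempotent
(under interpolation a second pass can tighten the bounds slightly on
extreme distributions).  Fewer than 20 observed values leave the
segment unclipped with a warning.

Detrending removes slow trends in the mean that would otherwise
masquerade as rising variance or autocorrelation.  The primary method
is a Nadaraya–Watson smoother with a Gaussian kernel over the scheduled
slot index of *observed* beeps (gaps do not stretch the kernel).  The
bandwidth defaults to 10% of the segment's observed span — wide enough
to leave two-week indicator dynamics intact, narrow enough to track
slow drift — and a sensitivity sweep over {5%, 10%, 20%} is a
`--bandwidth-frac` flag away.  Residuals are mean-centered per segment;
this is a pure normalization, since both indicators are invariant to a
common shift, and it pins the residual sum at zero.  The sensitivity
variant removes an OLS line *within each window* instead; agreement
between the two variants' significance patterns is summarized by
Cohen's kappa with the conventional bands (< .40 low, .40–.59 weak,
.60–.79 moderate, ≥ .80 high).

## Moving-window indicators

Windows span two calendar weeks — 70 scheduled slots at 5 beeps/day —
and slide one slot per step.  Because the window is a whole number of
weeks, every placement covers the same number of weekend days at day
granularity; a strict mode (`stride = beeps_per_day`) keeps weekend
composition constant at slot granularity too.  "70 observations" is
read as 70 *scheduled* slots, not 70 completed assessments: this keeps
calendar alignment exact, and per-window observed counts are carried
for audit.

* **ar1** — least-squares slope of residual[t] on residual[t−1] over
  pairs of consecutive slots that are both observed *and* on the same
  calendar day.  The overnight pair of each day (evening → next
  morning) is never formed, so an 8–12-hour gap cannot contaminate the
  3-hour lag.  Pairwise deletion handles missingness.
* **sd** — sample standard deviation (n−1) of the observed residuals
  in the window, listwise per value.

Windows with insufficient coverage are invalid rather than silently
estimated: the thresholds default to 50% of capacity for each statistic
— 35 of 70 slots for sd, and 28 of the 56 possible same-day pairs for
ar1 (56, not 69, because each day contributes `beeps_per_day − 1`
pairs).  At 24% missingness the expected pair count is ~32, so a 50%
pair-capacity floor keeps most windows usable while discarding sparse
ones.

For a pre-transition segment the window ending flush at the transition
beep is dropped (unless it is the only one), matching the convention
that a transition at the 150th observation supports 150 − 70 = 80
windows; control segments use every placement
(`n = length − 70 + 1`).

## Trend testing

Indicator values from windows ending in the final two weeks before the
transition (or before the control segment's end, mirroring the
pre-transition evaluation symmetrically) are tested for a monotone
rise with the Mann–Kendall statistic: `S = Σ_{i<j} sign(x_j − x_i)`,
tie-corrected var(S), τ (tau-b) as effect size, and a
continuity-corrected normal approximation for the p-value.  Series
shorter than the fortnight use all available points; fewer than 3 valid
points skip the test with a recorded reason.

**Serial dependence.** Consecutive windows share 69 of 70 slots, so the
indicator series is smooth and the nominal var(S) is a severe
underestimate.  The Hamed–Rao correction inflates it by

    1 + 2/(n(n−1)(n−2)) · Σ_i (n−i)(n−i−1)(n−i−2) · ρ_s(i)

with ρ_s(i) the lag-i autocorrelation of the ranks of the Sen-detrended
values, restricted to significant lags (|ρ| > z_{.975}/√m).  A key
design choice: ρ_s is estimated on the segment's **full** indicator
series, not only on the tested fortnight.  The dependence length of the
indicator series equals the window length — i.e. the entire tested
stretch — so a fortnight of values cannot reveal its own
autocorrelation structure; the full series can, and in simulation this
choice roughly halves the realized false-positive rate relative to the
textbook single-series recipe (which remains available as
`HamedRaoOptions(acf_source="fortnight")`, with lags capped at n/4).
The factor is floored at 1 (configurable), and series with n < 10 fall
back to the uncorrected test with a warning.

**Multiplicity and direction.** Within each patient, all
(state × indicator × segment) corrected p-values enter a
Benjamini–Hochberg step-up at q = .05.  A test is an early warning
signal only if it survives BH *and* τ > 0 — a significant fall is not a
warning.  P-values are two-sided by default; a one-sided mode exists
for sensitivity analyses.  The two detrending variants are treated as
separate analyses, each with its own FDR family.

## Evaluation

Per (state, indicator, transition type): TP/FN over transition segments
of that type, FP/TN over control segments (controls are shared, so
specificity carries no type subscript).  Prevalence is the fraction of
all segments carrying a transition of the type (e.g. 7 manic of 22
segments → 32%).  PPV/NPV follow the prevalence-form identities given
in the README; when the segment classes embody the prevalence these
reduce exactly to TP/(TP+FP) and TN/(TN+FN), which the tests verify.
Averaged rows treat a segment as alarm-positive when *any* state shows
the indicator's EWS.  Four degenerate alarm patterns are distinguished
from honest percentages — an indicator that never fires has an
*undefined* PPV ("no alarms"), not 0%; 0% is reserved for alarms that
occur only in controls — plus the two symmetric NPV cases.  The report
also carries the mean number of significant EWS per segment class and
the Jaccard overlap of the ar1 and sd alarm sets per transition type.

## The synthetic cohort

The generator produces what the analysis assumes, with known truth:

* latent AR(1) per patient × state, `x_t = φ_t x_{t−1} + ε_t`,
  `ε_t ~ N(0, σ_t²)`, with defaults φ = 0.2 and σ = 10 slider points;
  the first beep of each day is drawn from the local stationary
  distribution (no overnight carryover), mirroring the estimator's
  overnight exclusion — a carryover flag exists for robustness checks;
* observed value = `clip(50 + x, [0, 100])`; with the default gain the
  clipped fraction is well under 5%;
* missingness MCAR at 24% (76% compliance), with an optional elevated
  post-transition rate, off by default;
* planted EWS: φ and/or σ ramp linearly over the final 14 days before
  the anchor transition (e.g. 0.2 → 0.7), then reset to baseline so a
  later segment of the same patient starts clean;
* weekly scales: small stable integers (changes ≤ 2) with programmed
  jumps of ≥ 6 after two frozen antecedent weeks, a ~2-week elevated
  episode, then return to baseline; "unstable" patients oscillate by
  5 points, yielding neither transitions nor control runs.

What this emulates — and what it does not: bounded sliders, the beep
schedule, overnight discontinuity, missingness and abrupt weekly jumps
are realistic; the marginal distribution of momentary states, circadian
structure, event-driven mood shocks, mixed states and any mechanistic
bistable mood model are not represented.  Passing tests demonstrate the
pipeline's operating characteristics under its own assumptions, not
clinical validity on real patients.

## Measured operating characteristics

Problem sizes: the false-positive experiment uses 500 replicate
stationary patients (17 states, one 245-slot control segment each); the
power experiment 100 replicate patients with one planted AR ramp and a
transition at week 7 (a 245-slot pre-transition period, matching the
mean); the cohort experiment 20 replicate 22-segment cohorts; the
round-trip check 200 random weekly configurations.

* The transition-rule round trip is exact: every programmed transition
  recovered by type and week, zero false events.
* Uncorrected Mann–Kendall flags roughly 40% of null state-indicator
  tests even after FDR; the corrected pipeline flags well under 1%.
  At the *family* level ("any flag for this patient") the corrected
  rate is ~20%: with ~2–3 effective degrees of freedom per tested
  fortnight, no data-driven variance correction fully calibrates the
  test, only the design-level remedies (longer test stretches or
  non-overlapping windows) would.
* Detection of a single planted 0.2 → 0.7 fortnight ramp at q = .05
  within a 34-test family is rare (~5–10%): the same conservatism that
  controls false positives removes most power at this effect size and
  window overlap.  Group-level signal survives: planted ramps raise
  alarm rates enough that the averaged planted-indicator PPV exceeds
  the transition prevalence in essentially every replicate cohort.

## Known limitations

* The fortnight trend test on maximally overlapping windows is the
  procedure's structural weak point — simultaneously anti-conservative
  at the family level and low-powered per test.  The package exposes
  window length, stride, test-stretch length and the correction variant
  so that better-calibrated designs (e.g. daily stride) can be run, but
  the defaults reproduce the canonical procedure.
* Winsorization and detrending operate per segment; results therefore
  depend (documented, configurable) on segmentation.
* The smoother's abscissa is the scheduled slot index, not clock time;
  long gaps do not widen the kernel in time units.
* Control segments anchor their "final fortnight" at the segment end by
  symmetry with pre-transition segments; this choice directly shapes
  false-positive accounting.
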