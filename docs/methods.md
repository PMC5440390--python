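# Methods

## Problem and model

Habitual physical activity is increasingly estimated from 24 h-accelerometry
worn over one or two weeks. Interpreting the count signal requires knowing
when the device was *not* worn: non-wear time (NWT) left in the data inflates
the lowest activity intensity, while wear time misclassified as non-wear and
excluded deflates sedentary estimates. The standard automated rule flags a
period as non-wear when the vector-magnitude count — the rounded Euclidean
norm of the three axis counts per 60 s epoch, zero iff no axis registered any
acceleration — is zero for more than T consecutive minutes, with no
interruptions tolerated (the "T-min algorithm"; T ∈ {60, 90, 120, 150, 180}
here). The inequality is strict: a run of exactly T zero minutes does not
qualify, so at 60 s epochs a >60 min period needs at least 61 zero epochs.
Rules developed for waking-hours recordings are stressed by 24 h wear, because
motionless spells during sleep routinely exceed 60 minutes while truly being
wear time.

This package implements the detection rule and two ways of validating it
against an activity diary, the reference standard, per participant and pooled
over a cohort, each stratified three ways: the *total time of assessment*
(first to last recorded diary time point), and the diary-derived *waking* and
*sleeping* phases.

### Period-level classification (fourfold table)

Diary entries are merged when adjacent or overlapping, then thresholded at the
same T as the detector. Each thresholded diary period is paired greedily with
the accelerometry period of maximal minute overlap (ties broken toward the
earlier diary period; each period matched at most once). A pair whose overlap
is at least 50 % of the reference duration is a true positive (a); positive
but sub-50 % overlap is "not assigned" and excluded from both metrics; a diary
period overlapping nothing is a false negative (c); an accelerometry period
overlapping no thresholded diary period is a false positive (b); a wear
evaluation unit untouched by detection is a true negative (d). Sensitivity is
a/(a+c), specificity d/(b+d), each undefined (reported as null) on a zero
denominator.

Two points here are interpretations, because no published operational
definition exists, and both are configurable rather than asserted as faithful:

* **Overlap denominator.** The 50 % rule is measured against the diary
  (reference) period's duration by default; `overlap_denominator` also accepts
  `accelerometry` or `shorter`.
* **True-negative units.** Wear has no natural period boundaries. The
  implemented units are the sub-threshold diary entries (short removals such
  as showering, which a correct detector must leave alone), optionally plus
  the wear blocks between reported entries inside the assessment window.
  The default `tn_units="entries+wear_blocks"` keeps specificity defined even
  when every reported removal exceeds the threshold; `entries` restricts to
  reported short removals only.

### Minute-level overlap decomposition

Within the assessment window the diary's and the detector's non-wear minutes
form two sets. Their union — the *potential total NWT* — decomposes exactly
into minutes flagged by both, by the diary only, and by accelerometry only;
the three shares sum to 100 %. Two variants: both sources thresholded at T
("thresholded" diary mode), or the diary taken at face value regardless of
entry length ("any" mode), which measures how much reported non-wear the
algorithms can see at all. Stratum restriction is done at the minute level
(intersection with the stratum's phase minutes) by default, since the analysis
is defined minute-by-minute; a period-level variant (keep whole periods
attributed to the stratum) is behind `stratum_restriction="period"`.

### Phase attribution and timeline conventions

All intervals are half-open `[start, end)` on the one-minute grid; diary
seconds are truncated on read. A period spanning a wake/sleep boundary is
attributed to the phase kind covering the majority of its minutes; an exact
tie goes to the phase containing the period's first minute. This attribution
rule is a package choice — boundary-spanning periods have no published
treatment — and is deliberately confined to one function (`assign_phase`).
Minutes of the assessment window covered by no diary phase enter the total
stratum only. Recording gaps split an epoch series into segments; zero runs
never span a gap, and a run abutting a segment edge is flagged (`at_gap`)
because its observed length is only a lower bound.

## Synthetic cohorts

No raw cohort recordings are publicly deposited, so the package ships a
generator that emulates the data-generating process the analyses assume, and
all empirical tests run on its output:

* alternating waking (16 h) and sleeping (8 h) phases with ±30 min jitter over
  7 (default) or 14 days;
* device removals as a Poisson process (0.85/24 h), mostly during waking
  (90 %), log-normal durations with median 25 min and σ = 0.75 — ≈ 12 % of
  removals exceed 60 min, matching the field observation that the large
  majority of diary-reported removals (showering, changing clothes) are
  shorter than any usable threshold;
* wear-time zero runs that are *not* removals: short sedentary spells during
  waking (median 10 min) and long motionless runs during sleep, log-normal
  with median 50 min (σ = 0.7) for hip placement and a lighter tail
  (median 25 min, σ = 0.5) for wrist-at-night wear — the mechanism behind
  false-positive detection during sleep;
* non-zero wear counts drawn log-normally (they only need to be positive;
  magnitudes are not biomechanically calibrated);
* a reported diary derived from the exact one by jittering entry start/end
  times (SD 5 min) and rounding to 5 min, the way participants round clock
  times.

Placed zero runs are kept from touching each other (one-minute margin) so each
is a maximal run of exactly its intended length; removals that cannot be
placed are dropped with a log message. Presets: `activE_like` (hip, 14 days),
`kora_like` (hip/wrist mixed, 7 days, lighter sleep tail), `ideal` (no
reporting error, removals all ≥ 75 min, wear zero runs capped at 45 min — the
parameter-recovery condition under which every metric must be exactly 1.0 at
T = 60), and `worked_example`, a deterministic single-day layout with reported
removals of 30, 30, 115, 130 and 30 minutes against detected zero runs of 65
and 140 minutes (waking) and 75 minutes (sleeping), used as a fully
hand-checkable fixture. In the worked example the count stream follows the
accelerometry layout rather than the diary, because the two sources disagree
by construction; in the stochastic generator every true removal minute has
count zero, while the converse is false by design.

What passing tests on these cohorts show: the pipeline recovers a known truth
exactly under ideal conditions, and reproduces the qualitative behaviour of
real 24 h recordings — specificity rising with T as sleep motionless runs stop
qualifying, and the accelerometry-only share of the potential total falling
with T. What they do not show: agreement with the absolute published
cohort-level values (e.g. per-study sensitivities or overlap percentages),
which depend on unavailable raw recordings and diaries and are **not**
reproduced here; the synthetic distribution families (Poisson counts,
log-normal durations) are pragmatic, not estimates fitted to those cohorts.
Real diaries also omit and misreport events; the generator's error model
perturbs times but never drops or invents entries.

## Numerical and reporting choices

* Durations are integral minutes throughout; percentages are exact ratios of
  minute counts, so the decomposition conserves minutes exactly and shares sum
  to 100 within floating-point noise (tested at ±0.1).
* Undefined ratios (empty union, zero fourfold denominators) are `None`/null,
  never 0 or NaN-as-number.
* Result writers round sensitivity/specificity to 2 decimals and percentages
  to 1 decimal; in-memory values stay full precision.
* Epoch lengths other than 60 s are accepted only when the threshold converts
  to a whole number of epochs; daylight-saving or otherwise non-monotone
  timestamps are a hard read error.
* Cohort summaries pool periods across participants by default (total counts
  over total counts; per-24 h rates divide by summed half-phase-pair units); a
  per-participant-mean variant is behind `pooled=False`.

## Problem sizes used in the shipped checks

The randomised oracle comparison uses 1,000 series of up to 10,080 epochs at
all five thresholds; parameter-recovery and trend checks use 200 simulated
participants at 7 and 14 days respectively. These sizes make the binomial
noise on pooled proportions small (±3 percentage points covers the removal
tail calibration at n ≈ 1,200 events) while keeping the full suite fast.

## Known limitations

* The true-negative enumeration and the 50 % denominator are interpretations
  (see above); absolute specificity values are therefore convention-dependent,
  which is also why wear-block TNs make total-stratum specificity not directly
  comparable across strata.
* Detection runs on the full count stream and is stratified afterwards;
  within-phase detection would slightly change boundary-spanning runs.
* No interruption-tolerant ("artefactual movement") variants are validated;
  the tolerance option exists but is off by default everywhere.
* Sub-minute resolution, raw-signal processing and count generation from
  accelerations are out of scope.
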