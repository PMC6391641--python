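# Methods

This note records the model behind `adherepay`, the defaults and why they
were chosen, the numerical and design decisions made where the rules left
room, and what the synthetic cohort does and does not show about real
trial data.

## Study weeks

Adjudication operates on per-participant, enrollment-anchored 7-day
windows: week *w* covers local dates
`[enrollment + 7(w−1), enrollment + 7w)` in a single configurable study
timezone (`StudyConfig.study_timezone`, default `America/New_York`).
Enrollment anchoring was chosen over calendar weeks because cohorts
enroll on a staggered calendar, and per-participant windows keep every
participant's week *w* at the same study stage. Week membership is
decided by the event's *local calendar date*, not elapsed hours, which
keeps window boundaries stable across daylight-saving transitions. The
cut-off is local midnight at the end of day 7; a participant is "due"
for week *w* once that date is reached.

## Weigh-in quality control

Home cellular scales can be gamed (a proxy weigher, partial
weight-bearing). The screen flags any participant-local calendar day
whose readings have relative spread `(max − min)/min` strictly greater
than `same_day_gaming_fraction` (default 0.10) and removes *all* of that
day's readings — with discordant values there is no basis for deciding
which reading is genuine. Three choices here were genuinely open and are
worth stating:

* **Denominator**: the day's minimum weight. Using the minimum is the
  most sensitive of the plausible normalizations (min/max/mean), i.e.
  the conservative choice for an anti-gaming screen.
* **Strictness**: the boundary case (spread exactly 10%) is retained;
  removal requires a strictly greater spread.
* **Granularity**: day extremes rather than consecutive-pair
  differences. For two readings they coincide; for more, the day-extreme
  rule dominates any pairwise rule, and the two are compared against a
  brute-force pairwise oracle in the tests.

The filter is idempotent and monotone in the threshold (a larger
threshold never removes more). It deliberately ignores cross-day
variation: week-to-week change is the very signal being adjudicated.

## Weekly criteria

* **Diet**: ≥ `min_logging_days` (default 5) days in the window with
  logged calories ≥ the sex-specific threshold (1000 kcal female /
  1200 kcal male), at least one qualifying day falling on a Saturday or
  Sunday in the study timezone (`require_weekend_day`, default on).
  Per-entry app rows are summed to daily totals at ingestion; the
  criterion is about daily totals.
* **Weight**: the week must be *evaluable* — ≥ `min_weighins_per_week`
  (default 2) retained weigh-ins at ≥ 2 distinct timestamps. The change
  is first-minus-last retained weight by timestamp; the criterion is met
  iff the change is strictly positive. Zero change is not loss. A
  non-evaluable week fails with the change reported as missing rather
  than zero, so downstream consumers can distinguish "didn't lose" from
  "couldn't tell".

Both criteria are evaluated for every participant regardless of arm —
the data streams exist in all arms and staff review both — while the arm
determines which criteria pay and which message scenario applies.

## Payouts

Money is integer cents throughout; caps and halving never touch floats.
The schedule assigns each week a diet component `D_w` and a weight
component `W_w` (defaults identical). Weekly component earnings are:
group 2 `D_w·[diet met]`; group 3 `W_w·[weight met]`; group 1
`⌈D_w/2⌉·[diet met] + ⌊W_w/2⌋·[weight met]` — the combined arm splits
the same weekly maximum across two behaviors, with any odd cent
deterministically assigned to the diet half; group 4 earns nothing.

The per-cohort weekly floor (default $2.00 in cohort 3, $0 elsewhere)
is added unconditionally for incentive arms: the payout range in cohort
3 is $2–$28 per week rather than $0–$28. The weekly payout including
the floor is clipped at `weekly_cap` ($28.00), so the floor can never
push a week past the printed maximum. Cumulative earnings are truncated
at `total_cap` ($300.00). The foregone amount is computed before total-cap
truncation as (weekly maximum attainable − weekly earned); the floor
appears in both terms and cancels, so a missed week's message quotes
exactly the component value the participant failed to earn.

**Default schedule.** Only the envelope is fixed by the design ($300
total per arm, ≤$28 in any week); the week-by-week split is a site
choice. The shipped default escalates — $10 for weeks 1–12, $13 for
weeks 13–20, $16 for weeks 21–23, and a $28 final week — summing to
exactly $300 for a single-component arm. Escalation back-loads reward
into the period where adherence typically sags. Any schedule satisfying
the envelope invariants (validated at construction) can be configured.

## Messaging

One outcome SMS per adjudicated participant-week. Earned scenarios
state the earned amount; the missed scenario is loss-framed, quoting the
foregone amount ("you would have earned $X") to exploit loss aversion;
the control arm receives encouragement with no dollar amount. Bodies
must fit one 160-character SMS; the bound is enforced twice — at
configuration time against worst-case renderings, and again at each
render, where an overflow raises rather than truncating (silent
truncation could corrupt the stated amount). Dollar amounts render
without cents when whole (`$28`, `$2`) and with two decimals otherwise
(`$13.50`). The behavior phrase in the both-behaviors-missed message is
"log your food or lose weight": the longer phrasing used when a single
behavior is missed ("lose enough weight") would push the combined
rendering past 160 characters. Tip messages (twice weekly, cohorts 2–3
by default) cycle deterministically through a configurable library; the
shipped library is placeholder content. Session reminders go to every
arm alike.

## Ledger

Entries move through `computed → approved | edited | denied`, then
`approved/edited → scheduled → paid`. Scheduling applies a configurable
delay after review (default 24 h — the institutional gap between the
notification text and money reaching the debit card; holiday extensions
are out of scope). Edits must respect both caps; an entry whose
scheduling would push a participant's committed (scheduled + paid)
total past `total_cap` is held with a reason instead of scheduled.
Every mutation appends to an event log and replaying the log
reconstructs identical state, so the CSV review-actions workflow is
auditable and crash-safe by rebuild. Review-actions files are applied
all-or-nothing: a conflicting duplicate action aborts before any state
changes. The outcome text is composed at adjudication time, before
review — notification precedes payment, so a later denial does not
retract a sent message; sites wanting review-first ordering can simply
send the outbox after applying actions.

## Synthetic cohort

The generator emulates the behavioral structure the engine assumes, not
human physiology:

* **Enrollment**: cohorts of 34/31/31 (N=96) starting 12 weeks apart,
  individual enrollment jittered 0–6 days; groups assigned by permuted
  blocks of the four arms within cohort.
* **Adherence**: each participant draws a daily logging propensity from
  Beta(6,2) (mean 0.75) and a weighing propensity from Beta(5,3) (mean
  0.625); days are independent Bernoulli given the propensity. A linear
  logit drift (default −0.02/week) mimics declining participation.
  These values are loosely calibrated to the high-but-declining
  adherence such trials report (early averages around 5 weigh-in days
  per week); they are synthetic defaults, not estimates. Setting
  `p_log_day`/`p_weigh_day` overrides the draw with a fixed value for
  forced-adherence scenarios.
* **Calories**: logged days draw Normal(1400, 250) kcal, floored at 0 —
  so a realistic minority of logged days falls below threshold.
* **Weight**: baseline Normal(105, 15) kg; the true trajectory loses
  0.25 kg per adherent week (adherent = that week's diet criterion held)
  and is flat otherwise, with i.i.d. Normal(0, 0.4) kg measurement noise
  and readings rounded to 0.01 kg. About 15% of weigh-in days get a
  second genuine reading.
* **Gaming**: each weigh-in day is independently gamed with probability
  0.01; the injected reading multiplies the day minimum by
  Uniform(1.10, 1.5), nudged up after rounding if needed so the day's
  spread strictly exceeds the threshold — injected days are removable by
  construction, which is what makes the detection-rate-equals-one
  property a test of the filter rather than of luck.
* **Dropout**: per-week withdrawal hazard 0.01 from week 2 on; withdrawn
  participants stop emitting events and are skipped by the runner (their
  pre-withdrawal weeks therefore appear in ground truth only).

Ground truth for both criteria is computed *during generation* by an
inline, self-contained restatement of the rules applied to the rounded
written values — independent code from the engine modules it is used to
check. One seed drives a single `numpy` generator; a fixed seed
reproduces every output file byte for byte.

**What passing tests show, and don't.** Exact agreement between the
engine and ground truth shows the rule implementations are mutually
consistent and deterministic, and the envelope/cap/messaging properties
hold under realistic volumes. The simulator omits device faults,
transmission gaps, retrospective (back-dated) logging, incentive→behavior
feedback, and physiological weight dynamics, so it demonstrates nothing
about behavioral efficacy and only bounds, not guarantees, robustness to
real-world data quirks (the malformed/duplicate/unknown-record paths are
exercised by dedicated fixtures instead).

## Numerical and degenerate-input choices

* Caps, halving, floors: integer arithmetic only; the odd-cent tie-break
  goes to the diet component.
* QC spread uses float division; the boundary test pins behavior at a
  representable exact-10% pair, and the threshold comparison is strict.
* Empty event streams adjudicate to both criteria failed (missed /
  control scenarios), not an error; empty files parse to empty streams.
* Duplicate weigh-in transmissions (identical participant, timestamp,
  weight) are dropped with an error code; identical-timestamp distinct
  weights are kept (two readings can share a scale minute) but cannot by
  themselves make a week evaluable.
* Problem sizes in the shipped tests and acceptance script: the full
  default cohort (96 participants × 24 weeks, ≈10⁴ events) for
  end-to-end properties, single-block cohorts for forced-adherence
  scenarios, and exhaustive enumeration (128 day-subsets; 864 payout
  cells; ~2.5×10⁴ renderings) where the rule space is small enough to
  enumerate.

## Known limitations

* The "sufficiently active" eligibility notion is reduced to roster
  status = active; no data-transmission-based activity heuristic is
  implemented.
* No cross-day outlier detection or device-fault diagnosis; a
  consistently miscalibrated scale passes QC.
* The ledger models states and caps, not authentication or an actual
  payment rail.
* Weekly windows assume the enrollment date is the participant's first
  study day; partial first weeks are not modeled.
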