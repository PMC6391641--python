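# adherepay

A weekly financial-incentive adjudication engine for remote weight-loss
trials, with a synthetic cohort simulator so the whole pipeline runs and
tests without real participant data.

## The problem

Contingency-management weight-loss trials reward participants in near real
time for objectively verified behaviors: logging their diet in a phone app
and losing weight on a cellular home scale. Running such a trial requires a
weekly batch of unglamorous but correctness-critical plumbing:

* **ingest** time-stamped weigh-in events and per-day calorie logs from
  device/app exports, tolerating malformed and duplicated transmissions;
* **screen** weigh-ins for gaming — a proxy weigher or partial
  weight-bearing shows up as discordant same-day readings;
* **adjudicate** two weekly criteria per participant under a 2×2 factorial
  design (incentives for self-monitoring, weight loss, both, or neither);
* **notify** each participant by a single ≤160-character SMS, loss-framed
  when the incentive was missed ("you would have earned $X");
* **stage payments** through a staff review step (approve / edit / deny)
  with an institutional ~1-day delay and hard spending caps.

`adherepay` implements that batch as a typed, tested library plus a thin
CLI. It is aimed at trial engineers and methodologists who need the
adjudication rules to be exact, auditable, and replayable.

## The rules it encodes

For participant *i* in study week *w* (enrollment-anchored, 7-day,
half-open windows in the study timezone):

* **Diet criterion** — at least 5 days of week *w* with logged calories
  ≥ the sex-specific threshold (1000 kcal female / 1200 kcal male), at
  least one of them a Saturday or Sunday.
* **Weight QC** — for each calendar day, if the day's weigh-ins satisfy
  (max − min)/min > 0.10, all of that day's readings are removed.
* **Weight criterion** — with ≥2 retained weigh-ins at distinct times,
  Δ = first − last weight over the week; the criterion is met iff Δ > 0.
* **Payout** — with week-*w* component amounts `D_w` (diet) and `W_w`
  (weight), group 2 earns `D_w·[diet]`, group 3 earns `W_w·[weight]`,
  group 1 earns `⌈D_w/2⌉·[diet] + ⌊W_w/2⌋·[weight]`, group 4 earns 0. A
  per-cohort weekly floor (default $2 in cohort 3) is added
  unconditionally for incentive arms; the weekly payout is clipped at $28
  and the cumulative total truncated at $300. The foregone amount
  (weekly maximum attainable − earned) feeds the loss-framed message.

All money is integer cents end to end.

## Worked example

```bash
adherepay simulate --out-dir data --seed 5
adherepay adjudicate --data-dir data --week all-due --as-of 2024-06-01T09:00:00-04:00
```

The first command writes `roster.csv` (96 participants in cohorts of
34/31/31), `weighins.csv`, `diet.csv`, and the generator's
`ground_truth.csv`. The second runs QC, adjudication, messaging, and
ledger staging for every elapsed week, logging:

```
... adherepay INFO adjudicated 1824 participant-weeks (1824 messages, 1034 ledger entries)
```

1824 is one verdict per non-withdrawn participant per elapsed week; each
verdict produced one SMS body, e.g. for an earned diet-only week

```
Great job on logging your food this week! $10 will be added to your debit card. Keep up the good work!
```

and for a missed week the loss-framed counterpart

```
You did not log your food this week. If you had, you would have earned $10. Please log your food and lose weight for a chance to earn money.
```

1034 positive amounts were staged as `computed` ledger entries awaiting
staff review. Approving them schedules payment one day later:

```bash
adherepay ledger --data-dir data --actions approve_all.csv --as-of 2024-06-02T17:00:00-04:00
```

The same calls are available as library functions (`generate_cohort`,
`run_study`, `compose_weekly_message`, `Ledger`), which is how the test
suite uses the package.

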