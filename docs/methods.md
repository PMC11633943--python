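# Methods

## The evaluation model

The engine treats one patient at one evaluation time as a pure function of a
typed event stream. Every event carries a half-open effective interval
`[start, end)` (ISO-8601 timestamps with offsets; `end` omitted while an
order, device or state is ongoing), so adjacency is unambiguous and interval
arithmetic needs no special cases. A `PatientDayContext` is assembled by
deduplicating on `event_id` (latest-recorded wins, mirroring EHR amendment
semantics; exact recorded-time ties break on the canonical JSON serialization
so assembly is order-independent), sorting, and fixing `day_start` at 00:00
of the evaluation time's calendar day in a configurable timezone (default
UTC). Events that predate admission are kept with a logged warning — charts
really do contain them, and dropping data silently would bias rules that look
back several days.

"Current day" denominators use *elapsed* time, `[day_start, eval_time)`. A
coverage criterion like "compression device in place ≥ 75 % of the current
day" is ill-posed minutes after midnight, so the three day-coverage rules
(the VTE trio) abstain — no flag, reason
`partial_day_below_minimum_elapsed` — until a configurable minimum of the day
has elapsed (default 4 h). Abstention is distinct from a negative result and
can never co-occur with a flag.

## Rule structure and missing data

All 23 metrics are conjunctions of named criteria. Each evaluated criterion
contributes a stable snake_case reason code suffixed `:met`/`:unmet`, and
every input consulted is echoed in `inputs_used` either as its resolved value
or as a `missing(<policy>)` marker. This is deliberately the granularity at
which a chart reviewer audits a flag: which branch fired, from which datum.

Three missing-data policies make every rule total over incomplete charts:

| policy | absent datum | resolution |
|---|---|---|
| expected-present | chemoprophylaxis order, nutrition record, code status … | negative finding |
| expected-absent | device episode, bleeding diagnosis, transfusion … | positive finding |
| lab | INR, aPTT, platelets, glucose | assumed normal (configured defaults: INR 1.0, aPTT 30 s, platelets 250 k/µL, glucose 100 mg/dL) |

Medication state is resolved **only** from orders and MAR actions; flowsheet
rows claiming a dose are structurally invisible to medication queries (they
are not consulted at all, rather than filtered), which is what makes the
note/MAR-discordance invariance an architectural property rather than a
tested coincidence. Flowsheet documentation *is* a legitimate input where it
is the only source (liquid-stool output for the rectal-tube rule).

An evaluator that raises internally yields an abstained result with reason
`evaluator_error`: a broken rule must never produce a false actionable alert,
because clinician trust is the scarce resource such a tool spends.

## Thresholds

Printed, authoritative values: glucose ≤ 70 mg/dL (inclusive); compression
coverage ≥ 0.75 (inclusive); platelets < 50 k/µL, INR ≥ 1.5, aPTT > 40 s over
a 3-day lookback (comparators exactly as printed, screened as *any* abnormal
value in the window); > 1 PRBC unit per 24 h (counted as transfusion events,
a literal reading of "prior 24 hours"); tidal volume > 8 mL/kg predicted body
weight; delivered < 80 % of goal kcal (exactly 80 % is meeting need).

The remaining criteria are declared, config-overridable defaults modeled on
standard ICU clinical-practice-guideline logic — they are this package's own
decision table, not a claim about any particular hospital's build: sedation
wean needs ≥ 6 h of infusion today and no paralytic/contraindication
(status epilepticus, intracranial hypertension); SBT readiness needs
FiO₂ ≤ 0.5, PEEP ≤ 8 cmH₂O, no vasopressor dose in 4 h, no paralytic, no
trial yet today; nutrition must start by 48 h after admission; device-removal
indications per device (retention/obstruction, strict I/O + vasopressor, or
bladder irrigation for urinary catheters; vasopressor dose in 12 h,
central-only medication, or hemodialysis for central lines; vasopressor dose
or ≥ 4 ABGs/24 h for arterial lines; long-course IV therapy for PICCs; liquid
stool *with* skin breakdown for rectal tubes); high-risk lines are femoral or
beyond dwell limits (7 d for central/arterial/HD, 30 d for PICC). The
surveillance-culture rule flags while an outside-placed line remains in and
no blood culture has been drawn since admission — the flag persists until the
culture is drawn or the line comes out. Tidal volume is scaled by Devine
predicted body weight (the lung-protective-ventilation standard; the source
material does not specify actual vs ideal vs predicted weight, and PBW is the
defensible default), floored at 0 with an abstention guard for degenerate
heights.

Comfort-care status suppresses every prophylaxis, nutrition, sedation-wean
and device-removal prompt. It deliberately does **not** suppress the
SUP-discontinuation prompt (a de-prescribing suggestion aligned with comfort
goals) or the purely informational high-risk-line and hypoglycemia metrics.

The registry carries 23 rules. The source validation table prints 23
per-metric rows even though the accompanying narrative counts 22 metrics;
this package follows the table, since every row has its own n and statistics.

## The synthetic census

The generator emulates a single ICU patient-day evaluated at 18:00 (1080
elapsed minutes — far past the partial-day abstention floor, which is
exercised separately in unit tests). A neutral baseline patient is full code,
admitted 96 h earlier, on prophylactic LMWH, with an adequate nutrition
record and no devices — a state in which no metric fires. Each scenario then
perturbs exactly one target metric:

- **actionable**: the target's criteria are all satisfied by construction,
  with irrelevant values randomized (lab values inside safe bands, coverage
  minutes above threshold, etc.);
- **non-actionable**: one randomly chosen criterion is defused, drawn from a
  per-rule spoiler list designed not to awaken any *other* metric.

Because the truth label is fixed by construction — never by running the
engine — the closed loop (simulate → evaluate → validate, expecting
sensitivity = specificity = 1 at zero noise) is a genuine two-route test.
One isolation exception is logically forced: the combined
mechanical-and/or-chemical VTE metric's conditions strictly imply the
mechanical-VTE metric's conditions, so a day actionable for the combined
metric is labelled actionable for both. Scenario interactions are handled in
the construction itself (a ventilated scenario carries an acid suppressant so
the SUP metric stays quiet; a long-dwell line carries the indication that
keeps its removal metric quiet), and boundary values (exactly 75 % coverage,
aPTT exactly 40 s, glucose exactly 70 mg/dL, delivered exactly 80 % of goal)
are sampled with point masses so comparator directions are genuinely tested.

Documentation noise reproduces three phenomena: flowsheet notes claiming a
medication with no MAR action, labs never drawn, and flowsheet device claims
with no device episode. MAR actions are never altered — the MAR is the source
of truth — so note noise provably changes zero flags, while lab deletion
legitimately changes results through the assumed-normal policy.

What the generator does **not** emulate, and hence what passing tests do not
show about real data: realistic demographic/acuity distributions, multi-day
trajectories, correlated multi-metric gaps in one patient, free-text
documentation, charting-time lag between an action and its record, and
mapping noise in drug classes or diagnosis categories (inputs arrive
pre-mapped). Closed-loop perfection is a statement about engine correctness
against its own decision tables, not about accuracy on real charts.

## Validation statistics and row inversion

Statistics are reported rounded half-away-from-zero to 3 decimals (implemented
in integer arithmetic, `(2000·num + den) // (2·den)`, so 0.9375 → 0.938
exactly), with trailing zeros truncated on output ("0.97", "0.8", "1") and
`NaN` for zero denominators. The reconstruction solver enumerates all
(tp, fp, tn, fn) with the published n (≤ n³/6 tuples, pruned on sensitivity
first; well under a second at n = 189) and keeps tuples whose recomputed
statistics round to every printed value; a printed `NaN` is itself a
constraint (that denominator must be zero). At 3-decimal precision some rows
are genuinely under-determined: any all-correct row admits every split of n
into tp + tn, and two of the imperfect published rows admit exactly two
tuples each. The solver therefore reports the full survivor set with a
uniqueness flag rather than pretending to a precision the printed row does
not carry.

## Problem sizes

The shipped checks use a 500-patient closed-loop census, 1000 random
scenarios per rule for oracle equivalence in the test suite (250 in the
acceptance script), 200–300 random instances for the minute-grid coverage
comparison, a 115-patient census for noise invariance, and the full power set
of absent event groups per rule (≤ 2⁷ subsets) for missing-data totality.
These sizes give binomial resolution well below the 1-in-hundreds error rates
that would matter here while keeping a full run in seconds.
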