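# icuflags

A rule-based engine for **daily ICU rounding quality metrics**: given a
structured EHR event stream (medication orders, MAR actions, labs, device
episodes, diagnoses, ventilator observations, nutrition records, code status,
transfusions, activity orders, flowsheet documentation) and one evaluation
time per patient, it renders a census-style table of binary **actionable
flags** — an "X" where a gap exists between the patient's active care and
guideline-recommended care, and an empty cell where no action is needed.

It is written for clinical informaticists and intensivists building or
validating dynamic clinical decision support: the kind of tool that replaces
a static two-dozen-item daily checklist with prompts that fire only when a
specific, auditable criterion set is met.

## The metrics and the model

The shipped registry evaluates **23 metrics in 7 categories**: hypoglycemia,
venous thromboembolism (VTE) prophylaxis, stress ulcer prophylaxis (SUP),
mechanical ventilation, sedation, nutrition, and catheter removal/risk. The
flagship rule, *consider chemical VTE prophylaxis*, flags iff:

- mechanical prophylaxis (compression device) has been in place for
  ≥ 75 % of the current day, and
- no chemical prophylactic or therapeutic anticoagulant (UFH, LMWH, DOAC,
  warfarin) order is active, and
- the patient is **not** coagulopathic (no platelets < 50 k/µL, INR ≥ 1.5 or
  aPTT > 40 s in the last 3 days), has no active bleeding/hematoma diagnosis,
  is not comfort care, received ≤ 1 unit of PRBCs in the prior 24 h, and is
  not ambulatory.

Three missing-data policies make every rule total over incomplete charts:
data *expected but absent* is a **negative finding** (e.g. no
chemoprophylaxis order → the gap is real), data *expected to be absent* is a
**positive finding** (e.g. no central line → nothing to remove), and an
absent lab is **assumed normal** (the team chose not to draw it). Medication
state is read only from orders and MAR actions; flowsheet notes claiming a
dose are ignored (source-of-truth rule). Tidal-volume scaling uses the Devine
predicted body weight: `PBW = 50 (male) / 45.5 (female) + 0.91·(height_cm −
152.4)` kg.

Validation machinery mirrors a chart-review study: per-metric confusion
counts (TP/FP/TN/FN) against reviewer ground truth, the five derived
statistics (sensitivity, specificity, accuracy, PPV, NPV), and an exact
integer solver that inverts a published, 3-decimal-rounded statistics row
back to the confusion counts that produced it.

## Worked example

Simulate a 6-patient census with known per-metric ground truth, evaluate it
at 18:00, and score the flags against the truth:

```bash
icuflags simulate --seed 11 --size 6 --out demo
icuflags evaluate --events demo/events.jsonl --patients demo/patients.jsonl \
    --at 2024-03-14T18:00:00+00:00 --census demo/census.csv --flags demo/flags.csv
icuflags validate --flags demo/flags.csv --truth demo/truth.csv --out demo/stats.csv
```

The census (first columns shown) puts an X exactly where a constructed care
gap exists — patient `p0000` has a glucose ≤ 70 mg/dL today, `p0001` has
compression boots but no anticoagulant order:

```
patient_id,unit,hypoglycemia,vte_chemical,vte_mechanical,vte_any
p0000,micu,X,,,
p0001,micu,,X,,
p0002,micu,,,X,
p0003,micu,,,,
```

`demo/stats.csv` confirms the engine reproduces the generator's ground truth
exactly (6 patients × 23 metrics = 138 evaluations, 4 actionable):

```
rule_id,n,tp,fp,tn,fn,sensitivity,specificity,accuracy,ppv,npv
overall,138,4,0,134,0,1,1,1,1,1
```

The reconstruction solver inverts a published validation row (n = 33,
sensitivity 1, specificity 0.966, accuracy 0.97, PPV 0.8, NPV 1) to its
unique integer confusion counts:

```bash
$ icuflags reconstruct --n 33 --sensitivity 1 --specificity 0.966 \
      --accuracy 0.97 --ppv 0.8 --npv 1
tp=4 fp=1 tn=28 fn=0 unique=yes
```

Rule thresholds are overridable per rule via `--config thresholds.yaml`,
e.g. `vte_chemical: {mech_vte_day_coverage: 0.8}`.

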