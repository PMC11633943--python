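"""Independent decision-table oracles for every metric.

These re-derive each metric's expected flag straight from scenario
parameters, without touching the event stream, the temporal queries, or any
evaluator code — a genuinely separate route from the engine under test.
"""

from datetime import timedelta

ELAPSED_MIN = 1080  # scenario day elapsed at the 18:00 evaluation


def pbw(height_cm, sex):
    base = 50.0 if sex == "male" else 45.5
    return max(0.0, base + 0.91 * (height_cm - 152.4))


def _coagulopathic(p):
    plt, inr, aptt = p.get("plt"), p.get("inr"), p.get("aptt")
    return (
        (plt is not None and plt < 50)
        or (inr is not None and inr >= 1.5)
        or (aptt is not None and aptt > 40)
    )


def _vte_exclusions_clear(p):
    return (
        not _coagulopathic(p)
        and not p["bleeding"]
        and not p["comfort"]
        and p["prbc_units"] <= 1
        and not p["ambulate"]
    )


def _cov(p):
    return p["coverage_min"] / ELAPSED_MIN


ORACLES = {
    "hypoglycemia": lambda p: any(v <= 70 for v in p["glucose_values"]),
    "vte_chemical": lambda p: (
        _cov(p) >= 0.75 and not p["anticoag"] and _vte_exclusions_clear(p)
    ),
    "vte_mechanical": lambda p: (
        not p["anticoag"] and _cov(p) < 0.75
        and not p["ambulate"] and not p["comfort"]
    ),
    "vte_any": lambda p: (
        not p["anticoag"] and _cov(p) < 0.75 and _vte_exclusions_clear(p)
    ),
    "sup_start": lambda p: (
        (p["ventilated"] or p["coag"])
        and not p["suppressant"]
        and not p.get("comfort", False)
    ),
    "sup_stop": lambda p: (
        p["suppressant"] and not p["ventilated"] and not p["coag"]
    ),
    "low_tidal_volume": lambda p: (
        p["ventilated"]
        and p["mode"] == "controlled"
        and p["vt_ml"] / pbw(p["height"], p["sex"]) > 8.0
    ),
    "sedation_wean": lambda p: (
        p["sedative"]
        and p["hours"] >= 6.0
        and not p["paralytic"]
        and not p["comfort"]
        and not p["contra"]
    ),
    "sbt_ready": lambda p: (
        p["intubated"]
        and p["fio2"] <= 0.5
        and p["peep"] <= 8.0
        and not p["pressor"]
        and not p["paralytic"]
        and not p["sbt_done"]
    ),
    "sbt_passed": lambda p: p["intubated"] and p["sbt"] == "passed",
    "nutrition_start": lambda p: (
        p["hours_since_admit"] >= 48.0 and not p["fed"] and not p["comfort"]
    ),
    "nutrition_adequacy": lambda p: (
        p["active"]
        and p["delivered"] < 0.8 * p["goal"]
        and not p["comfort"]
    ),
    "urinary_catheter_removal": lambda p: (
        p["present"]
        and not (
            p["retention"]
            or (p["strict_io"] and p["pressor_order"])
            or p["cbi"]
        )
        and not p["comfort"]
    ),
    "central_line_removal": lambda p: (
        p["present"]
        and not (p["pressor_admin"] or p["central_med"] or p["hd"])
        and not p["comfort"]
    ),
    "arterial_line_removal": lambda p: (
        p["present"]
        and not (p["pressor_admin"] or p["abg_count"] >= 4)
        and not p["comfort"]
    ),
    "picc_removal": lambda p: (
        p["present"] and not p["long_course"] and not p["comfort"]
    ),
    "surveillance_culture": lambda p: (
        p["outside"] and p["active"] and not p["culture"]
    ),
    "rectal_tube_removal": lambda p: (
        p["present"] and not (p["liquid"] and p["skin"]) and not p["comfort"]
    ),
    "ng_to_og": lambda p: p["ngt"] and p["intubated"] and not p["comfort"],
    "high_risk_central_line": lambda p: (
        p["present"] and (p["femoral"] or p["dwell_days"] > 7.0)
    ),
    "high_risk_arterial_line": lambda p: (
        p["present"] and (p["femoral"] or p["dwell_days"] > 7.0)
    ),
    "high_risk_hd_line": lambda p: (
        p["present"] and (p["femoral"] or p["dwell_days"] > 7.0)
    ),
    "high_risk_picc": lambda p: (
        p["present"] and (p["femoral"] or p["dwell_days"] > 30.0)
    ),
}


def minute_grid_coverage(intervals, window):
    """Brute-force coverage: count covered whole minutes of the window."""
    w0, w1 = window
    total = int((w1 - w0) / timedelta(minutes=1))
    covered = 0
    for k in range(total):
        t = w0 + timedelta(minutes=k)
        if any(a <= t < b for a, b in intervals):
            covered += 1
    return covered / total


def brute_force_confusion(pairs):
    """Tally (flag, truth) booleans the pedestrian way."""
    tp = sum(1 for f, t in pairs if f and t)
    fp = sum(1 for f, t in pairs if f and not t)
    tn = sum(1 for f, t in pairs if not f and not t)
    fn = sum(1 for f, t in pairs if not f and t)
    return tp, fp, tn, fn
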