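"""The daily ICU quality-metric evaluators, across seven categories
(hypoglycemia, VTE prophylaxis, stress ulcer prophylaxis, mechanical
ventilation, sedation, nutrition, catheter removal/risk).

Printed, authoritative thresholds: glucose <=70 mg/dL, mechanical-prophylaxis
day coverage >=75%, coagulopathy screens (platelets <50 k/uL, INR >=1.5,
aPTT >40 s, each over a 3-day lookback), >1 PRBC unit in 24 h, tidal volume
8 mL/kg predicted body weight, and 80% of nutritional need. Every other
criterion is a declared, config-overridable default modeled on institutional
clinical-practice-guideline logic; the shipped defaults are the authoritative
decision table the test oracle checks against, not a claim about any
particular hospital's build.

Boundary semantics follow the printed comparators exactly: <=70 flags,
>=0.75 coverage counts, exactly 80% of need is *meeting* need (no flag).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from datetime import timedelta
from typing import Mapping, Optional

from .ehr_model import (
    ANTICOAGULANT_CLASSES,
    Activity,
    Analyte,
    Device,
    DrugClass,
    LINE_DEVICES,
    PatientDayContext,
    Product,
    SbtResult,
    VentMode,
    coverage_fraction,
    predicted_body_weight,
)
from .rule_engine import (
    AbstainEvaluation,
    EvalContext,
    MissingPolicy,
    RuleDefinition,
    RuleResult,
    resolve_missing,
)


@dataclass(frozen=True)
class Thresholds:
    """All tunable rule criteria. Units in field names where applicable."""

    # printed thresholds
    hypoglycemia_mg_dl: float = 70.0
    mech_vte_day_coverage: float = 0.75
    platelets_low_k: float = 50.0
    inr_high: float = 1.5
    aptt_high_sec: float = 40.0
    coag_lookback_days: float = 3.0
    prbc_units_24h: int = 1
    vt_per_kg_ml: float = 8.0
    nutrition_adequacy: float = 0.80
    # declared defaults (config-overridable)
    min_elapsed_day_h: float = 4.0  # below this, day-coverage rules abstain
    sedation_min_infusion_h: float = 6.0
    sbt_fio2_max: float = 0.5
    sbt_peep_max: float = 8.0
    sbt_vasopressor_lookback_h: float = 4.0
    nutrition_start_window_h: float = 48.0
    device_vasopressor_lookback_h: float = 12.0
    abg_count_indication_24h: int = 4
    dwell_limit_days_central: float = 7.0
    dwell_limit_days_arterial: float = 7.0
    dwell_limit_days_hd: float = 7.0
    dwell_limit_days_picc: float = 30.0
    # assumed-normal lab defaults (the lab_missing policy)
    normal_glucose_mg_dl: float = 100.0
    normal_platelets_k: float = 250.0
    normal_inr: float = 1.0
    normal_aptt_sec: float = 30.0
    # structured-diagnosis keyword lists
    bleeding_dx: tuple[str, ...] = ("bleeding", "hematoma")
    urinary_indication_dx: tuple[str, ...] = ("urinary_retention", "urinary_obstruction")
    sedation_contraindication_dx: tuple[str, ...] = (
        "status_epilepticus",
        "intracranial_hypertension",
    )
    skin_breakdown_dx: tuple[str, ...] = ("skin_breakdown",)


DEFAULT_THRESHOLDS = Thresholds()

_DAY = timedelta(days=1)


# ---------------------------------------------------------------------------
# Shared criterion helpers
# ---------------------------------------------------------------------------

def _comfort_care(ctx: PatientDayContext, ec: EvalContext) -> bool:
    raw = ctx.comfort_care()
    resolved = resolve_missing(
        "code_status", raw, MissingPolicy.EXPECTED_PRESENT_MISSING
    )
    ec.use(resolved)
    return bool(resolved.value)


def _anticoagulant_active(ctx: PatientDayContext, ec: EvalContext) -> bool:
    orders = ctx.active_orders_at(ANTICOAGULANT_CLASSES, ctx.eval_time)
    resolved = resolve_missing(
        "anticoagulant_order",
        [o.drug_class.value for o in orders] or None,
        MissingPolicy.EXPECTED_PRESENT_MISSING,
    )
    ec.use(resolved)
    return resolved.value is not None


def _coagulopathic(ctx: PatientDayContext, ec: EvalContext, th: Thresholds) -> bool:
    """Any abnormal coagulation value within the lookback; absent labs are
    assumed normal."""
    lookback = timedelta(days=th.coag_lookback_days)
    plts = [e.value for e in ctx.labs_in_window(Analyte.PLATELETS_K_PER_UL, lookback)]
    inrs = [e.value for e in ctx.labs_in_window(Analyte.INR, lookback)]
    aptts = [e.value for e in ctx.labs_in_window(Analyte.APTT_SEC, lookback)]
    plt = ec.use(
        resolve_missing(
            "platelets_min_3d",
            min(plts) if plts else None,
            MissingPolicy.LAB_MISSING,
            th.normal_platelets_k,
        )
    )
    inr = ec.use(
        resolve_missing(
            "inr_max_3d",
            max(inrs) if inrs else None,
            MissingPolicy.LAB_MISSING,
            th.normal_inr,
        )
    )
    aptt = ec.use(
        resolve_missing(
            "aptt_max_3d",
            max(aptts) if aptts else None,
            MissingPolicy.LAB_MISSING,
            th.normal_aptt_sec,
        )
    )
    return plt < th.platelets_low_k or inr >= th.inr_high or aptt > th.aptt_high_sec


def _mech_coverage(ctx: PatientDayContext, ec: EvalContext, th: Thresholds) -> float:
    if ctx.elapsed < timedelta(hours=th.min_elapsed_day_h):
        raise AbstainEvaluation("partial_day_below_minimum_elapsed")
    intervals = ctx.device_active_intervals(Device.COMPRESSION_DEVICE)
    cov = coverage_fraction(intervals, ctx.day_window)
    ec.note("compression_coverage_fraction", cov)
    return cov


def _ambulatory(ctx: PatientDayContext, ec: EvalContext) -> bool:
    orders = ctx.active_activity_orders_at({Activity.AMBULATE}, ctx.eval_time)
    ec.note("ambulate_order", bool(orders))
    return bool(orders)


def _vte_exclusions(ctx: PatientDayContext, ec: EvalContext, th: Thresholds) -> None:
    """Shared VTE exclusion criteria: coagulopathy, active bleeding, comfort
    care, recent transfusion burden, ambulatory status."""
    ec.criterion("not_coagulopathic", not _coagulopathic(ctx, ec, th))
    bleeding = ctx.active_diagnoses(th.bleeding_dx)
    ec.note("bleeding_diagnosis", [d.category for d in bleeding])
    ec.criterion("no_bleeding_or_hematoma_diagnosis", not bleeding)
    ec.criterion("not_comfort_care", not _comfort_care(ctx, ec))
    prbc = ctx.transfusion_count(Product.PRBC, timedelta(hours=24))
    ec.note("prbc_units_prior_24h", prbc)
    ec.criterion("prbc_not_more_than_1_unit_24h", prbc <= th.prbc_units_24h)
    ec.criterion("not_ambulatory", not _ambulatory(ctx, ec))


def _ventilated(ctx: PatientDayContext, ec: EvalContext) -> bool:
    ett = ctx.device_active_at_eval(Device.ETT)
    ec.note("ett_active", ett)
    return ett


# ---------------------------------------------------------------------------
# Category: hypoglycemia
# ---------------------------------------------------------------------------

def eval_hypoglycemia(ctx: PatientDayContext, th: Thresholds) -> RuleResult:
    """Flag any glucose at or below the hypoglycemia threshold today."""
    ec = EvalContext("hypoglycemia")
    labs = ctx.labs_in_window(Analyte.GLUCOSE_MG_DL, ctx.elapsed)
    low = ec.use(
        resolve_missing(
            "glucose_min_today",
            min((e.value for e in labs), default=None),
            MissingPolicy.LAB_MISSING,
            th.normal_glucose_mg_dl,
        )
    )
    ec.criterion("glucose_at_or_below_threshold", low <= th.hypoglycemia_mg_dl)
    return ec.result()


# ---------------------------------------------------------------------------
# Category: VTE prophylaxis
# ---------------------------------------------------------------------------

def eval_vte_chemical(ctx: PatientDayContext, th: Thresholds) -> RuleResult:
    """Mechanical prophylaxis in place most of the day but no chemical
    prophylaxis/anticoagulation ordered, and no contraindication."""
    ec = EvalContext("vte_chemical")
    cov = _mech_coverage(ctx, ec, th)
    ec.criterion("mech_prophylaxis_coverage_at_threshold", cov >= th.mech_vte_day_coverage)
    ec.criterion("no_active_anticoagulant_order", not _anticoagulant_active(ctx, ec))
    _vte_exclusions(ctx, ec, th)
    return ec.result()


def eval_vte_mechanical(ctx: PatientDayContext, th: Thresholds) -> RuleResult:
    """No prophylaxis modality in place and mechanical prophylaxis is the
    missing piece (declared default logic)."""
    ec = EvalContext("vte_mechanical")
    cov = _mech_coverage(ctx, ec, th)
    ec.criterion("no_active_anticoagulant_order", not _anticoagulant_active(ctx, ec))
    ec.criterion("mech_prophylaxis_coverage_below_threshold", cov < th.mech_vte_day_coverage)
    ec.criterion("not_ambulatory", not _ambulatory(ctx, ec))
    ec.criterion("not_comfort_care", not _comfort_care(ctx, ec))
    return ec.result()


def eval_vte_any(ctx: PatientDayContext, th: Thresholds) -> RuleResult:
    """Neither modality active, with the shared exclusions."""
    ec = EvalContext("vte_any")
    cov = _mech_coverage(ctx, ec, th)
    ec.criterion("no_active_anticoagulant_order", not _anticoagulant_active(ctx, ec))
    ec.criterion("mech_prophylaxis_coverage_below_threshold", cov < th.mech_vte_day_coverage)
    _vte_exclusions(ctx, ec, th)
    return ec.result()


# ---------------------------------------------------------------------------
# Category: stress ulcer prophylaxis
# ---------------------------------------------------------------------------

def _sup_risk(ctx: PatientDayContext, ec: EvalContext, th: Thresholds) -> bool:
    vent = _ventilated(ctx, ec)
    coag = _coagulopathic(ctx, ec, th)
    ec.note("sup_risk_factors", {"mechanical_ventilation": vent, "coagulopathy": coag})
    return vent or coag


def _acid_suppressant_active(ctx: PatientDayContext, ec: EvalContext) -> bool:
    orders = ctx.active_orders_at({DrugClass.ACID_SUPPRESSANT}, ctx.eval_time)
    resolved = resolve_missing(
        "acid_suppressant_order",
        [o.event_id for o in orders] or None,
        MissingPolicy.EXPECTED_PRESENT_MISSING,
    )
    ec.use(resolved)
    return resolved.value is not None


def eval_sup_start(ctx: PatientDayContext, th: Thresholds) -> RuleResult:
    ec = EvalContext("sup_start")
    ec.criterion("sup_risk_factor_active", _sup_risk(ctx, ec, th))
    ec.criterion("no_acid_suppressant_order", not _acid_suppressant_active(ctx, ec))
    ec.criterion("not_comfort_care", not _comfort_care(ctx, ec))
    return ec.result()


def eval_sup_stop(ctx: PatientDayContext, th: Thresholds) -> RuleResult:
    ec = EvalContext("sup_stop")
    ec.criterion("acid_suppressant_order_active", _acid_suppressant_active(ctx, ec))
    ec.criterion("no_sup_risk_factor", not _sup_risk(ctx, ec, th))
    return ec.result()


# ---------------------------------------------------------------------------
# Category: mechanical ventilation
# ---------------------------------------------------------------------------

def eval_low_tidal_volume(ctx: PatientDayContext, th: Thresholds) -> RuleResult:
    """Controlled ventilation with tidal volume above the mL/kg-PBW target."""
    ec = EvalContext("low_tidal_volume")
    vent = _ventilated(ctx, ec)
    obs = ctx.latest_vent_obs()
    mode = obs.mode if obs is not None else None
    ec.note("vent_mode", mode.value if mode else None)
    ec.criterion(
        "on_controlled_ventilation", vent and mode is VentMode.CONTROLLED
    )
    vt = ec.use(
        resolve_missing(
            "tidal_volume_ml",
            obs.tidal_volume_ml if obs is not None else None,
            MissingPolicy.EXPECTED_PRESENT_MISSING,
        )
    )
    pbw = predicted_body_weight(ctx.attributes.height_cm, ctx.attributes.sex)
    if pbw <= 0:
        raise AbstainEvaluation("predicted_body_weight_undefined")
    ec.note("predicted_body_weight_kg", round(pbw, 2))
    vt_per_kg = vt / pbw if vt is not None else None
    ec.note("vt_ml_per_kg_pbw", round(vt_per_kg, 3) if vt_per_kg is not None else None)
    ec.criterion(
        "tidal_volume_above_target",
        vt_per_kg is not None and vt_per_kg > th.vt_per_kg_ml,
    )
    return ec.result()


def _sbt_results_today(ctx: PatientDayContext):
    return [
        o
        for o in ctx.vent_obs_today()
        if o.sbt_result is not None or o.mode is VentMode.SBT_IN_PROGRESS
    ]


def eval_sbt_ready(ctx: PatientDayContext, th: Thresholds) -> RuleResult:
    ec = EvalContext("sbt_ready")
    ec.criterion("intubated", _ventilated(ctx, ec))
    obs = ctx.latest_vent_obs()
    fio2 = ec.use(
        resolve_missing(
            "fio2",
            obs.fio2 if obs is not None else None,
            MissingPolicy.EXPECTED_PRESENT_MISSING,
        )
    )
    peep = ec.use(
        resolve_missing(
            "peep_cmh2o",
            obs.peep_cmh2o if obs is not None else None,
            MissingPolicy.EXPECTED_PRESENT_MISSING,
        )
    )
    ec.criterion("fio2_at_or_below_max", fio2 is not None and fio2 <= th.sbt_fio2_max)
    ec.criterion("peep_at_or_below_max", peep is not None and peep <= th.sbt_peep_max)
    pressors = ctx.med_admins_in_window(
        DrugClass.VASOPRESSOR, timedelta(hours=th.sbt_vasopressor_lookback_h)
    )
    ec.note("vasopressor_doses_recent", len(pressors))
    ec.criterion("no_recent_vasopressor", not pressors)
    paralytic = ctx.active_orders_at({DrugClass.PARALYTIC}, ctx.eval_time)
    ec.note("paralytic_order", bool(paralytic))
    ec.criterion("no_paralytic", not paralytic)
    ec.criterion("no_sbt_yet_today", not _sbt_results_today(ctx))
    return ec.result()


def eval_sbt_passed(ctx: PatientDayContext, th: Thresholds) -> RuleResult:
    ec = EvalContext("sbt_passed")
    results = [o for o in _sbt_results_today(ctx) if o.sbt_result is not None]
    latest = (
        max(results, key=lambda o: o.start).sbt_result if results else None
    )
    ec.note("latest_sbt_result_today", latest.value if latest else None)
    ec.criterion("sbt_passed_today", latest is SbtResult.PASSED)
    ec.criterion("still_intubated", _ventilated(ctx, ec))
    return ec.result()


# ---------------------------------------------------------------------------
# Category: sedation
# ---------------------------------------------------------------------------

def eval_sedation_wean(ctx: PatientDayContext, th: Thresholds) -> RuleResult:
    ec = EvalContext("sedation_wean")
    sedative = ctx.active_orders_at({DrugClass.SEDATIVE_INFUSION}, ctx.eval_time)
    ec.use(
        resolve_missing(
            "sedative_infusion_order",
            [o.event_id for o in sedative] or None,
            MissingPolicy.EXPECTED_PRESENT_MISSING,
        )
    )
    ec.criterion("sedative_infusion_active", bool(sedative))
    hours = ctx.admin_coverage_today(DrugClass.SEDATIVE_INFUSION) / timedelta(hours=1)
    ec.note("sedative_infusion_hours_today", round(hours, 2))
    ec.criterion(
        "infusion_duration_at_threshold", hours >= th.sedation_min_infusion_h
    )
    paralytic = ctx.active_orders_at({DrugClass.PARALYTIC}, ctx.eval_time)
    ec.note("paralytic_order", bool(paralytic))
    ec.criterion("no_paralytic", not paralytic)
    ec.criterion("not_comfort_care", not _comfort_care(ctx, ec))
    contra = ctx.active_diagnoses(th.sedation_contraindication_dx)
    ec.note("contraindication_diagnosis", [d.category for d in contra])
    ec.criterion("no_contraindication_diagnosis", not contra)
    return ec.result()


# ---------------------------------------------------------------------------
# Category: nutrition
# ---------------------------------------------------------------------------

def eval_nutrition_start(ctx: PatientDayContext, th: Thresholds) -> RuleResult:
    ec = EvalContext("nutrition_start")
    window = timedelta(hours=th.nutrition_start_window_h)
    since_admit = ctx.eval_time - ctx.attributes.admit_time
    ec.note("hours_since_admission", round(since_admit / timedelta(hours=1), 1))
    ec.criterion("admitted_at_least_48h", since_admit >= window)
    recent = ctx.nutrition_in_window(window)
    ec.use(
        resolve_missing(
            "nutrition_record_48h",
            [e.event_id for e in recent] or None,
            MissingPolicy.EXPECTED_PRESENT_MISSING,
        )
    )
    ec.criterion("no_nutrition_in_last_48h", not recent)
    ec.criterion("not_comfort_care", not _comfort_care(ctx, ec))
    return ec.result()


def eval_nutrition_adequacy(ctx: PatientDayContext, th: Thresholds) -> RuleResult:
    """Delivered kcal over the prior 24 h below the adequacy fraction of the
    goal; meeting exactly the fraction is adequate (no flag)."""
    ec = EvalContext("nutrition_adequacy")
    recent = ctx.nutrition_in_window(timedelta(hours=24))
    latest = max(recent, key=lambda e: e.start) if recent else None
    ec.criterion("nutrition_active", latest is not None)
    goal = latest.goal_kcal if latest is not None else None
    delivered = latest.delivered_kcal_24h if latest is not None else None
    ec.note("goal_kcal", goal)
    ec.note("delivered_kcal_24h", delivered)
    below = (
        goal is not None
        and delivered is not None
        and delivered < th.nutrition_adequacy * goal
    )
    ec.criterion("intake_below_adequacy_fraction", below)
    ec.criterion("not_comfort_care", not _comfort_care(ctx, ec))
    return ec.result()


# ---------------------------------------------------------------------------
# Category: catheter removal / risk
# ---------------------------------------------------------------------------

def _vasopressor_admin_recent(
    ctx: PatientDayContext, ec: EvalContext, th: Thresholds
) -> bool:
    doses = ctx.med_admins_in_window(
        DrugClass.VASOPRESSOR, timedelta(hours=th.device_vasopressor_lookback_h)
    )
    ec.note("vasopressor_doses_recent", len(doses))
    return bool(doses)


def _removal_rule(rule_id, device, indications):
    """Build a removal evaluator: flag iff the device is in, no retention
    indication is active, and the patient is not comfort care. An absent
    device resolves to a positive finding (nothing to remove)."""

    def evaluator(ctx: PatientDayContext, th: Thresholds) -> RuleResult:
        ec = EvalContext(rule_id)
        ep = ctx.current_device_episode(device)
        ec.use(
            resolve_missing(
                device.value,
                ep.event_id if ep is not None else None,
                MissingPolicy.EXPECTED_ABSENT_MISSING,
            )
        )
        ec.criterion("device_present", ep is not None)
        active = indications(ctx, ec, th)
        ec.note("active_indications", active)
        ec.criterion("no_active_indication", not active)
        ec.criterion("not_comfort_care", not _comfort_care(ctx, ec))
        return ec.result()

    evaluator.__name__ = f"eval_{rule_id}"
    return evaluator


def _urinary_indications(ctx, ec, th):
    out = []
    if ctx.active_diagnoses(th.urinary_indication_dx):
        out.append("retention_or_obstruction_diagnosis")
    strict_io = ctx.active_activity_orders_at({Activity.STRICT_IO}, ctx.eval_time)
    pressor_order = ctx.active_orders_at({DrugClass.VASOPRESSOR}, ctx.eval_time)
    if strict_io and pressor_order:
        out.append("strict_io_with_vasopressor")
    if ctx.active_activity_orders_at({Activity.BLADDER_IRRIGATION}, ctx.eval_time):
        out.append("continuous_bladder_irrigation")
    return out


def _central_indications(ctx, ec, th):
    out = []
    if _vasopressor_admin_recent(ctx, ec, th):
        out.append("vasopressor_in_last_12h")
    if ctx.active_orders_at({DrugClass.CENTRAL_ONLY_MED}, ctx.eval_time):
        out.append("central_only_medication")
    if ctx.active_activity_orders_at({Activity.HEMODIALYSIS}, ctx.eval_time):
        out.append("active_hemodialysis")
    return out


def _arterial_indications(ctx, ec, th):
    out = []
    if _vasopressor_admin_recent(ctx, ec, th):
        out.append("vasopressor_in_last_12h")
    abgs = ctx.labs_in_window(Analyte.ABG, timedelta(hours=24))
    ec.note("abg_count_24h", len(abgs))
    if len(abgs) >= th.abg_count_indication_24h:
        out.append("frequent_abg_sampling")
    return out


def _picc_indications(ctx, ec, th):
    out = []
    if ctx.active_orders_at({DrugClass.LONG_COURSE_IV}, ctx.eval_time):
        out.append("long_course_iv_therapy")
    return out


def _rectal_indications(ctx, ec, th):
    liquid = any(d.value == "liquid" for d in ctx.stool_docs_today())
    skin = bool(ctx.active_diagnoses(th.skin_breakdown_dx))
    ec.note("liquid_stool_documented_today", liquid)
    ec.note("skin_breakdown_diagnosis", skin)
    return ["liquid_stool_with_skin_breakdown"] if liquid and skin else []


eval_urinary_catheter_removal = _removal_rule(
    "urinary_catheter_removal", Device.URINARY_CATHETER, _urinary_indications
)
eval_central_line_removal = _removal_rule(
    "central_line_removal", Device.CENTRAL_LINE, _central_indications
)
eval_arterial_line_removal = _removal_rule(
    "arterial_line_removal", Device.ARTERIAL_LINE, _arterial_indications
)
eval_picc_removal = _removal_rule("picc_removal", Device.PICC, _picc_indications)
eval_rectal_tube_removal = _removal_rule(
    "rectal_tube_removal", Device.RECTAL_TUBE, _rectal_indications
)


def eval_surveillance_culture(ctx: PatientDayContext, th: Thresholds) -> RuleResult:
    """A line placed at an outside facility is still in and no surveillance
    blood culture has been drawn since admission; the flag persists until a
    culture is drawn or the line comes out."""
    ec = EvalContext("surveillance_culture")
    outside = [
        d
        for d in (ctx.current_device_episode(dev) for dev in sorted(LINE_DEVICES))
        if d is not None and d.placed_outside
    ]
    ec.note("outside_placed_lines", [d.device.value for d in outside])
    ec.criterion("outside_placed_line_active", bool(outside))
    since_admit = ctx.eval_time - ctx.attributes.admit_time
    cultures = (
        ctx.labs_in_window(Analyte.BLOOD_CULTURE, since_admit)
        if since_admit > timedelta(0)
        else []
    )
    ec.use(
        resolve_missing(
            "blood_culture_since_admission",
            [e.event_id for e in cultures] or None,
            MissingPolicy.EXPECTED_PRESENT_MISSING,
        )
    )
    ec.criterion("no_blood_culture_since_admission", not cultures)
    return ec.result()


def eval_ng_to_og(ctx: PatientDayContext, th: Thresholds) -> RuleResult:
    """An intubated patient with a nasogastric tube should have it exchanged
    for an orogastric tube (sinusitis/VAP risk)."""
    ec = EvalContext("ng_to_og")
    ngt = ctx.current_device_episode(Device.NGT)
    ec.use(
        resolve_missing(
            "ngt",
            ngt.event_id if ngt is not None else None,
            MissingPolicy.EXPECTED_ABSENT_MISSING,
        )
    )
    ec.criterion("ngt_present", ngt is not None)
    ec.criterion("intubated", _ventilated(ctx, ec))
    ec.criterion("not_comfort_care", not _comfort_care(ctx, ec))
    return ec.result()


def _high_risk_rule(rule_id, device, limit_field):
    """Femoral placement or dwell beyond the per-line limit makes a line high
    risk for catheter-associated infection."""

    def evaluator(ctx: PatientDayContext, th: Thresholds) -> RuleResult:
        ec = EvalContext(rule_id)
        ep = ctx.current_device_episode(device)
        ec.use(
            resolve_missing(
                device.value,
                ep.event_id if ep is not None else None,
                MissingPolicy.EXPECTED_ABSENT_MISSING,
            )
        )
        ec.criterion("device_present", ep is not None)
        limit = timedelta(days=getattr(th, limit_field))
        femoral = ep is not None and ep.site.value == "femoral"
        dwell = (ctx.eval_time - ep.start) if ep is not None else None
        ec.note("site", ep.site.value if ep is not None else None)
        ec.note(
            "dwell_days", round(dwell / _DAY, 2) if dwell is not None else None
        )
        ec.criterion(
            "femoral_site_or_dwell_over_limit",
            femoral or (dwell is not None and dwell > limit),
        )
        return ec.result()

    evaluator.__name__ = f"eval_{rule_id}"
    return evaluator


eval_high_risk_central_line = _high_risk_rule(
    "high_risk_central_line", Device.CENTRAL_LINE, "dwell_limit_days_central"
)
eval_high_risk_arterial_line = _high_risk_rule(
    "high_risk_arterial_line", Device.ARTERIAL_LINE, "dwell_limit_days_arterial"
)
eval_high_risk_hd_line = _high_risk_rule(
    "high_risk_hd_line", Device.HD_LINE, "dwell_limit_days_hd"
)
eval_high_risk_picc = _high_risk_rule(
    "high_risk_picc", Device.PICC, "dwell_limit_days_picc"
)


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

_P = MissingPolicy.EXPECTED_PRESENT_MISSING
_A = MissingPolicy.EXPECTED_ABSENT_MISSING
_L = MissingPolicy.LAB_MISSING

_COAG_INPUTS = (("platelets", _L), ("inr", _L), ("aptt", _L))

#: (rule_id, category, census display name, evaluator, required inputs)
_RULE_TABLE = (
    ("hypoglycemia", "hypoglycemia", "Hypoglycemia (<=70 mg/dL)",
     eval_hypoglycemia, (("glucose_labs", _L),)),
    ("vte_chemical", "vte_prophylaxis", "Consider chemical VTE prophylaxis",
     eval_vte_chemical,
     (("compression_device", _P), ("anticoagulant_order", _P)) + _COAG_INPUTS
     + (("bleeding_diagnosis", _A), ("code_status", _P),
        ("transfusions", _A), ("activity_order", _A))),
    ("vte_mechanical", "vte_prophylaxis", "Consider mechanical VTE prophylaxis",
     eval_vte_mechanical,
     (("compression_device", _P), ("anticoagulant_order", _P),
      ("activity_order", _A), ("code_status", _P))),
    ("vte_any", "vte_prophylaxis",
     "Consider mechanical and/or chemical VTE prophylaxis",
     eval_vte_any,
     (("compression_device", _P), ("anticoagulant_order", _P)) + _COAG_INPUTS
     + (("bleeding_diagnosis", _A), ("code_status", _P),
        ("transfusions", _A), ("activity_order", _A))),
    ("sup_start", "sup", "Consider SUP", eval_sup_start,
     (("ett_device", _A), ("acid_suppressant_order", _P),
      ("code_status", _P)) + _COAG_INPUTS),
    ("sup_stop", "sup", "Consider to discontinue SUP", eval_sup_stop,
     (("ett_device", _A), ("acid_suppressant_order", _P)) + _COAG_INPUTS),
    ("low_tidal_volume", "mechanical_ventilation",
     "Low tidal volume (Vt <=8 mLs/kg)", eval_low_tidal_volume,
     (("ett_device", _A), ("vent_obs", _P))),
    ("sedation_wean", "sedation", "Ready for sedation wean",
     eval_sedation_wean,
     (("sedative_order", _P), ("sedative_admin", _P), ("paralytic_order", _A),
      ("code_status", _P), ("contraindication_diagnosis", _A))),
    ("sbt_ready", "mechanical_ventilation",
     "Ready for Spontaneous Breathing Trial", eval_sbt_ready,
     (("ett_device", _A), ("vent_obs", _P), ("vasopressor_admin", _A),
      ("paralytic_order", _A))),
    ("sbt_passed", "mechanical_ventilation",
     "Passed Spontaneous Breathing Trial: consider extubation",
     eval_sbt_passed, (("ett_device", _A), ("vent_obs", _P))),
    ("nutrition_start", "nutrition", "Needs nutrition started",
     eval_nutrition_start, (("nutrition_record", _P), ("code_status", _P))),
    ("nutrition_adequacy", "nutrition", "Not meeting nutritional 80% of need",
     eval_nutrition_adequacy, (("nutrition_record", _P), ("code_status", _P))),
    ("urinary_catheter_removal", "catheter", "Urinary catheter ready for removal",
     eval_urinary_catheter_removal,
     (("urinary_catheter", _A), ("indication_diagnosis", _A),
      ("activity_order", _A), ("code_status", _P))),
    ("central_line_removal", "catheter", "Central line ready for removal",
     eval_central_line_removal,
     (("central_line", _A), ("vasopressor_admin", _A),
      ("central_only_order", _A), ("code_status", _P))),
    ("arterial_line_removal", "catheter", "Arterial line ready for removal",
     eval_arterial_line_removal,
     (("arterial_line", _A), ("vasopressor_admin", _A), ("abg_labs", _A),
      ("code_status", _P))),
    ("picc_removal", "catheter", "PICC line ready for removal",
     eval_picc_removal,
     (("picc", _A), ("long_course_order", _A), ("code_status", _P))),
    ("surveillance_culture", "catheter",
     "Pre-existing line of admit needs surveillance blood culture",
     eval_surveillance_culture,
     (("line_devices", _A), ("blood_culture_lab", _P))),
    ("rectal_tube_removal", "catheter", "Rectal tube ready for removal",
     eval_rectal_tube_removal,
     (("rectal_tube", _A), ("stool_doc", _A), ("skin_diagnosis", _A),
      ("code_status", _P))),
    ("ng_to_og", "catheter", "Change Nasogastric tube to an Oralgastric Tube",
     eval_ng_to_og, (("ngt", _A), ("ett_device", _A), ("code_status", _P))),
    ("high_risk_central_line", "catheter", "High risk Central Venous Catheter",
     eval_high_risk_central_line, (("central_line", _A),)),
    ("high_risk_arterial_line", "catheter", "High risk arterial line",
     eval_high_risk_arterial_line, (("arterial_line", _A),)),
    ("high_risk_hd_line", "catheter", "High risk Hemodialysis line",
     eval_high_risk_hd_line, (("hd_line", _A),)),
    ("high_risk_picc", "catheter", "High risk PICC line",
     eval_high_risk_picc, (("picc", _A),)),
)

RULE_IDS: tuple[str, ...] = tuple(row[0] for row in _RULE_TABLE)
DISPLAY_NAMES: dict[str, str] = {row[0]: row[2] for row in _RULE_TABLE}
CATEGORIES: dict[str, str] = {row[0]: row[1] for row in _RULE_TABLE}

#: Flags suppressed outright by comfort-care status (prophylaxis, nutrition,
#: sedation wean); de-prescribing and informational metrics are not.
COMFORT_SUPPRESSED_RULES = frozenset(
    {
        "vte_chemical",
        "vte_mechanical",
        "vte_any",
        "sup_start",
        "sedation_wean",
        "nutrition_start",
        "nutrition_adequacy",
        "urinary_catheter_removal",
        "central_line_removal",
        "arterial_line_removal",
        "picc_removal",
        "rectal_tube_removal",
        "ng_to_og",
    }
)


def build_registry(
    overrides: Optional[Mapping[str, Mapping[str, object]]] = None,
) -> tuple[RuleDefinition, ...]:
    """Instantiate the rule registry with optional per-rule threshold overrides."""
    overrides = dict(overrides or {})
    unknown = set(overrides) - set(RULE_IDS)
    if unknown:
        raise ValueError(f"config overrides for unknown rule ids: {sorted(unknown)}")
    rules = []
    for rule_id, category, display, evaluator, inputs in _RULE_TABLE:
        th = DEFAULT_THRESHOLDS
        if rule_id in overrides:
            th = dataclasses.replace(th, **dict(overrides[rule_id]))
        rules.append(
            RuleDefinition(
                rule_id=rule_id,
                category=category,
                display_name=display,
                evaluator=evaluator,
                required_inputs=tuple(inputs),
                thresholds=th,
            )
        )
    return tuple(rules)
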