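"""Seeded generator of synthetic ICU patient-days with per-metric ground truth.

The generator emulates the data phenomena a rule engine must survive in a real
EHR: inter-staff documentation variability (flowsheet notes disagreeing with
the MAR), labs that were simply never drawn, and device episodes with
documentation gaps. It is the study-condition source for the closed-loop
validation: a patient-day is *constructed* to be actionable or not for one
target metric (all other metrics driven inactive), so the truth label is known
by construction rather than by running the engine — the loop engine-vs-truth
is therefore a real test, not a tautology.

One deliberate exception to single-rule isolation: the combined
mechanical-and/or-chemical VTE metric's actionable conditions strictly imply
the mechanical-VTE metric's conditions, so a patient-day actionable for the
combined metric is labelled actionable for both.

Scenario parameters are exposed (``sample_params`` / ``render_scenario``) so
an independent decision-table oracle can be checked against the engine on
randomized scenarios without sharing any evaluation code path.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .ehr_model import (
    ActivityOrderEvent,
    Activity,
    AdminAction,
    Analyte,
    CodeStatus,
    CodeStatusEvent,
    Device,
    DeviceEvent,
    DiagnosisEvent,
    DocType,
    DrugClass,
    FlowsheetDocEvent,
    LabEvent,
    MedAdminEvent,
    MedOrderEvent,
    NutritionEvent,
    NutritionRoute,
    OrderStatus,
    PatientAttributes,
    Product,
    SbtResult,
    Sex,
    Site,
    TransfusionEvent,
    VentMode,
    VentObsEvent,
)
from .metrics import RULE_IDS

UTC = timezone.utc

#: Fixed scenario clock: evaluation at 18:00, so 1080 min of the current day
#: have elapsed (partial-day handling is exercised separately in unit tests).
EVAL_TIME = datetime(2024, 3, 14, 18, 0, tzinfo=UTC)
DAY_START = datetime(2024, 3, 14, 0, 0, tzinfo=UTC)
ELAPSED_MINUTES = 1080


@dataclass(frozen=True)
class NoiseSpec:
    """Probabilities of the three documentation-noise phenomena."""

    note_claim_p: float = 0.0  # flowsheet claims a med not on the MAR
    lab_absent_p: float = 0.0  # each lab row deleted
    device_doc_gap_p: float = 0.0  # flowsheet claims a device with no episode


@dataclass(frozen=True)
class ScenarioSpec:
    """Description of a synthetic census: size, per-metric gap prevalence,
    and documentation noise. Same seed, same spec -> byte-identical output."""

    seed: int
    census_size: int = 50
    prevalence: Optional[Mapping[str, float]] = None  # rule_id -> P(actionable)
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def prevalence_map(self) -> dict[str, float]:
        if self.prevalence is None:
            return {rid: 0.3 for rid in RULE_IDS}
        bad = set(self.prevalence) - set(RULE_IDS)
        if bad:
            raise ValueError(f"unknown rule ids in prevalence: {sorted(bad)}")
        for rid, p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {rid} outside [0,1]: {p}")
        return dict(self.prevalence)


@dataclass(frozen=True)
class GroundTruthLabel:
    rule_id: str
    patient_id: str
    actionable: bool


@dataclass(frozen=True)
class GeneratedPatientDay:
    patient_id: str
    events: tuple
    attributes: PatientAttributes
    eval_time: datetime
    labels: dict  # rule_id -> bool, for every registered rule


# ---------------------------------------------------------------------------
# Event construction
# ---------------------------------------------------------------------------

class _Builder:
    def __init__(self, pid: str):
        self.pid = pid
        self.n = 0
        self.events: list = []

    def _id(self) -> str:
        self.n += 1
        return f"{self.pid}-e{self.n:03d}"

    def add(self, cls, **kw):
        ev = cls(patient_id=self.pid, event_id=self._id(), **kw)
        self.events.append(ev)
        return ev

    def med_order(self, drug, start, end=None, status=OrderStatus.ACTIVE):
        return self.add(
            MedOrderEvent, drug_class=drug, status=status, start=start, end=end
        )

    def med_admin(self, drug, dose_time, end=None):
        return self.add(
            MedAdminEvent,
            drug_class=drug,
            action=AdminAction.GIVEN,
            start=dose_time,
            end=end if end is not None else dose_time + timedelta(minutes=1),
            dose_time=dose_time,
        )

    def lab(self, analyte, value, result_time):
        return self.add(
            LabEvent,
            analyte=analyte,
            value=value,
            result_time=result_time,
            start=result_time,
        )

    def device(self, device, start, end=None, site=Site.OTHER, outside=False):
        return self.add(
            DeviceEvent,
            device=device,
            site=site,
            placed_outside=outside,
            start=start,
            end=end,
        )

    def diagnosis(self, category, start):
        return self.add(DiagnosisEvent, category=category, start=start)

    def vent_obs(self, at, mode, vt=None, fio2=None, peep=None, sbt=None):
        return self.add(
            VentObsEvent,
            mode=mode,
            tidal_volume_ml=vt,
            fio2=fio2,
            peep_cmh2o=peep,
            sbt_result=sbt,
            start=at,
        )


def _base(
    pid: str,
    *,
    admit_hours: float = 96.0,
    anticoag: bool = True,
    fed: bool = True,
    height: float = 175.0,
    sex: Sex = Sex.MALE,
    comfort: bool = False,
):
    """Neutral ICU patient: full code (or comfort), prophylactic LMWH to keep
    VTE metrics quiet, an adequate nutrition record, no devices."""
    b = _Builder(pid)
    admit = EVAL_TIME - timedelta(hours=admit_hours)
    attrs = PatientAttributes(
        patient_id=pid, height_cm=height, sex=sex, admit_time=admit, unit="micu"
    )
    b.add(
        CodeStatusEvent,
        code_status=CodeStatus.COMFORT_CARE if comfort else CodeStatus.FULL_CODE,
        start=admit,
    )
    if anticoag:
        b.med_order(DrugClass.LMWH_PROPHYLACTIC, start=admit)
    if fed:
        b.add(
            NutritionEvent,
            route=NutritionRoute.ENTERAL,
            goal_kcal=2000.0,
            delivered_kcal_24h=1900.0,
            start=EVAL_TIME - timedelta(hours=6),
        )
    return b, attrs, admit


def _vent(b: _Builder, admit, *, fio2=0.6, peep=5.0, vt=420.0,
          mode=VentMode.CONTROLLED, suppressant=True, ett_end=None):
    """Ventilated add-on; acid suppressant accompanies active ventilation so
    the SUP metrics stay quiet in isolation scenarios."""
    b.device(Device.ETT, start=EVAL_TIME - timedelta(hours=48), end=ett_end)
    b.vent_obs(DAY_START + timedelta(hours=16), mode, vt=vt, fio2=fio2, peep=peep)
    if suppressant:
        b.med_order(DrugClass.ACID_SUPPRESSANT, start=admit)


def _coag_labs(b: _Builder, plt=None, inr=None, aptt=None):
    if plt is not None:
        b.lab(Analyte.PLATELETS_K_PER_UL, plt, EVAL_TIME - timedelta(days=2))
    if inr is not None:
        b.lab(Analyte.INR, inr, EVAL_TIME - timedelta(days=1))
    if aptt is not None:
        b.lab(Analyte.APTT_SEC, aptt, EVAL_TIME - timedelta(hours=6))


# ---------------------------------------------------------------------------
# Per-rule scenario definitions
# ---------------------------------------------------------------------------

def _bern(rng, p=0.5) -> bool:
    return bool(rng.random() < p)


def _cov_minutes(rng) -> int:
    # mixture: mass at the exact 75% boundary plus a uniform spread
    if rng.random() < 0.15:
        return 810
    return int(rng.integers(0, ELAPSED_MINUTES + 1))


def _maybe(rng, sampler, p=0.7):
    return sampler() if rng.random() < p else None


@dataclass(frozen=True)
class _RuleScenario:
    sample: Callable  # rng -> params (fully random)
    actionable: Callable  # rng -> params forcing an actionable day
    spoilers: tuple  # callables rng -> param updates, each defusing the rule
    render: Callable  # (params, pid) -> (events, attributes)
    co_labels: Callable = lambda params: {}  # unavoidable co-actionable rules


# --- hypoglycemia ----------------------------------------------------------

def _render_hypoglycemia(p, pid):
    b, attrs, admit = _base(pid)
    for i, v in enumerate(p["glucose_values"]):
        b.lab(Analyte.GLUCOSE_MG_DL, float(v), DAY_START + timedelta(hours=6 + 2 * i))
    return b.events, attrs


_hypoglycemia = _RuleScenario(
    sample=lambda rng: {
        "glucose_values": [
            int(rng.integers(55, 131)) for _ in range(int(rng.integers(0, 4)))
        ]
    },
    actionable=lambda rng: {
        "glucose_values": [int(rng.integers(40, 71)), int(rng.integers(90, 131))]
    },
    spoilers=(
        lambda rng: {"glucose_values": [int(rng.integers(71, 131))]},
        lambda rng: {"glucose_values": []},
    ),
    render=_render_hypoglycemia,
)


# --- VTE -------------------------------------------------------------------

def _render_vte(p, pid):
    b, attrs, admit = _base(pid, anticoag=p["anticoag"], comfort=p["comfort"])
    m = int(p["coverage_min"])
    if m > 0:
        end = DAY_START + timedelta(minutes=m) if m < ELAPSED_MINUTES else None
        b.device(Device.COMPRESSION_DEVICE, start=DAY_START, end=end)
    _coag_labs(b, p.get("plt"), p.get("inr"), p.get("aptt"))
    if p.get("coag_suppressed"):
        # coagulopathy used to keep the combined-VTE metric quiet needs its
        # own SUP suppressor
        b.med_order(DrugClass.ACID_SUPPRESSANT, start=admit)
    if p.get("bleeding"):
        b.diagnosis("bleeding", start=admit)
    for k in range(int(p.get("prbc_units", 0))):
        b.add(
            TransfusionEvent,
            product=Product.PRBC,
            start=EVAL_TIME - timedelta(hours=2 + 3 * k),
        )
    if p["ambulate"]:
        b.add(
            ActivityOrderEvent,
            activity=Activity.AMBULATE,
            status=OrderStatus.ACTIVE,
            start=admit,
        )
    return b.events, attrs


def _sample_vte_chemical(rng):
    return {
        "coverage_min": _cov_minutes(rng),
        "anticoag": _bern(rng, 0.4),
        "plt": _maybe(rng, lambda: float(rng.integers(30, 301))),
        "inr": _maybe(rng, lambda: round(float(rng.uniform(0.9, 2.2)), 1)),
        "aptt": _maybe(rng, lambda: round(float(rng.uniform(25.0, 60.0)), 1)),
        "bleeding": _bern(rng, 0.2),
        "comfort": _bern(rng, 0.15),
        "prbc_units": int(rng.integers(0, 4)),
        "ambulate": _bern(rng, 0.2),
    }


def _actionable_vte_chemical(rng):
    return {
        "coverage_min": int(rng.integers(810, ELAPSED_MINUTES + 1)),
        "anticoag": False,
        "plt": float(rng.integers(120, 301)),
        "inr": round(float(rng.uniform(0.9, 1.3)), 1),
        "aptt": round(float(rng.uniform(25.0, 36.0)), 1),
        "bleeding": False,
        "comfort": False,
        "prbc_units": int(rng.integers(0, 2)),
        "ambulate": False,
    }


_vte_chemical = _RuleScenario(
    sample=_sample_vte_chemical,
    actionable=_actionable_vte_chemical,
    spoilers=(
        lambda rng: {"anticoag": True},
        lambda rng: {"ambulate": True},
        lambda rng: {"comfort": True},
        lambda rng: {"prbc_units": int(rng.integers(2, 4))},
        lambda rng: {"bleeding": True},
    ),
    render=_render_vte,
)


def _sample_vte_mechanical(rng):
    coag = _bern(rng, 0.3)
    return {
        "coverage_min": _cov_minutes(rng),
        "anticoag": _bern(rng, 0.4),
        "ambulate": _bern(rng, 0.2),
        "comfort": _bern(rng, 0.15),
        "inr": 1.8 if coag else None,
        "coag_suppressed": coag,
    }


_vte_mechanical = _RuleScenario(
    sample=_sample_vte_mechanical,
    actionable=lambda rng: {
        "coverage_min": int(rng.integers(0, 810)),
        "anticoag": False,
        "ambulate": False,
        "comfort": False,
        # a coagulopathy keeps the combined-VTE metric quiet
        "inr": 1.8,
        "coag_suppressed": True,
    },
    spoilers=(
        lambda rng: {"anticoag": True},
        lambda rng: {"ambulate": True},
        lambda rng: {"comfort": True},
        lambda rng: {"coverage_min": int(rng.integers(810, ELAPSED_MINUTES + 1))},
    ),
    render=_render_vte,
)


def _actionable_vte_any(rng):
    return {
        "coverage_min": int(rng.integers(0, 810)),
        "anticoag": False,
        "plt": float(rng.integers(120, 301)),
        "inr": round(float(rng.uniform(0.9, 1.3)), 1),
        "aptt": round(float(rng.uniform(25.0, 36.0)), 1),
        "bleeding": False,
        "comfort": False,
        "prbc_units": int(rng.integers(0, 2)),
        "ambulate": False,
    }


_vte_any = _RuleScenario(
    sample=_sample_vte_chemical,
    actionable=_actionable_vte_any,
    spoilers=(
        lambda rng: {"anticoag": True},
        lambda rng: {"ambulate": True},
        lambda rng: {"comfort": True},
    ),
    render=_render_vte,
    co_labels=lambda p: {"vte_mechanical": True},
)


# --- SUP -------------------------------------------------------------------

def _render_sup(p, pid):
    b, attrs, admit = _base(pid, comfort=p.get("comfort", False))
    if p["ventilated"]:
        _vent(b, admit, suppressant=False)
    if p["coag"]:
        _coag_labs(b, inr=1.8)
    if p["suppressant"]:
        b.med_order(DrugClass.ACID_SUPPRESSANT, start=admit)
    return b.events, attrs


def _sample_sup(rng):
    return {
        "ventilated": _bern(rng, 0.4),
        "coag": _bern(rng, 0.4),
        "suppressant": _bern(rng),
        "comfort": _bern(rng, 0.15),
    }


_sup_start = _RuleScenario(
    sample=_sample_sup,
    actionable=lambda rng: (
        {"ventilated": True, "coag": False}
        if _bern(rng)
        else {"ventilated": False, "coag": True}
    )
    | {"suppressant": False, "comfort": False},
    spoilers=(
        lambda rng: {"suppressant": True},
        lambda rng: {"ventilated": False, "coag": False},
        lambda rng: {"comfort": True},
    ),
    render=_render_sup,
)

_sup_stop = _RuleScenario(
    sample=_sample_sup,
    actionable=lambda rng: {
        "ventilated": False,
        "coag": False,
        "suppressant": True,
        "comfort": False,
    },
    spoilers=(
        lambda rng: {"suppressant": False},
        lambda rng: {"coag": True},
    ),
    render=_render_sup,
)


# --- mechanical ventilation ------------------------------------------------

def _render_low_vt(p, pid):
    b, attrs, admit = _base(pid, height=p["height"], sex=Sex(p["sex"]))
    if p["ventilated"]:
        _vent(b, admit, vt=p["vt_ml"], mode=VentMode(p["mode"]))
    return b.events, attrs


_low_tidal_volume = _RuleScenario(
    sample=lambda rng: {
        "ventilated": _bern(rng, 0.7),
        "mode": str(rng.choice(["controlled", "spontaneous"])),
        "vt_ml": round(float(rng.uniform(300.0, 750.0)), 1),
        "height": round(float(rng.uniform(150.0, 200.0)), 1),
        "sex": str(rng.choice(["male", "female"])),
    },
    actionable=lambda rng: {
        "ventilated": True,
        "mode": "controlled",
        "vt_ml": round(float(rng.uniform(620.0, 750.0)), 1),
        "height": 175.0,
        "sex": "male",
    },
    spoilers=(
        lambda rng: {"vt_ml": round(float(rng.uniform(300.0, 520.0)), 1)},
        lambda rng: {"mode": "spontaneous"},
        lambda rng: {"ventilated": False},
    ),
    render=_render_low_vt,
)


def _render_sbt_ready(p, pid):
    b, attrs, admit = _base(pid)
    if p["intubated"]:
        b.device(Device.ETT, start=EVAL_TIME - timedelta(hours=48))
        b.med_order(DrugClass.ACID_SUPPRESSANT, start=admit)
        if p["sbt_done"]:
            b.vent_obs(
                DAY_START + timedelta(hours=10),
                VentMode.SPONTANEOUS,
                sbt=SbtResult.FAILED,
            )
        b.vent_obs(
            DAY_START + timedelta(hours=14),
            VentMode.CONTROLLED,
            vt=420.0,
            fio2=p["fio2"],
            peep=p["peep"],
        )
    if p["pressor"]:
        b.med_admin(DrugClass.VASOPRESSOR, EVAL_TIME - timedelta(hours=2))
    if p["paralytic"]:
        b.med_order(DrugClass.PARALYTIC, start=admit)
    return b.events, attrs


_sbt_ready = _RuleScenario(
    sample=lambda rng: {
        "intubated": _bern(rng, 0.7),
        "fio2": float(rng.choice([0.3, 0.4, 0.5, 0.6, 0.8])),
        "peep": float(rng.choice([5.0, 8.0, 10.0, 12.0])),
        "pressor": _bern(rng, 0.3),
        "paralytic": _bern(rng, 0.2),
        "sbt_done": _bern(rng, 0.3),
    },
    actionable=lambda rng: {
        "intubated": True,
        "fio2": float(rng.choice([0.3, 0.4, 0.5])),
        "peep": float(rng.choice([5.0, 8.0])),
        "pressor": False,
        "paralytic": False,
        "sbt_done": False,
    },
    spoilers=(
        lambda rng: {"fio2": float(rng.choice([0.6, 0.8]))},
        lambda rng: {"peep": float(rng.choice([10.0, 12.0]))},
        lambda rng: {"pressor": True},
        lambda rng: {"paralytic": True},
        lambda rng: {"sbt_done": True},
        lambda rng: {"intubated": False},
    ),
    render=_render_sbt_ready,
)


def _render_sbt_passed(p, pid):
    b, attrs, admit = _base(pid)
    ett_end = None if p["intubated"] else DAY_START + timedelta(hours=12)
    b.device(Device.ETT, start=EVAL_TIME - timedelta(hours=48), end=ett_end)
    if p["intubated"]:
        b.med_order(DrugClass.ACID_SUPPRESSANT, start=admit)
    b.vent_obs(
        DAY_START + timedelta(hours=8),
        VentMode.SPONTANEOUS,
        fio2=p["fio2"],
        peep=5.0,
    )
    if p["sbt"] is not None:
        b.vent_obs(
            DAY_START + timedelta(hours=10),
            VentMode.SPONTANEOUS,
            sbt=SbtResult(p["sbt"]),
        )
    return b.events, attrs


_sbt_passed = _RuleScenario(
    sample=lambda rng: {
        "intubated": _bern(rng, 0.7),
        "sbt": [None, "passed", "failed"][int(rng.integers(0, 3))],
        "fio2": float(rng.choice([0.4, 0.6])),
    },
    actionable=lambda rng: {"intubated": True, "sbt": "passed", "fio2": 0.45},
    spoilers=(
        lambda rng: {"sbt": "failed"},
        lambda rng: {"sbt": None, "fio2": 0.6},
        lambda rng: {"intubated": False},
    ),
    render=_render_sbt_passed,
)


# --- sedation --------------------------------------------------------------

def _render_sedation(p, pid):
    b, attrs, admit = _base(pid, comfort=p["comfort"])
    if p["sedative"]:
        b.med_order(DrugClass.SEDATIVE_INFUSION, start=admit)
        hours = float(p["hours"])
        if hours > 0:
            b.med_admin(
                DrugClass.SEDATIVE_INFUSION,
                DAY_START,
                end=DAY_START + timedelta(hours=hours),
            )
    if p["paralytic"]:
        b.med_order(DrugClass.PARALYTIC, start=admit)
    if p["contra"]:
        b.diagnosis("status_epilepticus", start=admit)
    return b.events, attrs


_sedation_wean = _RuleScenario(
    sample=lambda rng: {
        "sedative": _bern(rng, 0.7),
        "hours": float(rng.choice([0.0, 2.0, 4.0, 6.0, 8.0, 12.0])),
        "paralytic": _bern(rng, 0.2),
        "comfort": _bern(rng, 0.15),
        "contra": _bern(rng, 0.2),
    },
    actionable=lambda rng: {
        "sedative": True,
        "hours": float(rng.choice([6.0, 8.0, 10.0, 12.0])),
        "paralytic": False,
        "comfort": False,
        "contra": False,
    },
    spoilers=(
        lambda rng: {"sedative": False, "hours": 0.0},
        lambda rng: {"hours": float(rng.choice([0.0, 2.0, 4.0]))},
        lambda rng: {"paralytic": True},
        lambda rng: {"comfort": True},
        lambda rng: {"contra": True},
    ),
    render=_render_sedation,
)


# --- nutrition -------------------------------------------------------------

def _render_nutrition_start(p, pid):
    b, attrs, admit = _base(
        pid, admit_hours=float(p["hours_since_admit"]), fed=p["fed"],
        comfort=p["comfort"],
    )
    return b.events, attrs


_nutrition_start = _RuleScenario(
    sample=lambda rng: {
        "hours_since_admit": float(rng.choice([24.0, 47.0, 48.0, 72.0, 120.0])),
        "fed": _bern(rng),
        "comfort": _bern(rng, 0.15),
    },
    actionable=lambda rng: {
        "hours_since_admit": float(rng.choice([60.0, 96.0, 150.0])),
        "fed": False,
        "comfort": False,
    },
    spoilers=(
        lambda rng: {"fed": True},
        lambda rng: {"comfort": True},
        lambda rng: {"hours_since_admit": float(rng.choice([12.0, 24.0, 40.0]))},
    ),
    render=_render_nutrition_start,
)


def _render_nutrition_adequacy(p, pid):
    b, attrs, admit = _base(
        pid,
        admit_hours=96.0 if p["active"] else 24.0,
        fed=False,
        comfort=p["comfort"],
    )
    if p["active"]:
        b.add(
            NutritionEvent,
            route=NutritionRoute.ENTERAL,
            goal_kcal=float(p["goal"]),
            delivered_kcal_24h=float(p["delivered"]),
            start=EVAL_TIME - timedelta(hours=6),
        )
    return b.events, attrs


def _sample_nutrition_adequacy(rng):
    goal = float(rng.integers(160, 241) * 10)
    if rng.random() < 0.1:
        delivered = 0.8 * goal  # exact boundary: meeting need, no flag
    else:
        delivered = round(goal * float(rng.uniform(0.4, 1.1)), 1)
    return {
        "active": _bern(rng, 0.7),
        "goal": goal,
        "delivered": delivered,
        "comfort": _bern(rng, 0.15),
    }


def _actionable_nutrition_adequacy(rng):
    goal = float(rng.integers(160, 241) * 10)
    return {
        "active": True,
        "goal": goal,
        "delivered": round(goal * float(rng.uniform(0.4, 0.75)), 1),
        "comfort": False,
    }


# delivered-kcal spoilers depend on the sampled goal, so they set a marker
# that generate_patient_day resolves once the goal is known
def _spoil_adequacy_high(rng):
    return {"_spoil": "high"}


def _spoil_adequacy_boundary(rng):
    return {"_spoil": "boundary"}


def _spoil_adequacy_comfort(rng):
    return {"comfort": True}


def _spoil_adequacy_inactive(rng):
    return {"active": False}


_nutrition_adequacy = _RuleScenario(
    sample=_sample_nutrition_adequacy,
    actionable=_actionable_nutrition_adequacy,
    spoilers=(
        _spoil_adequacy_high,
        _spoil_adequacy_boundary,
        _spoil_adequacy_comfort,
        _spoil_adequacy_inactive,
    ),
    render=_render_nutrition_adequacy,
)


# --- catheter removal ------------------------------------------------------

def _render_urinary(p, pid):
    b, attrs, admit = _base(pid, comfort=p["comfort"])
    if p["present"]:
        b.device(Device.URINARY_CATHETER, start=admit)
    if p["retention"]:
        b.diagnosis("urinary_retention", start=admit)
    if p["strict_io"]:
        b.add(
            ActivityOrderEvent,
            activity=Activity.STRICT_IO,
            status=OrderStatus.ACTIVE,
            start=admit,
        )
    if p["pressor_order"]:
        b.med_order(DrugClass.VASOPRESSOR, start=admit)
    if p["cbi"]:
        b.add(
            ActivityOrderEvent,
            activity=Activity.BLADDER_IRRIGATION,
            status=OrderStatus.ACTIVE,
            start=admit,
        )
    return b.events, attrs


_urinary = _RuleScenario(
    sample=lambda rng: {
        "present": _bern(rng, 0.7),
        "retention": _bern(rng, 0.2),
        "strict_io": _bern(rng, 0.3),
        "pressor_order": _bern(rng, 0.3),
        "cbi": _bern(rng, 0.15),
        "comfort": _bern(rng, 0.15),
    },
    actionable=lambda rng: {
        "present": True,
        "retention": False,
        "strict_io": _bern(rng, 0.3),  # strict I/O alone is not an indication
        "pressor_order": False,
        "cbi": False,
        "comfort": False,
    },
    spoilers=(
        lambda rng: {"present": False},
        lambda rng: {"retention": True},
        lambda rng: {"cbi": True},
        lambda rng: {"strict_io": True, "pressor_order": True},
        lambda rng: {"comfort": True},
    ),
    render=_render_urinary,
)


def _render_central(p, pid):
    b, attrs, admit = _base(pid, comfort=p["comfort"])
    if p["present"]:
        b.device(
            Device.CENTRAL_LINE, start=EVAL_TIME - timedelta(days=2), site=Site.IJ
        )
    if p["pressor_admin"]:
        b.med_admin(DrugClass.VASOPRESSOR, EVAL_TIME - timedelta(hours=6))
    if p["central_med"]:
        b.med_order(DrugClass.CENTRAL_ONLY_MED, start=admit)
    if p["hd"]:
        b.add(
            ActivityOrderEvent,
            activity=Activity.HEMODIALYSIS,
            status=OrderStatus.ACTIVE,
            start=admit,
        )
    return b.events, attrs


_central_removal = _RuleScenario(
    sample=lambda rng: {
        "present": _bern(rng, 0.7),
        "pressor_admin": _bern(rng, 0.3),
        "central_med": _bern(rng, 0.25),
        "hd": _bern(rng, 0.15),
        "comfort": _bern(rng, 0.15),
    },
    actionable=lambda rng: {
        "present": True,
        "pressor_admin": False,
        "central_med": False,
        "hd": False,
        "comfort": False,
    },
    spoilers=(
        lambda rng: {"present": False},
        lambda rng: {"pressor_admin": True},
        lambda rng: {"central_med": True},
        lambda rng: {"hd": True},
        lambda rng: {"comfort": True},
    ),
    render=_render_central,
)


def _render_arterial(p, pid):
    b, attrs, admit = _base(pid, comfort=p["comfort"])
    if p["present"]:
        b.device(
            Device.ARTERIAL_LINE, start=EVAL_TIME - timedelta(days=2), site=Site.RADIAL
        )
    if p["pressor_admin"]:
        b.med_admin(DrugClass.VASOPRESSOR, EVAL_TIME - timedelta(hours=6))
    for k in range(int(p["abg_count"])):
        b.lab(Analyte.ABG, 7.4, EVAL_TIME - timedelta(hours=1 + 3 * k))
    return b.events, attrs


_arterial_removal = _RuleScenario(
    sample=lambda rng: {
        "present": _bern(rng, 0.7),
        "pressor_admin": _bern(rng, 0.3),
        "abg_count": int(rng.integers(0, 7)),
        "comfort": _bern(rng, 0.15),
    },
    actionable=lambda rng: {
        "present": True,
        "pressor_admin": False,
        "abg_count": int(rng.integers(0, 4)),
        "comfort": False,
    },
    spoilers=(
        lambda rng: {"present": False},
        lambda rng: {"pressor_admin": True},
        lambda rng: {"abg_count": int(rng.integers(4, 7))},
        lambda rng: {"comfort": True},
    ),
    render=_render_arterial,
)


def _render_picc(p, pid):
    b, attrs, admit = _base(pid, admit_hours=144.0, comfort=p["comfort"])
    if p["present"]:
        b.device(Device.PICC, start=EVAL_TIME - timedelta(days=5), site=Site.OTHER)
    if p["long_course"]:
        b.med_order(DrugClass.LONG_COURSE_IV, start=admit)
    return b.events, attrs


_picc_removal = _RuleScenario(
    sample=lambda rng: {
        "present": _bern(rng, 0.7),
        "long_course": _bern(rng, 0.4),
        "comfort": _bern(rng, 0.15),
    },
    actionable=lambda rng: {"present": True, "long_course": False, "comfort": False},
    spoilers=(
        lambda rng: {"present": False},
        lambda rng: {"long_course": True},
        lambda rng: {"comfort": True},
    ),
    render=_render_picc,
)


def _render_rectal(p, pid):
    b, attrs, admit = _base(pid, comfort=p["comfort"])
    if p["present"]:
        b.device(Device.RECTAL_TUBE, start=EVAL_TIME - timedelta(days=1))
    if p["liquid"]:
        b.add(
            FlowsheetDocEvent,
            doc_type=DocType.STOOL_OUTPUT,
            value="liquid",
            start=DAY_START + timedelta(hours=9),
        )
    if p["skin"]:
        b.diagnosis("skin_breakdown", start=admit)
    return b.events, attrs


_rectal_removal = _RuleScenario(
    sample=lambda rng: {
        "present": _bern(rng, 0.7),
        "liquid": _bern(rng, 0.4),
        "skin": _bern(rng, 0.4),
        "comfort": _bern(rng, 0.15),
    },
    actionable=lambda rng: {
        "present": True,
        # one of the pair alone is not an indication
        "liquid": _bern(rng, 0.3),
        "skin": False,
        "comfort": False,
    },
    spoilers=(
        lambda rng: {"present": False},
        lambda rng: {"liquid": True, "skin": True},
        lambda rng: {"comfort": True},
    ),
    render=_render_rectal,
)


def _render_surveillance(p, pid):
    b, attrs, admit = _base(pid)
    end = None if p["active"] else EVAL_TIME - timedelta(hours=2)
    b.device(
        Device.HD_LINE, start=admit, end=end, site=Site.IJ, outside=p["outside"]
    )
    if p["culture"]:
        b.lab(Analyte.BLOOD_CULTURE, 1.0, admit + timedelta(hours=12))
    return b.events, attrs


_surveillance = _RuleScenario(
    sample=lambda rng: {
        "outside": _bern(rng),
        "active": _bern(rng, 0.8),
        "culture": _bern(rng, 0.4),
    },
    actionable=lambda rng: {"outside": True, "active": True, "culture": False},
    spoilers=(
        lambda rng: {"culture": True},
        lambda rng: {"outside": False},
        lambda rng: {"active": False},
    ),
    render=_render_surveillance,
)


def _render_ng_to_og(p, pid):
    b, attrs, admit = _base(pid, comfort=p["comfort"])
    if p["ngt"]:
        b.device(Device.NGT, start=EVAL_TIME - timedelta(days=1))
    if p["intubated"]:
        _vent(b, admit)
    return b.events, attrs


_ng_to_og = _RuleScenario(
    sample=lambda rng: {
        "ngt": _bern(rng),
        "intubated": _bern(rng),
        "comfort": _bern(rng, 0.15),
    },
    actionable=lambda rng: {"ngt": True, "intubated": True, "comfort": False},
    spoilers=(
        lambda rng: {"ngt": False},
        lambda rng: {"intubated": False},
        lambda rng: {"comfort": True},
    ),
    render=_render_ng_to_og,
)


def _high_risk_scenario(device, limit_days, site_ok, suppress):
    """``suppress`` adds the indication that keeps the matching removal
    metric quiet while the line is in."""

    def render(p, pid):
        dwell = float(p["dwell_days"])
        b, attrs, admit = _base(pid, admit_hours=max(96.0, dwell * 24 + 24))
        if p["present"]:
            site = Site.FEMORAL if p["femoral"] else site_ok
            b.device(device, start=EVAL_TIME - timedelta(days=dwell), site=site)
            suppress(b, admit)
        return b.events, attrs

    lo, hi = (1.0, limit_days - 1.0), (limit_days + 1.0, limit_days * 2)
    return _RuleScenario(
        sample=lambda rng: {
            "present": _bern(rng, 0.7),
            "femoral": _bern(rng, 0.3),
            "dwell_days": round(float(rng.uniform(1.0, limit_days * 2)), 2),
        },
        actionable=lambda rng: (
            {"femoral": True, "dwell_days": round(float(rng.uniform(*lo)), 2)}
            if _bern(rng)
            else {"femoral": False, "dwell_days": round(float(rng.uniform(*hi)), 2)}
        )
        | {"present": True},
        spoilers=(
            lambda rng: {"present": False},
            lambda rng: {
                "femoral": False,
                "dwell_days": round(float(rng.uniform(*lo)), 2),
            },
        ),
        render=render,
    )


def _suppress_with_pressor(b, admit):
    b.med_admin(DrugClass.VASOPRESSOR, EVAL_TIME - timedelta(hours=6))


def _suppress_with_long_course(b, admit):
    b.med_order(DrugClass.LONG_COURSE_IV, start=admit)


def _suppress_nothing(b, admit):
    pass


_high_risk_central = _high_risk_scenario(
    Device.CENTRAL_LINE, 7.0, Site.IJ, _suppress_with_pressor
)
_high_risk_arterial = _high_risk_scenario(
    Device.ARTERIAL_LINE, 7.0, Site.RADIAL, _suppress_with_pressor
)
_high_risk_hd = _high_risk_scenario(Device.HD_LINE, 7.0, Site.IJ, _suppress_nothing)
_high_risk_picc = _high_risk_scenario(
    Device.PICC, 30.0, Site.OTHER, _suppress_with_long_course
)


SCENARIOS: dict[str, _RuleScenario] = {
    "hypoglycemia": _hypoglycemia,
    "vte_chemical": _vte_chemical,
    "vte_mechanical": _vte_mechanical,
    "vte_any": _vte_any,
    "sup_start": _sup_start,
    "sup_stop": _sup_stop,
    "low_tidal_volume": _low_tidal_volume,
    "sedation_wean": _sedation_wean,
    "sbt_ready": _sbt_ready,
    "sbt_passed": _sbt_passed,
    "nutrition_start": _nutrition_start,
    "nutrition_adequacy": _nutrition_adequacy,
    "urinary_catheter_removal": _urinary,
    "central_line_removal": _central_removal,
    "arterial_line_removal": _arterial_removal,
    "picc_removal": _picc_removal,
    "surveillance_culture": _surveillance,
    "rectal_tube_removal": _rectal_removal,
    "ng_to_og": _ng_to_og,
    "high_risk_central_line": _high_risk_central,
    "high_risk_arterial_line": _high_risk_arterial,
    "high_risk_hd_line": _high_risk_hd,
    "high_risk_picc": _high_risk_picc,
}

assert set(SCENARIOS) == set(RULE_IDS)


def sample_params(rule_id: str, rng: np.random.Generator) -> dict:
    """Fully random scenario parameters for ``rule_id`` (oracle testing)."""
    return SCENARIOS[rule_id].sample(rng)


def render_scenario(rule_id: str, params: dict, patient_id: str):
    """Materialize scenario parameters into (events, attributes)."""
    return SCENARIOS[rule_id].render(params, patient_id)


def _apply_adequacy_spoiler(params: dict, rng) -> dict:
    # delivered-kcal spoilers need the sampled goal
    spoil = params.pop("_spoil", None)
    if spoil == "high":
        params["delivered"] = round(params["goal"] * float(rng.uniform(0.85, 1.05)), 1)
    elif spoil == "boundary":
        params["delivered"] = 0.8 * params["goal"]
    return params


def generate_patient_day(
    rule_id: str,
    actionable: bool,
    seed: int,
    patient_id: str = "p0001",
) -> GeneratedPatientDay:
    """One synthetic patient-day whose ground truth for ``rule_id`` is
    ``actionable`` by construction; every other metric is driven inactive
    (combined-VTE exception documented above). Deterministic per seed."""
    if rule_id not in SCENARIOS:
        raise KeyError(f"unknown rule_id: {rule_id}")
    rng = np.random.default_rng(seed)
    sc = SCENARIOS[rule_id]
    params = sc.actionable(rng)
    if not actionable:
        spoiler = sc.spoilers[int(rng.integers(0, len(sc.spoilers)))]
        params = {**params, **spoiler(rng)}
    if rule_id == "nutrition_adequacy":
        params = _apply_adequacy_spoiler(dict(params), rng)
    events, attrs = sc.render(params, patient_id)
    labels = {rid: False for rid in RULE_IDS}
    labels[rule_id] = actionable
    if actionable:
        labels.update(sc.co_labels(params))
    return GeneratedPatientDay(
        patient_id=patient_id,
        events=tuple(events),
        attributes=attrs,
        eval_time=EVAL_TIME,
        labels=labels,
    )


# ---------------------------------------------------------------------------
# Documentation noise
# ---------------------------------------------------------------------------

def inject_noise(
    events: Sequence, noise: NoiseSpec, rng: np.random.Generator
) -> list:
    """Perturb one patient's stream per the noise probabilities.

    Adds flowsheet rows contradicting the MAR and deletes labs; MAR actions
    themselves are never altered (the MAR is the source of truth). Stool
    documentation is never fabricated, since it is a legitimate rule input.
    """
    out = list(events)
    if noise.lab_absent_p > 0:
        out = [
            e
            for e in out
            if not (isinstance(e, LabEvent) and rng.random() < noise.lab_absent_p)
        ]
    if not out:
        return out
    pid = out[0].patient_id
    anchor = max(e.start for e in out)
    n = 0
    if rng.random() < noise.note_claim_p:
        n += 1
        out.append(
            FlowsheetDocEvent(
                patient_id=pid,
                event_id=f"{pid}-noise{n:02d}",
                doc_type=DocType.MED_GIVEN_CLAIM,
                drug_class=DrugClass.UFH_PROPHYLACTIC,
                value="charted as given in note",
                start=anchor,
            )
        )
    if rng.random() < noise.device_doc_gap_p:
        n += 1
        out.append(
            FlowsheetDocEvent(
                patient_id=pid,
                event_id=f"{pid}-noise{n:02d}",
                doc_type=DocType.DEVICE_CLAIM,
                device=Device.COMPRESSION_DEVICE,
                value="boots documented, no device episode",
                start=anchor,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortPaths:
    events: Path
    patients: Path
    truth: Path


def generate_cohort(spec: ScenarioSpec, out_dir: str | Path) -> CohortPaths:
    """Write a census-sized cohort: events JSONL, patient-attribute JSONL and
    the ground-truth CSV. Target metrics cycle through the prevalence map in
    registry order; actionability is Bernoulli per that map. Reproducible and
    byte-identical for identical spec."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prevalence = spec.prevalence_map()
    rule_cycle = [rid for rid in RULE_IDS if rid in prevalence]
    if not rule_cycle:
        raise ValueError("prevalence map selects no rules")
    rng = np.random.default_rng(spec.seed)
    paths = CohortPaths(
        events=out / "events.jsonl",
        patients=out / "patients.jsonl",
        truth=out / "truth.csv",
    )
    with (
        open(paths.events, "w") as ef,
        open(paths.patients, "w") as pf,
        open(paths.truth, "w", newline="") as tf,
    ):
        tw = csv.writer(tf)
        tw.writerow(["patient_id", "rule_id", "actionable"])
        for i in range(spec.census_size):
            rid = rule_cycle[i % len(rule_cycle)]
            actionable = bool(rng.random() < prevalence[rid])
            day_seed = int(rng.integers(0, 2**31))
            day = generate_patient_day(
                rid, actionable, day_seed, patient_id=f"p{i:04d}"
            )
            events = inject_noise(day.events, spec.noise, rng)
            for ev in events:
                ef.write(
                    json.dumps(ev.model_dump(mode="json", exclude_none=True),
                               sort_keys=True)
                    + "\n"
                )
            pf.write(
                json.dumps(
                    day.attributes.model_dump(mode="json"), sort_keys=True
                )
                + "\n"
            )
            for rule in RULE_IDS:
                tw.writerow(
                    [day.patient_id, rule, str(day.labels[rule]).lower()]
                )
    return paths
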