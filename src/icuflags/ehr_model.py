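"""Structured EHR event model and the temporal query primitives rules consume.

The engine's only input is a per-patient stream of typed, timestamped clinical
events (orders, MAR actions, labs, device episodes, diagnoses, ventilator
observations, nutrition records, code status, transfusions, activity orders,
and flowsheet documentation rows). Every event carries a half-open effective
interval ``[start, end)`` with ``end`` omitted while the order/device/state is
still in effect. A :class:`PatientDayContext` assembles one patient's events
into a queryable, deduplicated view at a single evaluation time; all rule
logic is a pure function of that context.

Source-of-truth rule: medication-dependent queries read only medication orders
and MAR (medication administration record) actions. Flowsheet documentation
claiming a drug was given is never consulted for medication state, because
order/MAR data is far more reliable than note documentation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from datetime import datetime, timedelta
from enum import Enum
from typing import Annotated, Literal, Optional, Sequence, Union
from zoneinfo import ZoneInfo

from pydantic import (
    AwareDatetime,
    BaseModel,
    ConfigDict,
    Field,
    TypeAdapter,
    model_validator,
)

logger = logging.getLogger(__name__)

Interval = tuple[datetime, datetime]


# ---------------------------------------------------------------------------
# Enumerations
# ---------------------------------------------------------------------------

class DrugClass(str, Enum):
    UFH_PROPHYLACTIC = "ufh_prophylactic"
    LMWH_PROPHYLACTIC = "lmwh_prophylactic"
    UFH_THERAPEUTIC = "ufh_therapeutic"
    LMWH_THERAPEUTIC = "lmwh_therapeutic"
    DOAC = "doac"
    WARFARIN = "warfarin"
    ACID_SUPPRESSANT = "acid_suppressant"
    SEDATIVE_INFUSION = "sedative_infusion"
    VASOPRESSOR = "vasopressor"
    PARALYTIC = "paralytic"
    INSULIN = "insulin"
    CENTRAL_ONLY_MED = "central_only_med"
    LONG_COURSE_IV = "long_course_iv"
    OTHER = "other"


#: Chemical VTE prophylaxis or therapeutic anticoagulation (UFH, LMWH, DOAC,
#: warfarin) — any active order from this set satisfies the VTE chemical arm.
ANTICOAGULANT_CLASSES = frozenset(
    {
        DrugClass.UFH_PROPHYLACTIC,
        DrugClass.LMWH_PROPHYLACTIC,
        DrugClass.UFH_THERAPEUTIC,
        DrugClass.LMWH_THERAPEUTIC,
        DrugClass.DOAC,
        DrugClass.WARFARIN,
    }
)


class OrderStatus(str, Enum):
    ACTIVE = "active"
    DISCONTINUED = "discontinued"
    HELD = "held"


class Route(str, Enum):
    IV = "iv"
    PO = "po"
    SC = "sc"
    OTHER = "other"


class AdminAction(str, Enum):
    GIVEN = "given"
    HELD = "held"
    MISSED = "missed"


class Analyte(str, Enum):
    GLUCOSE_MG_DL = "glucose_mg_dl"
    PLATELETS_K_PER_UL = "platelets_k_per_ul"
    INR = "inr"
    APTT_SEC = "aptt_sec"
    BLOOD_CULTURE = "blood_culture"
    ABG = "abg"
    OTHER = "other"


class Device(str, Enum):
    URINARY_CATHETER = "urinary_catheter"
    CENTRAL_LINE = "central_line"
    ARTERIAL_LINE = "arterial_line"
    PICC = "picc"
    HD_LINE = "hd_line"
    RECTAL_TUBE = "rectal_tube"
    NGT = "ngt"
    OGT = "ogt"
    COMPRESSION_DEVICE = "compression_device"
    ETT = "ett"


#: Vascular access devices eligible for the surveillance-culture rule.
LINE_DEVICES = frozenset(
    {Device.CENTRAL_LINE, Device.ARTERIAL_LINE, Device.PICC, Device.HD_LINE}
)


class Site(str, Enum):
    FEMORAL = "femoral"
    IJ = "ij"
    SUBCLAVIAN = "subclavian"
    RADIAL = "radial"
    OTHER = "other"
    UNKNOWN = "unknown"


class VentMode(str, Enum):
    CONTROLLED = "controlled"
    SPONTANEOUS = "spontaneous"
    SBT_IN_PROGRESS = "sbt_in_progress"


class SbtResult(str, Enum):
    PASSED = "passed"
    FAILED = "failed"


class NutritionRoute(str, Enum):
    ORAL = "oral"
    ENTERAL = "enteral"
    PARENTERAL = "parenteral"


class CodeStatus(str, Enum):
    FULL_CODE = "full_code"
    DNR_DNI = "dnr_dni"
    COMFORT_CARE = "comfort_care"


class Product(str, Enum):
    PRBC = "prbc"
    FFP = "ffp"
    PLATELETS = "platelets"
    OTHER = "other"


class Activity(str, Enum):
    AMBULATE = "ambulate"
    BEDREST = "bedrest"
    STRICT_IO = "strict_io"
    BLADDER_IRRIGATION = "bladder_irrigation"
    HEMODIALYSIS = "hemodialysis"
    OTHER = "other"


class DocType(str, Enum):
    MED_GIVEN_CLAIM = "med_given_claim"
    DEVICE_CLAIM = "device_claim"
    STOOL_OUTPUT = "stool_output"
    OTHER = "other"


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------

class _BaseEvent(BaseModel):
    """Common envelope: identity plus the half-open effective interval."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    patient_id: str
    event_id: str
    start: AwareDatetime
    end: Optional[AwareDatetime] = None
    #: Time the row was written/amended; drives duplicate resolution
    #: (latest-recorded wins). Defaults to ``start``.
    recorded: Optional[AwareDatetime] = None

    @model_validator(mode="after")
    def _check_interval(self):
        if self.end is not None and not self.start < self.end:
            raise ValueError("effective interval requires start < end")
        return self

    @property
    def recorded_time(self) -> datetime:
        return self.recorded if self.recorded is not None else self.start

    def interval_clipped(self, lo: datetime, hi: datetime) -> Optional[Interval]:
        """Intersection of the effective interval with ``[lo, hi)``."""
        end = self.end if self.end is not None else hi
        a, b = max(self.start, lo), min(end, hi)
        return (a, b) if a < b else None


class MedOrderEvent(_BaseEvent):
    kind: Literal["med_order"] = "med_order"
    drug_class: DrugClass
    status: OrderStatus
    route: Route = Route.OTHER


class MedAdminEvent(_BaseEvent):
    """One MAR action; for infusions the interval spans the running time."""

    kind: Literal["med_admin"] = "med_admin"
    drug_class: DrugClass
    action: AdminAction
    dose_time: AwareDatetime

    @model_validator(mode="after")
    def _dose_in_interval(self):
        if self.dose_time < self.start or (
            self.end is not None and self.dose_time >= self.end
        ):
            raise ValueError("dose_time must lie within the effective interval")
        return self


class LabEvent(_BaseEvent):
    kind: Literal["lab"] = "lab"
    analyte: Analyte
    value: float = Field(ge=0, allow_inf_nan=False)
    result_time: AwareDatetime

    @model_validator(mode="after")
    def _result_in_interval(self):
        if self.result_time < self.start or (
            self.end is not None and self.result_time >= self.end
        ):
            raise ValueError("result_time must lie within the effective interval")
        return self


class DeviceEvent(_BaseEvent):
    kind: Literal["device"] = "device"
    device: Device
    site: Site = Site.UNKNOWN
    #: Present on admission from an outside facility.
    placed_outside: bool = False


class DiagnosisEvent(_BaseEvent):
    """Structured problem-list entry; ``category`` is a pre-mapped keyword
    (no free-text NLP, no terminology service)."""

    kind: Literal["diagnosis"] = "diagnosis"
    category: str


class VentObsEvent(_BaseEvent):
    kind: Literal["vent_obs"] = "vent_obs"
    mode: VentMode
    tidal_volume_ml: Optional[float] = Field(default=None, gt=0)
    fio2: Optional[float] = Field(default=None, ge=0.21, le=1.0)
    peep_cmh2o: Optional[float] = Field(default=None, ge=0)
    sbt_result: Optional[SbtResult] = None


class NutritionEvent(_BaseEvent):
    kind: Literal["nutrition"] = "nutrition"
    route: NutritionRoute
    goal_kcal: Optional[float] = Field(default=None, gt=0)
    delivered_kcal_24h: Optional[float] = Field(default=None, ge=0)


class CodeStatusEvent(_BaseEvent):
    kind: Literal["code_status"] = "code_status"
    code_status: CodeStatus


class TransfusionEvent(_BaseEvent):
    """One administered blood-product unit (unit counting is per event)."""

    kind: Literal["transfusion"] = "transfusion"
    product: Product


class ActivityOrderEvent(_BaseEvent):
    kind: Literal["activity_order"] = "activity_order"
    activity: Activity
    status: OrderStatus = OrderStatus.ACTIVE


class FlowsheetDocEvent(_BaseEvent):
    """Nurse/provider documentation row. Deliberately *not* a medication
    source of truth: med queries ignore ``med_given_claim`` rows."""

    kind: Literal["flowsheet_doc"] = "flowsheet_doc"
    doc_type: DocType
    drug_class: Optional[DrugClass] = None
    device: Optional[Device] = None
    value: Optional[str] = None


ClinicalEvent = Annotated[
    Union[
        MedOrderEvent,
        MedAdminEvent,
        LabEvent,
        DeviceEvent,
        DiagnosisEvent,
        VentObsEvent,
        NutritionEvent,
        CodeStatusEvent,
        TransfusionEvent,
        ActivityOrderEvent,
        FlowsheetDocEvent,
    ],
    Field(discriminator="kind"),
]

EVENT_ADAPTER: TypeAdapter = TypeAdapter(ClinicalEvent)


class PatientAttributes(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    patient_id: str
    height_cm: float = Field(gt=100, lt=250)
    sex: Sex
    admit_time: AwareDatetime
    unit: str = "icu"


def predicted_body_weight(height_cm: float, sex: Sex) -> float:
    """Devine predicted body weight in kg, floored at 0.

    male: 50 + 0.91*(height_cm - 152.4); female: 45.5 + 0.91*(height_cm - 152.4).
    The standard denominator for lung-protective tidal volume (mL/kg PBW).
    """
    base = 50.0 if sex is Sex.MALE else 45.5
    return max(0.0, base + 0.91 * (height_cm - 152.4))


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Sequence[Interval]) -> list[Interval]:
    """Union of half-open intervals as a sorted list of disjoint intervals."""
    ivs = sorted((a, b) for a, b in intervals if a < b)
    out: list[Interval] = []
    for a, b in ivs:
        if out and a <= out[-1][1]:
            if b > out[-1][1]:
                out[-1] = (out[-1][0], b)
        else:
            out.append((a, b))
    return out


def coverage_fraction(intervals: Sequence[Interval], window: Interval) -> float:
    """|union(intervals) ∩ window| / |window| for half-open intervals.

    Raises ``ValueError`` on a degenerate (empty) window.
    """
    w0, w1 = window
    if not w0 < w1:
        raise ValueError("degenerate window")
    covered = timedelta(0)
    for a, b in merge_intervals(intervals):
        lo, hi = max(a, w0), min(b, w1)
        if lo < hi:
            covered += hi - lo
    return covered / (w1 - w0)


# ---------------------------------------------------------------------------
# Patient-day context
# ---------------------------------------------------------------------------

def _dedup_key(ev) -> tuple:
    # Deterministic regardless of input order: latest-recorded wins, then the
    # canonical JSON serialization breaks exact recorded-time ties.
    return (ev.recorded_time, json.dumps(ev.model_dump(mode="json"), sort_keys=True))


@dataclass(frozen=True)
class PatientDayContext:
    """Queryable view of one patient at one evaluation time.

    ``day_start`` is 00:00 of the evaluation time's calendar day in the
    configured timezone; day-coverage denominators use the *elapsed* current
    day ``[day_start, eval_time)``. All query methods are pure.
    """

    patient_id: str
    eval_time: datetime
    day_start: datetime
    events: tuple
    attributes: PatientAttributes

    # -- plumbing -----------------------------------------------------------

    @property
    def elapsed(self) -> timedelta:
        return self.eval_time - self.day_start

    @property
    def day_window(self) -> Interval:
        return (self.day_start, self.eval_time)

    def events_of(self, cls) -> list:
        return [e for e in self.events if isinstance(e, cls)]

    # -- labs ---------------------------------------------------------------

    def labs_in_window(self, analyte: Analyte, lookback: timedelta) -> list[LabEvent]:
        """All labs of ``analyte`` with result_time in [eval - lookback, eval]."""
        lo = self.eval_time - lookback
        return [
            e
            for e in self.events_of(LabEvent)
            if e.analyte == analyte and lo <= e.result_time <= self.eval_time
        ]

    def latest_lab_in_window(
        self, analyte: Analyte, lookback: timedelta
    ) -> Optional[tuple[float, datetime]]:
        """Most recent lab of ``analyte`` in the lookback, or None.

        Ties on result_time break by latest-recorded order.
        """
        if lookback <= timedelta(0):
            raise ValueError("lookback must be positive")
        labs = self.labs_in_window(analyte, lookback)
        if not labs:
            return None
        best = max(labs, key=lambda e: (e.result_time, _dedup_key(e)))
        return best.value, best.result_time

    # -- orders -------------------------------------------------------------

    def active_orders_at(
        self, drug_classes: frozenset | set, at: datetime
    ) -> list[MedOrderEvent]:
        """Active medication orders of the given classes whose interval contains ``at``."""
        out = []
        for e in self.events_of(MedOrderEvent):
            if (
                e.drug_class in drug_classes
                and e.status is OrderStatus.ACTIVE
                and e.start <= at
                and (e.end is None or at < e.end)
            ):
                out.append(e)
        return out

    def active_activity_orders_at(
        self, activities: set, at: datetime
    ) -> list[ActivityOrderEvent]:
        return [
            e
            for e in self.events_of(ActivityOrderEvent)
            if e.activity in activities
            and e.status is OrderStatus.ACTIVE
            and e.start <= at
            and (e.end is None or at < e.end)
        ]

    # -- MAR ----------------------------------------------------------------

    def med_admins_in_window(
        self,
        drug_class: DrugClass,
        lookback: timedelta,
        action: AdminAction = AdminAction.GIVEN,
    ) -> list[MedAdminEvent]:
        """MAR actions of ``drug_class`` with dose_time in (eval - lookback, eval]."""
        lo = self.eval_time - lookback
        return [
            e
            for e in self.events_of(MedAdminEvent)
            if e.drug_class == drug_class
            and e.action == action
            and lo < e.dose_time <= self.eval_time
        ]

    def admin_coverage_today(self, drug_class: DrugClass) -> timedelta:
        """Union duration of given-administration intervals within the elapsed day."""
        ivs = []
        for e in self.events_of(MedAdminEvent):
            if e.drug_class == drug_class and e.action is AdminAction.GIVEN:
                clipped = e.interval_clipped(self.day_start, self.eval_time)
                if clipped:
                    ivs.append(clipped)
        return sum(
            ((b - a) for a, b in merge_intervals(ivs)),
            timedelta(0),
        )

    # -- devices ------------------------------------------------------------

    def device_active_intervals(self, device: Device) -> list[Interval]:
        """Device episodes intersected with [day_start, eval_time), order preserved."""
        out = []
        for e in self.events_of(DeviceEvent):
            if e.device == device:
                clipped = e.interval_clipped(self.day_start, self.eval_time)
                if clipped:
                    out.append(clipped)
        return out

    def current_device_episode(self, device: Device) -> Optional[DeviceEvent]:
        """The episode open at eval_time (start <= eval < end/ongoing), or None."""
        open_eps = [
            e
            for e in self.events_of(DeviceEvent)
            if e.device == device
            and e.start <= self.eval_time
            and (e.end is None or self.eval_time < e.end)
        ]
        if not open_eps:
            return None
        return max(open_eps, key=lambda e: (e.start, _dedup_key(e)))

    def device_active_at_eval(self, device: Device) -> bool:
        return self.current_device_episode(device) is not None

    # -- other state --------------------------------------------------------

    def active_diagnoses(self, categories: Sequence[str]) -> list[DiagnosisEvent]:
        cats = set(categories)
        return [
            e
            for e in self.events_of(DiagnosisEvent)
            if e.category in cats
            and e.start <= self.eval_time
            and (e.end is None or self.eval_time < e.end)
        ]

    def comfort_care(self) -> Optional[bool]:
        """Comfort-care status per the latest code-status event, None if undocumented."""
        docs = [e for e in self.events_of(CodeStatusEvent) if e.start <= self.eval_time]
        if not docs:
            return None
        latest = max(docs, key=lambda e: (e.start, _dedup_key(e)))
        return latest.code_status is CodeStatus.COMFORT_CARE

    def transfusion_count(self, product: Product, lookback: timedelta) -> int:
        """Units (events) of ``product`` started in (eval - lookback, eval]."""
        lo = self.eval_time - lookback
        return sum(
            1
            for e in self.events_of(TransfusionEvent)
            if e.product == product and lo < e.start <= self.eval_time
        )

    def latest_vent_obs(self) -> Optional[VentObsEvent]:
        obs = [e for e in self.events_of(VentObsEvent) if e.start <= self.eval_time]
        if not obs:
            return None
        return max(obs, key=lambda e: (e.start, _dedup_key(e)))

    def vent_obs_today(self) -> list[VentObsEvent]:
        return [
            e
            for e in self.events_of(VentObsEvent)
            if self.day_start <= e.start <= self.eval_time
        ]

    def nutrition_in_window(self, lookback: timedelta) -> list[NutritionEvent]:
        lo = self.eval_time - lookback
        return [
            e
            for e in self.events_of(NutritionEvent)
            if lo <= e.start <= self.eval_time
        ]

    def stool_docs_today(self) -> list[FlowsheetDocEvent]:
        return [
            e
            for e in self.events_of(FlowsheetDocEvent)
            if e.doc_type is DocType.STOOL_OUTPUT
            and self.day_start <= e.start <= self.eval_time
        ]


def assemble_patient_day(
    events: Sequence,
    attributes: PatientAttributes,
    eval_time: datetime,
    tz: str = "UTC",
) -> PatientDayContext:
    """Build a deduplicated, time-sorted :class:`PatientDayContext`.

    Duplicate ``event_id``s resolve latest-recorded-wins (EHR amendment
    semantics). The result is identical for any permutation of the input
    stream. Events predating admission are kept with a logged warning; mixed
    patient ids are an error.
    """
    by_id: dict[str, object] = {}
    for ev in events:
        if ev.patient_id != attributes.patient_id:
            raise ValueError(
                f"mixed patient_ids: {ev.patient_id!r} vs {attributes.patient_id!r}"
            )
        prev = by_id.get(ev.event_id)
        if prev is None or _dedup_key(ev) > _dedup_key(prev):
            by_id[ev.event_id] = ev
    deduped = sorted(by_id.values(), key=lambda e: (e.start, e.event_id))
    for ev in deduped:
        if ev.start < attributes.admit_time:
            logger.warning(
                "event %s starts before admission (%s < %s); kept",
                ev.event_id,
                ev.start.isoformat(),
                attributes.admit_time.isoformat(),
            )
    zone = ZoneInfo(tz)
    local_eval = eval_time.astimezone(zone)
    day_start = local_eval.replace(hour=0, minute=0, second=0, microsecond=0)
    return PatientDayContext(
        patient_id=attributes.patient_id,
        eval_time=eval_time,
        day_start=day_start.astimezone(eval_time.tzinfo),
        events=tuple(deduped),
        attributes=attributes,
    )
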