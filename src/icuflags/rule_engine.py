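"""Generic rule-evaluation framework: missing-data policies, the rule
registry, and per-patient-day evaluation producing binary actionable flags.

Missing-data semantics
----------------------
Real ICU charts are incomplete, and a daily-metric engine must never crash on
absence. Every rule input declares exactly one of three policies:

``expected_present_missing``
    Data that should exist for the rule to be satisfied is absent (e.g. no
    chemoprophylaxis order on a patient expected to have chemical VTE
    prophylaxis): treat as a *negative finding* — the intervention is not in
    place.
``expected_absent_missing``
    Data whose absence is itself the good state (e.g. no central line when the
    patient does not require one): treat as a *positive finding* — nothing to
    act on.
``lab_missing``
    A lab that would inform the decision was never drawn: assume it is within
    normal limits (the clinicians actively chose not to obtain it) and
    substitute a configured normal default.

Fail-safe: an evaluator that raises internally yields an *abstained* result
(no flag) rather than a false actionable alert.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Any, Callable, Mapping, Optional, Sequence

from .ehr_model import PatientDayContext

logger = logging.getLogger(__name__)


class MissingPolicy(str, Enum):
    EXPECTED_PRESENT_MISSING = "expected_present_missing"
    EXPECTED_ABSENT_MISSING = "expected_absent_missing"
    LAB_MISSING = "lab_missing"


class Provenance(str, Enum):
    OBSERVED = "observed"
    MISSING_NEGATIVE = "missing_negative_finding"
    MISSING_POSITIVE = "missing_positive_finding"
    ASSUMED_NORMAL = "assumed_normal"


@dataclass(frozen=True)
class Resolved:
    """A rule input after the missing-data policy has been applied."""

    name: str
    value: Any
    provenance: Provenance

    @property
    def missing(self) -> bool:
        return self.provenance is not Provenance.OBSERVED

    def describe(self) -> Any:
        if self.provenance is Provenance.OBSERVED:
            return self.value
        if self.provenance is Provenance.ASSUMED_NORMAL:
            return f"missing({self.provenance.value}={self.value})"
        return f"missing({self.provenance.value})"


def resolve_missing(
    input_name: str,
    raw_value: Any,
    policy: MissingPolicy,
    normal_default: Any = None,
) -> Resolved:
    """Apply one of the three missing-data policies to a raw query result.

    Present values pass through unchanged (``observed``). Absent values
    (``None``) map per policy; the provenance tag records which branch fired.
    ``lab_missing`` requires a ``normal_default``.
    """
    if raw_value is not None:
        return Resolved(input_name, raw_value, Provenance.OBSERVED)
    if policy is MissingPolicy.LAB_MISSING:
        if normal_default is None:
            raise ValueError(
                f"lab_missing policy for {input_name!r} requires a normal_default"
            )
        return Resolved(input_name, normal_default, Provenance.ASSUMED_NORMAL)
    if policy is MissingPolicy.EXPECTED_PRESENT_MISSING:
        return Resolved(input_name, None, Provenance.MISSING_NEGATIVE)
    return Resolved(input_name, None, Provenance.MISSING_POSITIVE)


class AbstainEvaluation(Exception):
    """Raised by an evaluator that cannot responsibly flag (e.g. too little of
    the current day has elapsed for a day-coverage denominator)."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class RuleResult:
    """One metric's outcome: the binary actionable flag plus an audit trail.

    ``reasons`` carries one stable snake_case code per evaluated criterion,
    suffixed ``:met`` / ``:unmet``, so a reviewer can see exactly which branch
    fired. ``inputs_used`` maps each declared input to its resolved value or a
    ``missing(<policy>)`` marker.
    """

    rule_id: str
    flag: bool
    abstained: bool
    reasons: tuple[str, ...]
    inputs_used: Mapping[str, Any]

    def __post_init__(self):
        if self.flag and not self.reasons:
            raise ValueError("flag=true requires at least one reason code")
        if self.abstained and self.flag:
            raise ValueError("abstention never produces an actionable flag")


@dataclass(frozen=True)
class RuleDefinition:
    rule_id: str
    category: str
    display_name: str
    evaluator: Callable  # (ctx, thresholds) -> RuleResult
    #: input name -> MissingPolicy, mirroring the chart reviewers' per-element audit
    required_inputs: tuple[tuple[str, MissingPolicy], ...] = ()
    thresholds: Any = None  # metrics.Thresholds; filled by the registry


class EvalContext:
    """Helper evaluators use to accumulate criteria and resolved inputs."""

    def __init__(self, rule_id: str):
        self.rule_id = rule_id
        self.criteria: list[tuple[str, bool]] = []
        self.inputs: dict[str, Any] = {}

    def use(self, resolved: Resolved) -> Any:
        self.inputs[resolved.name] = resolved.describe()
        return resolved.value

    def note(self, name: str, value: Any) -> Any:
        self.inputs[name] = value
        return value

    def criterion(self, code: str, ok: bool) -> bool:
        self.criteria.append((code, bool(ok)))
        return bool(ok)

    def result(self) -> RuleResult:
        flag = all(ok for _, ok in self.criteria) and bool(self.criteria)
        reasons = tuple(
            f"{code}:{'met' if ok else 'unmet'}" for code, ok in self.criteria
        )
        return RuleResult(
            rule_id=self.rule_id,
            flag=flag,
            abstained=False,
            reasons=reasons,
            inputs_used=dict(self.inputs),
        )


def evaluate_rule(rule: RuleDefinition, ctx: PatientDayContext) -> RuleResult:
    """Evaluate one registered rule; never raises on missing data.

    Evaluator exceptions are absorbed into an abstained result with reason
    ``evaluator_error`` — a broken rule must not create false actionable
    alerts.
    """
    try:
        return rule.evaluator(ctx, rule.thresholds)
    except AbstainEvaluation as ab:
        return RuleResult(
            rule_id=rule.rule_id,
            flag=False,
            abstained=True,
            reasons=(ab.reason,),
            inputs_used={},
        )
    except Exception:
        logger.exception("evaluator for %s failed; abstaining", rule.rule_id)
        return RuleResult(
            rule_id=rule.rule_id,
            flag=False,
            abstained=True,
            reasons=("evaluator_error",),
            inputs_used={},
        )


def default_registry(
    overrides: Optional[Mapping[str, Mapping[str, Any]]] = None,
) -> tuple[RuleDefinition, ...]:
    """The shipped registry, one rule per daily metric, in census-column order.

    ``overrides`` maps rule_id -> {threshold field: value} (the YAML config
    shape); unknown rule ids or fields are an error.
    """
    from . import metrics  # deferred: metrics imports this module's types

    return metrics.build_registry(overrides)


def evaluate_patient_day(
    ctx: PatientDayContext,
    registry: Optional[Sequence[RuleDefinition]] = None,
) -> list[RuleResult]:
    """Evaluate every registered metric for one patient-day, in fixed order."""
    if registry is None:
        registry = default_registry()
    return [evaluate_rule(rule, ctx) for rule in registry]
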