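"""Confusion-matrix accumulation, the five classification statistics, and
exact integer reconstruction of confusion counts from published statistic
rows.

A flag/truth pair contributes a true positive when the engine flagged an
actionable finding that really was actionable, a true negative when it stayed
silent and no action was needed, and a false positive / false negative
otherwise. The five derived statistics are sensitivity ``tp/(tp+fn)``,
specificity ``tn/(tn+fp)``, accuracy ``(tp+tn)/n``, PPV ``tp/(tp+fp)`` and
NPV ``tn/(tn+fn)``; any statistic with a zero denominator is undefined and
rendered ``NaN``.

Reported statistics round half-away-from-zero to three decimals, and printed
values with truncated trailing zeros ("0.97", "0.8", "1") are accepted on
input as exactly that rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

STAT_NAMES = ("sensitivity", "specificity", "accuracy", "ppv", "npv")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class ClassificationStats:
    """Each statistic in [0,1], or NaN when its denominator is zero."""

    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in STAT_NAMES}


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def classification_stats(c: ConfusionCounts) -> ClassificationStats:
    return ClassificationStats(
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        accuracy=_ratio(c.tp + c.tn, c.n),
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
    )


def round3(value: float) -> float:
    """Round half-away-from-zero to three decimals; NaN passes through."""
    if math.isnan(value):
        return value
    sign = -1.0 if value < 0 else 1.0
    return sign * math.floor(abs(value) * 1000 + 0.5) / 1000


def render_stat(value: float) -> str:
    """Table-style rendering: 3 decimals, trailing zeros truncated, NaN as-is."""
    if math.isnan(value):
        return "NaN"
    text = f"{round3(value):.3f}".rstrip("0").rstrip(".")
    return text if text else "0"


def accumulate_confusion(
    flags: Iterable[tuple[str, str, bool]],
    truth: Iterable[tuple[str, str, bool]],
) -> tuple[dict[str, ConfusionCounts], ConfusionCounts]:
    """Tally per-rule and overall confusion counts.

    ``flags`` and ``truth`` are (patient_id, rule_id, boolean) triples; every
    flag must have exactly one matching truth label and vice versa.
    """
    truth_map: dict[tuple[str, str], bool] = {}
    for pid, rid, label in truth:
        key = (pid, rid)
        if key in truth_map:
            raise ValueError(f"duplicate truth label for {key}")
        truth_map[key] = bool(label)
    per_rule: dict[str, ConfusionCounts] = {}
    seen = set()
    for pid, rid, flag in flags:
        key = (pid, rid)
        if key in seen:
            raise ValueError(f"duplicate flag for {key}")
        seen.add(key)
        if key not in truth_map:
            raise ValueError(f"flag without truth label: {key}")
        label = truth_map[key]
        flag = bool(flag)
        cell = ConfusionCounts(
            tp=int(flag and label),
            fp=int(flag and not label),
            tn=int(not flag and not label),
            fn=int(not flag and label),
        )
        per_rule[rid] = per_rule.get(rid, ConfusionCounts()) + cell
    unmatched = set(truth_map) - seen
    if unmatched:
        raise ValueError(f"truth labels without flags: {sorted(unmatched)[:3]}...")
    overall = sum(per_rule.values(), ConfusionCounts())
    return per_rule, overall


# ---------------------------------------------------------------------------
# Integer reconstruction of counts from printed rows
# ---------------------------------------------------------------------------

def _printed_to_milli(printed: float) -> int:
    """A printed statistic as an integer in thousandths (0.97 -> 970)."""
    milli = int(round(printed * 1000))
    if not 0 <= milli <= 1000:
        raise ValueError(f"printed statistic outside [0,1]: {printed}")
    return milli


def _rounds_to(num: int, den: int, milli: Optional[int]) -> bool:
    """Does num/den round (half away from zero, 3 d.p.) to milli/1000?

    ``milli=None`` encodes a printed NaN: requires a zero denominator.
    """
    if milli is None:
        return den == 0
    if den == 0:
        return False
    return (2000 * num + den) // (2 * den) == milli


@dataclass(frozen=True)
class Reconstruction:
    counts: ConfusionCounts
    unique: bool
    survivors: tuple[ConfusionCounts, ...]


def reconstruct_counts(
    n: int,
    printed: Mapping[str, Optional[float]],
    min_stats: int = 3,
) -> Reconstruction:
    """Exhaustively invert a published statistics row to integer counts.

    ``printed`` maps statistic names (any subset of sensitivity, specificity,
    accuracy, ppv, npv) to their printed values; ``None`` encodes a printed
    NaN (undefined, zero denominator). All tuples (tp, fp, tn, fn) summing to
    ``n`` whose recomputed statistics round to every printed value survive;
    the first survivor (lexicographic in tp, fn, fp) is returned with a
    uniqueness flag. Zero survivors is an inconsistent row (error).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    unknown = set(printed) - set(STAT_NAMES)
    if unknown:
        raise ValueError(f"unknown statistics: {sorted(unknown)}")
    if len(printed) < min_stats:
        raise ValueError(
            f"at least {min_stats} printed statistics required, got {len(printed)}"
        )
    milli = {
        name: (None if value is None or (isinstance(value, float) and math.isnan(value))
               else _printed_to_milli(value))
        for name, value in printed.items()
    }
    sens = milli.get("sensitivity", ...)
    spec = milli.get("specificity", ...)
    acc = milli.get("accuracy", ...)
    ppv = milli.get("ppv", ...)
    npv = milli.get("npv", ...)

    survivors = []
    for tp in range(n + 1):
        for fn in range(n - tp + 1):
            if sens is not ... and not _rounds_to(tp, tp + fn, sens):
                continue
            for fp in range(n - tp - fn + 1):
                tn = n - tp - fn - fp
                if ppv is not ... and not _rounds_to(tp, tp + fp, ppv):
                    continue
                if spec is not ... and not _rounds_to(tn, tn + fp, spec):
                    continue
                if npv is not ... and not _rounds_to(tn, tn + fn, npv):
                    continue
                if acc is not ... and not _rounds_to(tp + tn, n, acc):
                    continue
                survivors.append(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
    if not survivors:
        raise ValueError("inconsistent row: no integer counts reproduce it")
    return Reconstruction(
        counts=survivors[0],
        unique=len(survivors) == 1,
        survivors=tuple(survivors),
    )
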