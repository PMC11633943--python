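"""Reference chart-review validation rows used as worked examples.

A multicenter chart-review validation of this kind of dynamic rule engine
reports, per metric, the number of evaluations and the five classification
statistics rounded to three decimals (trailing zeros truncated). Those rows
are inputs to :func:`icuflags.validation.reconstruct_counts`, which inverts
each row to the unique integer confusion counts consistent with every printed
value. The raw chart-level data behind the rows is not redistributable; only
the printed statistics are carried here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

NAN = math.nan

#: Screened / reviewed census arithmetic from the same review.
ADMITTED_PATIENTS = 4602
REVIEWED_PATIENTS = 484
REVIEWED_FEMALE = 211


@dataclass(frozen=True)
class ReportedRow:
    rule_id: str
    n: int
    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float

    def printed_stats(self) -> dict[str, Optional[float]]:
        """Statistics map in the shape reconstruct_counts expects
        (NaN encoded as None)."""
        out: dict[str, Optional[float]] = {}
        for name in ("sensitivity", "specificity", "accuracy", "ppv", "npv"):
            v = getattr(self, name)
            out[name] = None if math.isnan(v) else v
        return out

    @property
    def imperfect(self) -> bool:
        """True when at least one statistic is finite and not exactly 1."""
        return any(
            not math.isnan(v) and v != 1.0
            for v in (self.sensitivity, self.specificity, self.accuracy,
                      self.ppv, self.npv)
        )


#: Overall row (all metrics pooled); the per-metric rows below do not sum to
#: this n in the source report, so it is carried for reference only and is
#: not a reconstruction target.
OVERALL_ROW = ReportedRow("overall", 1421, 0.979, 0.978, 0.979, 0.969, 0.986)

REPORTED_ROWS: tuple[ReportedRow, ...] = (
    ReportedRow("hypoglycemia", 16, 1, 1, 1, 1, 1),
    ReportedRow("vte_chemical", 33, 1, 0.966, 0.97, 0.8, 1),
    ReportedRow("vte_mechanical", 22, 1, 1, 1, 1, 1),
    ReportedRow("vte_any", 33, 1, 0.962, 0.97, 0.875, 1),
    ReportedRow("sup_start", 18, 1, 1, 1, 1, 1),
    ReportedRow("sup_stop", 9, 1, 1, 1, 1, 1),
    ReportedRow("low_tidal_volume", 37, 1, 1, 1, 1, 1),
    ReportedRow("sedation_wean", 115, 0.985, 0.939, 0.965, 0.956, 0.979),
    ReportedRow("sbt_ready", 16, 1, 1, 1, 1, 1),
    ReportedRow("sbt_passed", 39, 1, 1, 1, 1, 1),
    ReportedRow("nutrition_start", 46, 0.714, 0.938, 0.87, 0.833, 0.882),
    ReportedRow("nutrition_adequacy", 53, 1, 0.973, 0.981, 0.941, 1),
    ReportedRow("urinary_catheter_removal", 130, 1, 0.944, 0.985, 0.979, 1),
    ReportedRow("central_line_removal", 149, 0.944, 0.974, 0.96, 0.971, 0.949),
    ReportedRow("arterial_line_removal", 189, 0.972, 0.983, 0.979, 0.972, 0.983),
    ReportedRow("picc_removal", 109, 0.974, 1, 0.991, 1, 0.986),
    ReportedRow("surveillance_culture", 25, NAN, 1, 1, NAN, 1),
    ReportedRow("rectal_tube_removal", 66, 1, 1, 1, 1, 1),
    ReportedRow("ng_to_og", 34, 1, 1, 1, 1, 1),
    ReportedRow("high_risk_central_line", 84, 1, 1, 1, 1, 1),
    ReportedRow("high_risk_arterial_line", 58, 1, 0.968, 0.983, 0.964, 1),
    ReportedRow("high_risk_hd_line", 36, 1, 0.962, 0.972, 0.909, 1),
    ReportedRow("high_risk_picc", 67, 1, 0.967, 0.97, 0.778, 1),
)

ROWS_BY_RULE = {row.rule_id: row for row in REPORTED_ROWS}
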