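"""Per-metric evaluator behaviour: printed-threshold boundaries, worked
examples, comfort-care suppression, and equivalence with an independent
decision-table oracle on randomized scenarios."""

import numpy as np
import pytest

from icuflags.metrics import COMFORT_SUPPRESSED_RULES, RULE_IDS
from icuflags.rule_engine import default_registry, evaluate_rule
from icuflags.synthetic_ehr import SCENARIOS, sample_params

from _oracle import ORACLES
from conftest import scenario_ctx

REGISTRY = {r.rule_id: r for r in default_registry()}


def run(rule_id, params):
    return evaluate_rule(REGISTRY[rule_id], scenario_ctx(rule_id, params))


def flag(rule_id, params):
    result = run(rule_id, params)
    assert not result.abstained, result.reasons
    return result.flag


_VTE_CHEM_BASE = {
    "coverage_min": 864,  # 80% of the elapsed day
    "anticoag": False,
    "plt": 60.0,
    "inr": 1.2,
    "aptt": 32.0,
    "bleeding": False,
    "comfort": False,
    "prbc_units": 0,
    "ambulate": False,
}


class TestVteChemical:
    def test_all_criteria_met_flags(self):
        assert flag("vte_chemical", _VTE_CHEM_BASE)

    @pytest.mark.parametrize(
        "update",
        [
            {"anticoag": True},  # active prophylactic order already present
            {"plt": 45.0},  # platelets <50 within 3 days
            {"inr": 1.5},  # INR >=1.5 boundary inclusive
            {"aptt": 40.5},  # aPTT >40
            {"prbc_units": 2},  # >1 unit PRBC in 24 h
            {"coverage_min": 756},  # 70% coverage, below 75%
            {"bleeding": True},
            {"comfort": True},
            {"ambulate": True},
        ],
    )
    def test_each_exclusion_suppresses(self, update):
        assert not flag("vte_chemical", {**_VTE_CHEM_BASE, **update})

    @pytest.mark.parametrize("minutes,expected", [(810, True), (809, False)])
    def test_75_percent_boundary_inclusive(self, minutes, expected):
        assert flag("vte_chemical", {**_VTE_CHEM_BASE, "coverage_min": minutes}) \
            is expected

    @pytest.mark.parametrize("aptt,expected", [(40.0, True), (40.1, False)])
    def test_aptt_boundary_exclusive(self, aptt, expected):
        assert flag("vte_chemical", {**_VTE_CHEM_BASE, "aptt": aptt}) is expected

    def test_absent_labs_assumed_normal(self):
        result = run("vte_chemical",
                     {**_VTE_CHEM_BASE, "plt": None, "inr": None, "aptt": None})
        assert result.flag
        assert result.inputs_used["inr_max_3d"] == "missing(assumed_normal=1.0)"


class TestVteMechanicalAndCombined:
    def test_no_modality_flags_mechanical(self):
        p = {"coverage_min": 0, "anticoag": False, "ambulate": False,
             "comfort": False, "inr": None, "coag_suppressed": False}
        assert flag("vte_mechanical", p)

    def test_heparin_prophylaxis_suppresses(self):
        p = {"coverage_min": 0, "anticoag": True, "ambulate": False,
             "comfort": False, "inr": None, "coag_suppressed": False}
        assert not flag("vte_mechanical", p)

    def test_comfort_care_suppresses(self):
        p = {"coverage_min": 0, "anticoag": False, "ambulate": False,
             "comfort": True, "inr": None, "coag_suppressed": False}
        assert not flag("vte_mechanical", p)

    def test_neither_modality_flags_combined(self):
        p = {**_VTE_CHEM_BASE, "coverage_min": 0}
        assert flag("vte_any", p)

    def test_good_compression_coverage_suppresses_combined(self):
        p = {**_VTE_CHEM_BASE, "coverage_min": 972}  # 0.9 of the day
        assert not flag("vte_any", p)

    def test_bleeding_diagnosis_suppresses_combined(self):
        p = {**_VTE_CHEM_BASE, "coverage_min": 0, "bleeding": True}
        assert not flag("vte_any", p)


class TestHypoglycemia:
    @pytest.mark.parametrize(
        "values,expected",
        [([70.0], True), ([71.0], False), ([], False), ([110.0, 65.0], True)],
    )
    def test_threshold_inclusive_and_missing_normal(self, values, expected):
        assert flag("hypoglycemia", {"glucose_values": values}) is expected


class TestSup:
    def test_ventilated_without_suppressant_starts(self):
        assert flag("sup_start", {"ventilated": True, "coag": False,
                                  "suppressant": False, "comfort": False})

    def test_suppressant_without_risk_stops(self):
        assert flag("sup_stop", {"ventilated": False, "coag": False,
                                 "suppressant": True, "comfort": False})

    def test_neither_risk_nor_suppressant_is_quiet(self):
        p = {"ventilated": False, "coag": False, "suppressant": False,
             "comfort": False}
        assert not flag("sup_start", p)
        assert not flag("sup_stop", p)


class TestLowTidalVolume:
    BASE = {"ventilated": True, "mode": "controlled", "height": 175.0,
            "sex": "male"}

    def test_600ml_in_175cm_male_exceeds_8_per_kg(self):
        # Devine PBW 70.57 kg -> 8.50 mL/kg
        assert flag("low_tidal_volume", {**self.BASE, "vt_ml": 600.0})

    def test_520ml_in_175cm_male_within_target(self):
        # 7.37 mL/kg
        assert not flag("low_tidal_volume", {**self.BASE, "vt_ml": 520.0})

    def test_not_ventilated_never_flags(self):
        assert not flag("low_tidal_volume",
                        {**self.BASE, "ventilated": False, "vt_ml": 900.0})

    def test_spontaneous_mode_not_flagged(self):
        assert not flag("low_tidal_volume",
                        {**self.BASE, "mode": "spontaneous", "vt_ml": 900.0})


class TestSedationWean:
    BASE = {"sedative": True, "hours": 8.0, "paralytic": False,
            "comfort": False, "contra": False}

    def test_long_infusion_without_exclusions_flags(self):
        assert flag("sedation_wean", self.BASE)

    @pytest.mark.parametrize(
        "update",
        [{"paralytic": True}, {"sedative": False, "hours": 0.0},
         {"hours": 3.0}, {"contra": True}],
    )
    def test_exclusions_suppress(self, update):
        assert not flag("sedation_wean", {**self.BASE, **update})


class TestSbt:
    READY = {"intubated": True, "fio2": 0.4, "peep": 5.0, "pressor": False,
             "paralytic": False, "sbt_done": False}

    def test_low_support_no_pressors_is_ready(self):
        assert flag("sbt_ready", self.READY)

    @pytest.mark.parametrize(
        "update",
        [{"fio2": 0.6}, {"peep": 10.0}, {"pressor": True},
         {"paralytic": True}, {"sbt_done": True}, {"intubated": False}],
    )
    def test_readiness_exclusions(self, update):
        assert not flag("sbt_ready", {**self.READY, **update})

    def test_passed_sbt_while_still_intubated_flags(self):
        assert flag("sbt_passed", {"intubated": True, "sbt": "passed",
                                   "fio2": 0.45})

    def test_extubated_after_passing_does_not_flag(self):
        assert not flag("sbt_passed", {"intubated": False, "sbt": "passed",
                                       "fio2": 0.45})

    def test_failed_sbt_does_not_flag(self):
        assert not flag("sbt_passed", {"intubated": True, "sbt": "failed",
                                       "fio2": 0.45})


class TestNutrition:
    def test_72h_without_any_nutrition_flags_start(self):
        assert flag("nutrition_start", {"hours_since_admit": 72.0,
                                        "fed": False, "comfort": False})

    def test_recently_admitted_not_flagged(self):
        assert not flag("nutrition_start", {"hours_since_admit": 24.0,
                                            "fed": False, "comfort": False})

    @pytest.mark.parametrize(
        "delivered,expected",
        [(1500.0, True),  # 75% of need
         (1600.0, False),  # exactly 80%: meeting need
         (1900.0, False)],
    )
    def test_80_percent_of_need_boundary(self, delivered, expected):
        p = {"active": True, "goal": 2000.0, "delivered": delivered,
             "comfort": False}
        assert flag("nutrition_adequacy", p) is expected

    def test_no_active_nutrition_no_adequacy_flag(self):
        assert not flag("nutrition_adequacy",
                        {"active": False, "goal": 2000.0, "delivered": 0.0,
                         "comfort": False})


class TestDeviceRemoval:
    CENTRAL = {"present": True, "pressor_admin": False, "central_med": False,
               "hd": False, "comfort": False}

    def test_idle_central_line_flags_for_removal(self):
        assert flag("central_line_removal", self.CENTRAL)

    def test_absent_device_is_positive_finding(self):
        result = run("central_line_removal", {**self.CENTRAL, "present": False})
        assert not result.flag
        assert result.inputs_used["central_line"] == \
            "missing(missing_positive_finding)"

    def test_retention_diagnosis_keeps_urinary_catheter(self):
        p = {"present": True, "retention": True, "strict_io": False,
             "pressor_order": False, "cbi": False, "comfort": False}
        assert not flag("urinary_catheter_removal", p)

    def test_strict_io_alone_is_not_an_indication(self):
        p = {"present": True, "retention": False, "strict_io": True,
             "pressor_order": False, "cbi": False, "comfort": False}
        assert flag("urinary_catheter_removal", p)

    def test_frequent_abgs_keep_arterial_line(self):
        p = {"present": True, "pressor_admin": False, "abg_count": 5,
             "comfort": False}
        assert not flag("arterial_line_removal", p)


class TestSurveillanceCulture:
    def test_outside_line_without_culture_flags(self):
        assert flag("surveillance_culture",
                    {"outside": True, "active": True, "culture": False})

    def test_culture_drawn_clears_flag(self):
        assert not flag("surveillance_culture",
                        {"outside": True, "active": True, "culture": True})

    def test_inhouse_lines_never_flag(self):
        assert not flag("surveillance_culture",
                        {"outside": False, "active": True, "culture": False})


class TestNgToOg:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ({"ngt": True, "intubated": True, "comfort": False}, True),
            ({"ngt": True, "intubated": False, "comfort": False}, False),
            ({"ngt": False, "intubated": True, "comfort": False}, False),
        ],
    )
    def test_exchange_only_while_intubated_with_ngt(self, p, expected):
        assert flag("ng_to_og", p) is expected


class TestHighRiskLines:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ({"present": True, "femoral": True, "dwell_days": 2.0}, True),
            ({"present": True, "femoral": False, "dwell_days": 9.0}, True),
            ({"present": True, "femoral": False, "dwell_days": 3.0}, False),
            ({"present": False, "femoral": True, "dwell_days": 9.0}, False),
        ],
    )
    def test_femoral_or_dwell(self, p, expected):
        assert flag("high_risk_central_line", p) is expected

    def test_picc_dwell_limit_is_30_days(self):
        assert not flag("high_risk_picc",
                        {"present": True, "femoral": False, "dwell_days": 12.0})
        assert flag("high_risk_picc",
                    {"present": True, "femoral": False, "dwell_days": 35.0})


@pytest.mark.parametrize("rule_id", RULE_IDS)
def test_evaluator_matches_decision_table_oracle(rule_id):
    """Each evaluator, fed rendered events, agrees with an independently
    coded oracle applied straight to the scenario parameters."""
    rng = np.random.default_rng(9000 + list(RULE_IDS).index(rule_id))
    for _ in range(200):
        params = sample_params(rule_id, rng)
        result = run(rule_id, params)
        assert result.flag == ORACLES[rule_id](params), params


@pytest.mark.parametrize("rule_id", sorted(COMFORT_SUPPRESSED_RULES))
def test_comfort_care_suppresses_category_flags(rule_id):
    """Comfort-care status silences every prophylaxis/nutrition/wean prompt."""
    rng = np.random.default_rng(77)
    for _ in range(10):
        params = SCENARIOS[rule_id].actionable(rng)
        assert flag(rule_id, params), (rule_id, params)
        assert not flag(rule_id, {**params, "comfort": True})
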