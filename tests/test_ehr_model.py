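"""Temporal query primitives: interval coverage, lab lookbacks, order/device
queries, and deterministic patient-day assembly."""

import logging
from datetime import datetime, timedelta, timezone

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icuflags.ehr_model import (
    Analyte,
    ANTICOAGULANT_CLASSES,
    DrugClass,
    Device,
    LabEvent,
    MedOrderEvent,
    DeviceEvent,
    OrderStatus,
    PatientAttributes,
    Sex,
    coverage_fraction,
    merge_intervals,
    predicted_body_weight,
)

from _oracle import minute_grid_coverage
from conftest import build_ctx

UTC = timezone.utc
T0 = datetime(2024, 3, 14, 0, 0, tzinfo=UTC)


def h(x):
    return T0 + timedelta(hours=x)


def attrs(pid="p1", admit_hours_before=96, height=175.0, sex=Sex.MALE):
    return PatientAttributes(
        patient_id=pid,
        height_cm=height,
        sex=sex,
        admit_time=h(18) - timedelta(hours=admit_hours_before),
    )


def lab(pid, eid, analyte, value, at, recorded=None):
    return LabEvent(
        patient_id=pid, event_id=eid, analyte=analyte, value=value,
        result_time=at, start=at, recorded=recorded,
    )


# ---------------------------------------------------------------------------
# coverage_fraction
# ---------------------------------------------------------------------------

class TestCoverageFraction:
    def test_three_quarters_of_a_day(self):
        assert coverage_fraction([(h(0), h(18))], (h(0), h(24))) == 0.75

    def test_empty_union_is_zero(self):
        assert coverage_fraction([], (h(0), h(24))) == 0.0

    def test_overlapping_intervals_merge_before_measuring(self):
        ivs = [(h(1), h(10)), (h(8), h(13)), (h(12), h(12.5))]
        got = coverage_fraction(ivs, (h(0), h(12)))
        assert got == pytest.approx(minute_grid_coverage(ivs, (h(0), h(12))), abs=1e-12)

    def test_degenerate_window_is_an_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            coverage_fraction([(h(0), h(1))], (h(5), h(5)))

    def test_matches_minute_grid_on_random_instances(self, rng):
        for _ in range(200):
            ivs = []
            for _ in range(rng.integers(0, 6)):
                a = int(rng.integers(0, 1440))
                b = int(rng.integers(a + 1, 1441))
                ivs.append((T0 + timedelta(minutes=a), T0 + timedelta(minutes=b)))
            got = coverage_fraction(ivs, (h(0), h(24)))
            grid = minute_grid_coverage(ivs, (h(0), h(24)))
            assert abs(got - grid) <= 1 / 1440

    @given(
        st.lists(
            st.tuples(st.integers(0, 1439), st.integers(1, 1440)).map(
                lambda ab: (min(ab), max(min(ab) + 1, ab[1]))
            ),
            max_size=6,
        ),
        st.tuples(st.integers(0, 1439), st.integers(1, 1440)).map(
            lambda ab: (min(ab), max(min(ab) + 1, ab[1]))
        ),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_under_adding_intervals(self, minutes, extra):
        ivs = [(T0 + timedelta(minutes=a), T0 + timedelta(minutes=b))
               for a, b in minutes]
        window = (h(0), h(24))
        base = coverage_fraction(ivs, window)
        extra_iv = (T0 + timedelta(minutes=extra[0]), T0 + timedelta(minutes=extra[1]))
        grown = coverage_fraction(ivs + [extra_iv], window)
        assert grown >= base
        assert 0.0 <= grown <= 1.0

    def test_merge_intervals_disjoint_sorted(self):
        got = merge_intervals([(h(5), h(6)), (h(1), h(3)), (h(2), h(4))])
        assert got == [(h(1), h(4)), (h(5), h(6))]


# ---------------------------------------------------------------------------
# lab lookbacks
# ---------------------------------------------------------------------------

class TestLatestLabInWindow:
    def test_inr_two_days_back_within_three_day_lookback(self):
        a = attrs()
        ev = [lab("p1", "e1", Analyte.INR, 1.6, h(18) - timedelta(days=2))]
        ctx = build_ctx(ev, a, eval_time=h(18))
        got = ctx.latest_lab_in_window(Analyte.INR, timedelta(days=3))
        assert got == (1.6, h(18) - timedelta(days=2))

    def test_outside_lookback_is_absent(self):
        a = attrs(admit_hours_before=200)
        ev = [lab("p1", "e1", Analyte.INR, 1.6, h(18) - timedelta(days=4))]
        ctx = build_ctx(ev, a, eval_time=h(18))
        assert ctx.latest_lab_in_window(Analyte.INR, timedelta(days=3)) is None

    def test_max_time_wins_against_exhaustive_scan(self, rng):
        a = attrs()
        times = sorted(int(rng.integers(0, 17 * 60)) for _ in range(3))
        ev = [
            lab("p1", f"e{i}", Analyte.PLATELETS_K_PER_UL, 100.0 + i,
                h(0) + timedelta(minutes=m))
            for i, m in enumerate(times)
        ]
        ctx = build_ctx(ev, a, eval_time=h(18))
        got = ctx.latest_lab_in_window(Analyte.PLATELETS_K_PER_UL, timedelta(days=3))
        best = max(ev, key=lambda e: e.result_time)
        assert got == (best.value, best.result_time)

    def test_result_time_tie_broken_by_latest_recorded(self):
        a = attrs()
        at = h(6)
        ev = [
            lab("p1", "e1", Analyte.INR, 1.1, at, recorded=h(7)),
            lab("p1", "e2", Analyte.INR, 1.9, at, recorded=h(9)),
        ]
        ctx = build_ctx(ev, a, eval_time=h(18))
        value, _ = ctx.latest_lab_in_window(Analyte.INR, timedelta(days=1))
        assert value == 1.9

    def test_nonpositive_lookback_rejected(self):
        ctx = build_ctx([], attrs(), eval_time=h(18))
        with pytest.raises(ValueError):
            ctx.latest_lab_in_window(Analyte.INR, timedelta(0))


# ---------------------------------------------------------------------------
# orders and devices
# ---------------------------------------------------------------------------

def order(pid, eid, drug, status=OrderStatus.ACTIVE, start=None, end=None):
    return MedOrderEvent(
        patient_id=pid, event_id=eid, drug_class=drug, status=status,
        start=start if start is not None else h(-48), end=end,
    )


class TestActiveOrders:
    def test_active_prophylactic_spanning_eval_is_listed(self):
        ev = [order("p1", "o1", DrugClass.LMWH_PROPHYLACTIC)]
        ctx = build_ctx(ev, attrs(), eval_time=h(18))
        got = ctx.active_orders_at(ANTICOAGULANT_CLASSES, h(18))
        assert [o.event_id for o in got] == ["o1"]

    def test_discontinued_order_not_listed(self):
        ev = [order("p1", "o1", DrugClass.LMWH_PROPHYLACTIC,
                    status=OrderStatus.DISCONTINUED)]
        ctx = build_ctx(ev, attrs(), eval_time=h(18))
        assert ctx.active_orders_at(ANTICOAGULANT_CLASSES, h(18)) == []

    def test_random_orders_agree_with_brute_force_filter(self, rng):
        classes = list(DrugClass)
        ev = []
        for i in range(5):
            start = h(float(rng.uniform(-72, 17)))
            end = None if rng.random() < 0.5 else start + timedelta(
                hours=float(rng.uniform(1, 96)))
            ev.append(order("p1", f"o{i}",
                            classes[int(rng.integers(0, len(classes)))],
                            status=list(OrderStatus)[int(rng.integers(0, 3))],
                            start=start, end=end))
        ctx = build_ctx(ev, attrs(), eval_time=h(18))
        at = h(18)
        got = {o.event_id for o in ctx.active_orders_at(ANTICOAGULANT_CLASSES, at)}
        expected = {
            o.event_id for o in ev
            if o.drug_class in ANTICOAGULANT_CLASSES
            and o.status is OrderStatus.ACTIVE
            and o.start <= at and (o.end is None or at < o.end)
        }
        assert got == expected


class TestDeviceIntervals:
    def test_open_episode_clipped_to_elapsed_day(self):
        ev = [DeviceEvent(patient_id="p1", event_id="d1",
                          device=Device.CENTRAL_LINE, start=h(-30))]
        ctx = build_ctx(ev, attrs(), eval_time=h(18))
        assert ctx.device_active_intervals(Device.CENTRAL_LINE) == [(h(0), h(18))]

    def test_no_device_events_empty(self):
        ctx = build_ctx([], attrs(), eval_time=h(18))
        assert ctx.device_active_intervals(Device.CENTRAL_LINE) == []

    def test_two_disjoint_episodes_order_preserving(self):
        ev = [
            DeviceEvent(patient_id="p1", event_id="d1",
                        device=Device.COMPRESSION_DEVICE, start=h(1), end=h(4)),
            DeviceEvent(patient_id="p1", event_id="d2",
                        device=Device.COMPRESSION_DEVICE, start=h(6), end=h(9)),
        ]
        ctx = build_ctx(ev, attrs(), eval_time=h(18))
        got = ctx.device_active_intervals(Device.COMPRESSION_DEVICE)
        assert got == [(h(1), h(4)), (h(6), h(9))]


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

class TestAssemblePatientDay:
    def test_shuffled_duplicate_stream_equals_sorted_unique(self, rng):
        a = attrs()
        ev = [lab("p1", f"e{i}", Analyte.GLUCOSE_MG_DL, 80.0 + i, h(6 + i))
              for i in range(5)]
        stream = ev + ev[:3]  # duplicates
        perm = [stream[i] for i in rng.permutation(len(stream))]
        c1 = build_ctx(perm, a, eval_time=h(18))
        c2 = build_ctx(ev, a, eval_time=h(18))
        assert c1 == c2

    def test_duplicate_event_id_latest_recorded_wins(self):
        a = attrs()
        stale = lab("p1", "e1", Analyte.INR, 1.0, h(6), recorded=h(6))
        amended = lab("p1", "e1", Analyte.INR, 1.8, h(6), recorded=h(8))
        for stream in ([stale, amended], [amended, stale]):
            ctx = build_ctx(stream, a, eval_time=h(18))
            assert len(ctx.events) == 1
            assert ctx.events[0].value == 1.8

    def test_empty_event_list_yields_valid_context(self):
        ctx = build_ctx([], attrs(), eval_time=h(18))
        assert ctx.events == ()
        assert ctx.latest_lab_in_window(Analyte.INR, timedelta(days=3)) is None

    def test_mixed_patient_ids_error(self):
        ev = [lab("p2", "e1", Analyte.INR, 1.0, h(6))]
        with pytest.raises(ValueError, match="mixed patient_ids"):
            build_ctx(ev, attrs(pid="p1"), eval_time=h(18))

    def test_event_before_admission_warns_but_is_kept(self, caplog):
        a = attrs(admit_hours_before=24)
        ev = [lab("p1", "e1", Analyte.INR, 1.0, h(18) - timedelta(days=4))]
        with caplog.at_level(logging.WARNING, logger="icuflags.ehr_model"):
            ctx = build_ctx(ev, a, eval_time=h(18))
        assert len(ctx.events) == 1
        assert any("before admission" in rec.message for rec in caplog.records)

    def test_queries_invariant_under_permutation(self, rng):
        a = attrs()
        ev = []
        for i in range(100):
            ev.append(lab("p1", f"e{i}", Analyte.GLUCOSE_MG_DL,
                          float(rng.integers(60, 200)),
                          h(0) + timedelta(minutes=int(rng.integers(0, 1080)))))
        perm = [ev[i] for i in rng.permutation(len(ev))]
        c1 = build_ctx(ev, a, eval_time=h(18))
        c2 = build_ctx(perm, a, eval_time=h(18))
        assert c1.latest_lab_in_window(Analyte.GLUCOSE_MG_DL, timedelta(hours=18)) \
            == c2.latest_lab_in_window(Analyte.GLUCOSE_MG_DL, timedelta(hours=18))
        assert c1.events == c2.events

    def test_day_start_respects_timezone(self):
        # 18:00 UTC is 14:00 in New York (EDT); the local day began at 04:00 UTC
        ctx = build_ctx([], attrs(), eval_time=h(18), tz="America/New_York")
        assert ctx.day_start == h(4)


# ---------------------------------------------------------------------------
# predicted body weight
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "height,sex,expected",
    [
        (175.0, Sex.MALE, 50 + 0.91 * 22.6),
        (175.0, Sex.FEMALE, 45.5 + 0.91 * 22.6),
        (152.4, Sex.MALE, 50.0),
        (101.0, Sex.FEMALE, 0.0),  # floored at zero below formula range
    ],
)
def test_predicted_body_weight(height, sex, expected):
    assert predicted_body_weight(height, sex) == pytest.approx(expected)
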