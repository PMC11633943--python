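from datetime import datetime, timezone

import numpy as np
import pytest

from icuflags.ehr_model import assemble_patient_day
from icuflags.synthetic_ehr import EVAL_TIME, render_scenario

UTC = timezone.utc


@pytest.fixture
def rng():
    return np.random.default_rng(20240314)


def build_ctx(events, attributes, eval_time=EVAL_TIME, tz="UTC"):
    return assemble_patient_day(events, attributes, eval_time, tz=tz)


def scenario_ctx(rule_id, params, patient_id="p0001"):
    """Render scenario parameters and assemble the patient-day context."""
    events, attrs = render_scenario(rule_id, params, patient_id)
    return build_ctx(events, attrs)


@pytest.fixture
def t0():
    """Midnight of the fixture day (UTC)."""
    return datetime(2024, 3, 14, 0, 0, tzinfo=UTC)
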