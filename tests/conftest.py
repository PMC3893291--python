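from datetime import datetime

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ethoforage.ethogram import BehaviorBout, BehaviorCategory

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_bout(activity, start, duration_s, deployment="D01", individual="A01"):
    return BehaviorBout(
        deployment_id=deployment,
        individual_id=individual,
        activity=activity,
        start=start,
        duration_s=duration_s,
    )


@pytest.fixture
def two_activity_bouts():
    """One sit-surface and one on-land bout of equal length."""
    return [
        make_bout(BehaviorCategory.SIT_SURFACE, datetime(2010, 4, 23, 10, 0), 1800),
        make_bout(BehaviorCategory.ON_LAND, datetime(2010, 4, 23, 11, 0), 1800),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
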