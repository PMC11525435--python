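import numpy as np
import pytest
from hypothesis import settings

from eventqa import CorruptionSpec, ExperimentPlan, generate_experiment

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def small_plan() -> ExperimentPlan:
    """12 events, 2x2 balanced design, grid-aligned timing at 1 kHz."""
    return ExperimentPlan(
        n_events=12,
        condition_factors={
            "category": ["face", "object"],
            "location": ["left", "right"],
        },
        planned_durations=0.5,
        inter_event_interval=0.5,
        start_time=10.0,
    )


@pytest.fixture
def clean_experiment(small_plan):
    return generate_experiment(small_plan, CorruptionSpec(), seed=7)


def make_plan(n_events: int, **kwargs) -> ExperimentPlan:
    defaults = dict(
        condition_factors={"category": ["face", "object"]},
        planned_durations=0.5,
        inter_event_interval=0.5,
        start_time=10.0,
    )
    defaults.update(kwargs)
    return ExperimentPlan(n_events=n_events, **defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
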