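import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from renalpet.frames import FramingSchedule, TimeActivityCurve, dynamic_framing_schedule
from renalpet.input_function import default_rat_bolus, eval_input_function

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def schedule() -> FramingSchedule:
    return dynamic_framing_schedule()


@pytest.fixture(scope="session")
def bolus():
    return default_rat_bolus()


def framed_input_tac(schedule: FramingSchedule, params, max_step: float = 0.5) -> TimeActivityCurve:
    """Noiseless frame-averaged arterial curve for a bolus parameter set."""
    nodes, frame_idx = schedule.refined(max_step)
    cp = np.asarray(eval_input_function(params, nodes), float)
    int_cp = 0.5 * (cp[:-1] + cp[1:]) * np.diff(nodes)
    means = np.bincount(frame_idx, weights=int_cp, minlength=schedule.n_frames) / schedule.duration
    return TimeActivityCurve(schedule, means, region="aorta")


@pytest.fixture(scope="session")
def aorta_tac(schedule, bolus) -> TimeActivityCurve:
    return framed_input_tac(schedule, bolus)
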