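import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from wormrle import StepTable

settings.register_profile(
    "wormrle",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("wormrle")


def make_step_table(
    angles, lengths=None, speeds=None, animal_id="a1", group="g"
) -> StepTable:
    """Step table straight from feature arrays (first angle should be NaN
    to mimic a real path's first step)."""
    angles = np.asarray(angles, dtype=float)
    n = angles.size
    lengths = np.ones(n) if lengths is None else np.asarray(lengths, float)
    speeds = np.ones(n) if speeds is None else np.asarray(speeds, float)
    t = np.arange(n, dtype=float)
    steps = pd.DataFrame(
        {
            "t_start": t,
            "t_end": t + 1.0,
            "length_mm": lengths,
            "angle_deg": angles,
            "speed_mm_s": speeds,
        }
    )
    return StepTable(animal_id, group, steps)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
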