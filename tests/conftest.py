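import numpy as np
import pytest

from hypotrial.series import MAPSeries


def random_map_series(rng: np.random.Generator, n: int = 60,
                      step: float = 20.0, mean: float = 70.0,
                      sd: float = 8.0, patient_id: str = "rand") -> MAPSeries:
    """A random-walk MAP series that crosses 65 mmHg with some probability."""
    times = step * np.arange(n)
    steps = rng.normal(0.0, sd / 3.0, size=n)
    values = np.clip(mean + np.cumsum(steps), 35.0, 140.0)
    return MAPSeries(patient_id=patient_id, times=times, values=values,
                     surgery_duration=times[-1] / 60.0 + 1.0,
                     nominal_step=step)


@pytest.fixture
def rng():
    return np.random.default_rng(20220113)


@pytest.fixture
def flat_series():
    """Constant 70 mmHg for one hour: never hypotensive."""
    times = 20.0 * np.arange(181)
    return MAPSeries(patient_id="flat", times=times,
                     values=np.full(181, 70.0), surgery_duration=60.0)
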