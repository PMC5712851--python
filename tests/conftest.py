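import numpy as np
import pytest

from ratiodecode.dataset import SensorArrayDataset
from ratiodecode.simulate import (
    ExperimentDesign,
    ExperimentTimeline,
    SensorModel,
    default_design,
    encode_categories,
    simulate_design,
)


def quiet_sensor(**kw) -> SensorModel:
    """A noise-free single-exponential sensor for analytic checks."""
    defaults = dict(
        polymer_id="Q",
        sensitivity_a=300.0,
        sensitivity_b=100.0,
        tau=150.0,
    )
    defaults.update(kw)
    return SensorModel(**defaults)


@pytest.fixture(scope="session")
def default_dataset() -> SensorArrayDataset:
    """The reference campaign at the canonical seed (45 samples x 3 sensors)."""
    return simulate_design(default_design(seed=0))


@pytest.fixture(scope="session")
def tiny_noiseless_dataset() -> SensorArrayDataset:
    """Two repeats per category, no noise, short recording: fast and exact."""
    timeline = ExperimentTimeline(total_duration=400.0)
    sensors = (
        quiet_sensor(polymer_id="S1", sensitivity_a=500.0, sensitivity_b=150.0, tau=120.0),
        quiet_sensor(polymer_id="S2", sensitivity_a=300.0, sensitivity_b=350.0, tau=150.0),
        quiet_sensor(polymer_id="S3", sensitivity_a=120.0, sensitivity_b=520.0, tau=180.0),
    )
    design = ExperimentDesign(
        blends=tuple(encode_categories()),
        sensors=sensors,
        timeline=timeline,
        repeats_low=2,
        repeats_high=2,
        injection_jitter_sd=0.0,
        seed=0,
    )
    return simulate_design(design)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
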