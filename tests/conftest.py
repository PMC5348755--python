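import numpy as np
import pytest
from hypothesis import settings

from cocompare.core import MeasurementRecord, StudyDataset
from cocompare.simulate import DeviceModel, SimulationConfig, simulate_study

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_dataset(n_subjects=2, methods=("td", "pR"), missing=(), values=None):
    """Small fully-observed study: td (state na) plus test channels in both
    calibration states, CO only. ``missing`` lists (subject, timepoint,
    method, state) cells to drop; ``values`` optionally maps the same key to
    a value (default 5.0)."""
    schedule = ("T0", "T1", "T2", "T3", "T4", "T5", "T6", "T7")
    records = []
    for i in range(n_subjects):
        subject = f"S{i + 1:03d}"
        for tp in schedule:
            for method in methods:
                states = ("na",) if method == "td" else ("precal", "postcal")
                for state in states:
                    key = (subject, tp, method, state)
                    if key in missing:
                        continue
                    value = (values or {}).get(key, 5.0)
                    records.append(
                        MeasurementRecord(subject, tp, method, "CO", state, value)
                    )
    return StudyDataset(records, schedule=schedule)


@pytest.fixture
def small_dataset():
    return make_dataset()


@pytest.fixture
def simulated_study():
    """Default-condition synthetic study (25 subjects x 8 timepoints)."""
    return simulate_study(SimulationConfig(seed=42))


@pytest.fixture
def noise_free_config():
    """Degenerate generator: the test channel reproduces the truth exactly."""
    dev = DeviceModel("p", additive_bias=0.0, proportional_scale=1.0,
                      subject_sd=0.0, noise_sd=0.0, drift_per_step=0.0,
                      calibration_reset=True, residual_sd=0.0)
    return SimulationConfig(n_subjects=5, devices=(dev,), td_noise_sd=0.0,
                            gedv_cv=0.0, seed=7)
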