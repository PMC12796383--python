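import numpy as np
import pandas as pd
import pytest

from discgrowth import VolumeSeries, gen_volume_series
from discgrowth.simulate import DEFAULT_GROWTH_TRUTH, SimulationConfig


@pytest.fixture
def noiseless_volume_series() -> VolumeSeries:
    """Exact logistic volumes on the default cohort design."""
    return gen_volume_series(SimulationConfig.volume_design(seed=0, noise_cv=0.0))


@pytest.fixture
def noisy_volume_series() -> VolumeSeries:
    return gen_volume_series(SimulationConfig.volume_design(seed=1, noise_cv=0.05))


@pytest.fixture
def growth_truth() -> dict:
    return dict(DEFAULT_GROWTH_TRUTH)


def toy_volume_table(times, volumes, replicates=None) -> pd.DataFrame:
    times = np.asarray(times, dtype=float)
    if replicates is None:
        replicates = np.arange(1, len(times) + 1)
    return pd.DataFrame({"time_h": times, "volume": volumes, "replicate": replicates})
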