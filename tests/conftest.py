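import numpy as np
import pandas as pd
import pytest

from actisync.device_io import CONSUMER, RESEARCH, DeviceMinuteSeries, _finalize_frame
from actisync.synthetic import DeviceBiasModel, SimulationConfig, generate_cohort


def make_series(
    device=RESEARCH,
    counts=None,
    steps=None,
    mets=None,
    intensity=None,
    start="2024-01-01 08:00",
    n=None,
):
    """Build a DeviceMinuteSeries from plain arrays for hand-constructed tests."""
    for arr in (counts, steps, mets, intensity):
        if arr is not None:
            n = len(arr)
            break
    if n is None:
        raise ValueError("give at least one column or n")
    index = pd.date_range(start, periods=n, freq="min")
    df = pd.DataFrame(index=index)
    df["counts"] = np.asarray(counts, dtype=float) if counts is not None else (0.0 if device == RESEARCH else np.nan)
    df["steps"] = np.asarray(steps, dtype=np.int64) if steps is not None else 0
    df["mets"] = np.asarray(mets, dtype=float) if mets is not None else np.nan
    df["intensity_code"] = np.asarray(intensity, dtype=float) if intensity is not None else np.nan
    df["wear"] = True
    return DeviceMinuteSeries(device=device, data=_finalize_frame(df))


@pytest.fixture(scope="session")
def identity_cohort():
    """Small cohort with an identity (truth-reporting) consumer device."""
    config = SimulationConfig(n_participants=3, n_days=5, seed=42)
    return generate_cohort(config, DeviceBiasModel.identity())


@pytest.fixture(scope="session")
def biased_cohort():
    """Small cohort under the default consumer distortion model."""
    config = SimulationConfig(n_participants=3, n_days=5, seed=42)
    return generate_cohort(config)
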