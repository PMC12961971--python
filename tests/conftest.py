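import numpy as np
import pandas as pd
import pytest

from multidien import synthetic
from multidien.types import DIEASeries


@pytest.fixture(scope="session")
def default_config():
    return synthetic.SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def default_sim(default_config):
    """Default two-year simulation: (series, ground truth)."""
    return synthetic.simulate_diea(default_config)


def make_series(z: np.ndarray, start: str = "2020-01-06") -> DIEASeries:
    """Wrap an already-z-scored hourly signal as a single-segment series."""
    n = len(z)
    ts = pd.date_range(start, periods=n, freq="h")
    s = DIEASeries(
        timestamps=ts,
        counts=np.zeros(n, int),
        visit_dates=pd.DatetimeIndex([]),
        z=np.asarray(z, float),
        segment_ids=np.zeros(n, int),
    )
    return s


def hourly_sinusoid(period_days: float, duration_days: float, phase0=0.0):
    t_days = np.arange(int(duration_days * 24)) / 24.0
    return np.cos(2 * np.pi * t_days / period_days + phase0)


def make_feature_table(
    n: int, shift: float, seed: int, n_informative: int = 4
) -> pd.DataFrame:
    """Synthetic classifier table: peak rows shifted +shift, trough -shift
    on the first ``n_informative`` features (group separation 2*shift SD)."""
    from multidien.classify import FEATURE_SETS

    rng = np.random.default_rng(seed)
    bins = rng.choice(["peak", "falling", "trough", "rising"], size=n)
    cols = {}
    feats = [f for f in FEATURE_SETS["eeg+spikes"] if f != "tod"]
    for j, f in enumerate(feats):
        x = rng.standard_normal(n)
        if j < n_informative:
            x = x + shift * (
                (bins == "peak").astype(float) - (bins == "trough")
            )
        cols[f] = x
    cols["tod"] = rng.integers(0, 2, n)
    cols["bin"] = bins
    cols["segment_id"] = 0
    return pd.DataFrame(cols)
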