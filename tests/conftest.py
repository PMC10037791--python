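import numpy as np
import pandas as pd
import pytest

from persistforage import mpmm, simdata


@pytest.fixture(scope="session")
def small_world():
    """One small simulated study shared by read-only tests."""
    cfg = simdata.SimConfig(n_individuals=4, steps_per_track=60, seed=11)
    grids, truths, raws, dives = simdata.simulate_all(cfg)
    return cfg, grids, truths, raws, dives


def make_tiny_mpmm_data(seed: int, n_steps: int = 3, n_ind: int = 1) -> mpmm.MpmmData:
    """A minimal random MpmmData instance (for likelihood-level tests)."""
    rng = np.random.default_rng(seed)
    n = n_steps * n_ind
    dprev = rng.normal(0.0, 1.2, (n, 2))
    dcur = rng.normal(0.0, 1.2, (n, 2))
    X = np.column_stack([np.ones(n), rng.normal(0.0, 1.0, n)])
    ind = np.repeat(np.arange(n_ind), n_steps)
    return mpmm.MpmmData(
        [f"i{k}" for k in range(n_ind)], ("x",), dprev, dcur, X, ind,
        np.array([f"i{k}_s0" for k in ind], dtype=object),
        np.arange(n).astype("datetime64[s]"),
    )


def weekly_ice(values, year=2009, start=None):
    """IceSeries from a list of weekly percentages."""
    start = start or f"{year}-06-01"
    idx = pd.date_range(start, periods=len(values), freq="7D")
    return simdata.IceSeries(idx, np.asarray(values, dtype=float))
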