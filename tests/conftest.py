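import numpy as np
import pandas as pd
import pytest

from tempodiff import SimulationConfig, simulate_timecourse
from tempodiff.normalize import ProfileSet, minmax_scale_set

TIME7 = np.array([0.0, 2.0, 4.0, 6.0, 9.0, 11.0, 14.0])


@pytest.fixture(scope="session")
def small_sim():
    """300-gene count-mode simulation with 10 planted genes."""
    cfg = SimulationConfig(n_genes=300, n_differential=10, seed=7)
    return cfg, simulate_timecourse(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_profile_set(wt: np.ndarray, ko: np.ndarray, time_vector=None, scaled=False) -> ProfileSet:
    """Assemble a ProfileSet directly from (N, T) arrays for metric tests."""
    wt = np.atleast_2d(np.asarray(wt, float))
    ko = np.atleast_2d(np.asarray(ko, float))
    n, T = wt.shape
    t = np.arange(T, dtype=float) if time_vector is None else np.asarray(time_vector, float)
    pooled = np.hstack([wt, ko])
    ps = ProfileSet(
        gene_ids=pd.Index([f"g{i}" for i in range(n)], name="gene_id"),
        time_vector=t,
        wt=wt,
        ko=ko,
        variance14=pooled.var(axis=1, ddof=1),
    )
    return minmax_scale_set(ps) if scaled else ps
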