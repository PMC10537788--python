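import numpy as np
import pandas as pd
import pytest

import sprintmech as sm


@pytest.fixture
def athlete():
    return sm.AthleteRecord("ath001", mass=63.1, stature=1.662)


@pytest.fixture
def quiet_spec():
    """Radar spec with noise switched off (closed-form checks)."""
    return sm.CohortSpec(noise_sd=0.0)


@pytest.fixture
def noisy_spec():
    """Radar spec at the instrument's nominal rate and accuracy."""
    return sm.CohortSpec()


_COHORT_CACHE: dict[int, sm.FeatureTable] = {}


def analytic_feature_table(seed: int, n: int = 26) -> sm.FeatureTable:
    """Feature table of a synthetic cohort derived through the analytic
    (noise-free, fit-free) profile path; cached per seed."""
    key = (seed, n)
    if key not in _COHORT_CACHE:
        res = sm.process_cohort(sm.CohortSpec(n=n, seed=seed), analytic=True)
        _COHORT_CACHE[key] = sm.build_feature_table(
            [r.fvp for r in res], [r.decel for r in res],
            [r.athlete for r in res], [r.splits for r in res], None, "t30")
    return _COHORT_CACHE[key]


def with_outcome(table: sm.FeatureTable, y, name: str) -> sm.FeatureTable:
    return sm.FeatureTable(table.frame,
                           pd.Series(np.asarray(y, float), index=table.frame.index),
                           name)


def trapezoid_time_to_distance(vmax: float, tau: float, distance: float,
                               dt: float = 1e-3) -> float:
    """Independent split-time oracle: cumulative trapezoid integration of the
    model speed on a fine grid, interpolated at the target distance."""
    t = np.arange(0.0, 60.0, dt)
    v = vmax * (1.0 - np.exp(-t / tau))
    x = np.concatenate([[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * dt)])
    i = int(np.searchsorted(x, distance))
    if i >= len(x):
        raise AssertionError("oracle grid too short")
    frac = (distance - x[i - 1]) / (x[i] - x[i - 1])
    return t[i - 1] + frac * dt
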