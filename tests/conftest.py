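import numpy as np
import pytest

from hapalysis import (
    HormoneSeries,
    RandomTrainOptions,
    SimConfig,
    generate_random_train,
    load_validation_train,
    run_hap,
    simulate,
    validation_gammas,
)


def make_series(values, delta_t=10.0, missing=None):
    """Build a HormoneSeries from a plain value list (grid from 0)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    mask = np.zeros(n, dtype=bool)
    if missing is not None:
        mask[list(missing)] = True
    vals = values.copy()
    vals[mask] = np.nan
    return HormoneSeries(delta_t * np.arange(n), vals, mask, delta_t)


@pytest.fixture
def micro_series():
    """The hand-traceable 5-point double pulse 1,3,2,6,1."""
    return make_series([1, 3, 2, 6, 1])


@pytest.fixture(scope="session")
def validation_parses():
    """(train, series, parse) for each packaged pulse train, defaults."""
    out = {}
    for gamma in validation_gammas():
        train = load_validation_train(gamma)
        series = simulate(train)
        out[gamma] = (train, series, run_hap(series))
    return out


def random_sim_series(seed, gamma=1.0):
    """A reproducible random 24-h pulsatile profile."""
    cfg = SimConfig(random_opts=RandomTrainOptions(seed=seed))
    train = generate_random_train(cfg, gamma=gamma)
    return simulate(train, cfg)


def random_walk_series(seed, n=50, integer=True):
    """A rough series exercising plateaus (integer steps) or floats."""
    rng = np.random.default_rng(seed)
    if integer:
        vals = np.cumsum(rng.integers(-2, 3, size=n)).astype(float)
    else:
        vals = np.cumsum(rng.normal(size=n))
    return make_series(vals - vals.min())
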