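import numpy as np
import pytest

from monofold import (
    Branch,
    ExperimentMeta,
    IsothermRecord,
    IsothermTrace,
    SyntheticModel,
)


def build_branch(areas, pressures, kind="compression", t0=0.0):
    """Branch from parallel arrays with synthetic 1 Hz timestamps."""
    records = tuple(
        IsothermRecord(t0 + i, float(a), float(p))
        for i, (a, p) in enumerate(zip(areas, pressures))
    )
    return Branch(kind, records)


def build_trace(areas, pressures, meta=None, times=None):
    if times is None:
        times = np.arange(len(list(areas)), dtype=float)
    records = tuple(
        IsothermRecord(float(t), float(a), float(p))
        for t, a, p in zip(times, areas, pressures)
    )
    return IsothermTrace(meta=meta or ExperimentMeta(), records=records)


@pytest.fixture
def triangle_trace():
    """Five full 166→46→166 cm² triangle sweeps with a quadratic Π response."""
    one_down = np.linspace(166.0, 46.0, 60)
    one_up = np.linspace(46.0, 166.0, 60)
    area = np.concatenate([np.concatenate([one_down, one_up]) for _ in range(5)])
    pressure = 70.0 * (166.0 - area) / 120.0
    return build_trace(area, pressure)


@pytest.fixture
def default_model():
    return SyntheticModel(seed=7)


@pytest.fixture
def noise_free_model():
    return SyntheticModel(noise_sd=0.0, seed=7)
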