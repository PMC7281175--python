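import numpy as np
import pandas as pd
import pytest

from triotrace import PeakTable


def make_table(data, groups, analytes=None):
    """Build a PeakTable from a 2-D array and a group label per sample."""
    data = np.asarray(data, dtype=float)
    n_analytes, n_samples = data.shape
    analytes = analytes or [f"a{i}" for i in range(n_analytes)]
    counts: dict[str, int] = {}
    samples = []
    for g in groups:
        counts[g] = counts.get(g, 0) + 1
        samples.append(f"{g}{counts[g]}")
    values = pd.DataFrame(data, index=analytes, columns=samples)
    return PeakTable(values=values, group_of=dict(zip(samples, groups)))


@pytest.fixture
def small_wpt_table():
    """3 analytes x 6 samples (W, P, T x 2) with distinct per-group levels."""
    rng = np.random.default_rng(7)
    base = np.array([[1.0, 2.0, 4.0], [5.0, 5.0, 5.0], [8.0, 4.0, 2.0]])
    data = np.repeat(base, 2, axis=1) * rng.lognormal(0, 0.05, (3, 6))
    return make_table(data, ["W", "W", "P", "P", "T", "T"])


@pytest.fixture
def noise_table():
    """20 analytes x 16 samples of pure log-normal noise, two groups."""
    rng = np.random.default_rng(11)
    return make_table(rng.lognormal(0, 0.3, (20, 16)), ["A"] * 8 + ["B"] * 8)
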