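import numpy as np
import pytest

from greenec import AnnualSeries, EnsemblePoint


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def years10():
    return np.arange(1990, 2000)


def make_series(values, start=1990, label="x"):
    values = np.asarray(values, dtype=float)
    return AnnualSeries(np.arange(start, start + values.size), values, label=label)


@pytest.fixture
def collinear_points():
    x = np.linspace(0.02, 0.08, 7)
    return [
        EnsemblePoint(f"m{i}", float(xi), 0.001, float(2.0 + 50.0 * xi), 0.1)
        for i, xi in enumerate(x)
    ]
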