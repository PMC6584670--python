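import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_trajectory(rng, n_points=None, nonnegative=True):
    """Random irregular-grid trajectory (times, values) for oracle checks."""
    n = n_points or int(rng.integers(2, 12))
    times = np.r_[0.0, np.cumsum(rng.uniform(0.5, 4.0, n - 1))]
    values = rng.uniform(0.0 if nonnegative else -5.0, 5.0, n)
    return times, values


def quadrature_signed_area(times, values, signed):
    """Fine-grid integration of the piecewise-linear interpolant.

    Independent oracle for auc1/auc2: integrates each segment on a dense
    sub-grid; with ``signed`` each segment carries the sign of its
    increment (+ for rising, - otherwise).
    """
    total = 0.0
    for i in range(len(times) - 1):
        t = np.linspace(times[i], times[i + 1], 2001)
        v = np.interp(t, [times[i], times[i + 1]], [values[i], values[i + 1]])
        area = np.trapezoid(v, t)
        if signed:
            area *= 1.0 if values[i + 1] - values[i] > 0 else -1.0
        total += area
    return total


def survival_arrays(records):
    t = np.array([r.time for r in records])
    e = np.array([r.event for r in records])
    return t, e
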