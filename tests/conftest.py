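import functools
import math

import numpy as np
import pytest

from beatshape.synth import SimConfig, make_beat_families, make_cohort


def brute_frechet(a: np.ndarray, b: np.ndarray) -> float:
    """Exponential-recursion discrete Fréchet oracle (independent of the DP
    implementation)."""
    a = [tuple(p) for p in np.asarray(a, dtype=float)]
    b = [tuple(p) for p in np.asarray(b, dtype=float)]

    @functools.lru_cache(maxsize=None)
    def rec(i: int, j: int) -> float:
        # plain -, *, +, sqrt: correctly-rounded IEEE ops, so agreement with
        # the DP implementation can be checked bitwise
        dx = a[i][0] - b[j][0]
        dy = a[i][1] - b[j][1]
        d = math.sqrt(dx * dx + dy * dy)
        if i == 0 and j == 0:
            return d
        if i == 0:
            return max(rec(0, j - 1), d)
        if j == 0:
            return max(rec(i - 1, 0), d)
        return max(d, min(rec(i - 1, j), rec(i - 1, j - 1), rec(i, j - 1)))

    return rec(len(a) - 1, len(b) - 1)


@pytest.fixture(scope="session")
def three_family_fixture():
    """Small planted-morphology clustering fixture (normal / QT-prolonged /
    PVC), shared across clustering and selection tests."""
    X, times, y = make_beat_families(n_per_family=400, noise_sd=0.05, seed=11)
    return X, times, y


@pytest.fixture(scope="session")
def small_cohort():
    """Two-rat, 45-minute cohort covering all glycemic classes."""
    cfg = SimConfig(
        n_rats=2,
        frac_diabetic=0.5,
        frac_died=0.5,
        duration_min=45.0,
        clamp_descent_min=25.0,
        seed=123,
    )
    return make_cohort(cfg)
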