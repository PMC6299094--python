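import numpy as np
import pytest

from mucoquant.microrheology import Trajectory


def brute_force_msd(x, y, max_lag):
    """Independent Eq-style oracle: explicit double loop over all (i, i+tau)
    overlapping pairs.  Deliberately naive."""
    n = len(x)
    out = []
    for tau in range(1, max_lag + 1):
        acc = 0.0
        for i in range(n - tau):
            acc += (x[i + tau] - x[i]) ** 2 + (y[i + tau] - y[i]) ** 2
        out.append(acc / (n - tau))
    return np.array(out)


@pytest.fixture
def random_trajectory():
    def make(seed, n=50, dt=0.1):
        rng = np.random.default_rng(seed)
        return Trajectory(
            bead_id=0,
            times=np.arange(n) * dt,
            x=rng.normal(0, 1, n).cumsum(),
            y=rng.normal(0, 1, n).cumsum(),
        )

    return make
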