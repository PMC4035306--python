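import numpy as np
import pytest

from persistlsd import (
    CovariateBundle,
    DetectionHistoryTable,
    MISSING,
    PersistenceLabels,
)


@pytest.fixture
def small_history():
    """4 sites x 3 occasions with one missing occasion."""
    y = np.array(
        [
            [1, 0, MISSING],
            [0, 0, 0],
            [1, 1, 1],
            [0, 1, 0],
        ],
        dtype=np.int8,
    )
    return DetectionHistoryTable(("A", "B", "C", "D"), y)


@pytest.fixture
def history_40():
    """40 sites x 3 complete occasions simulated at psi=0.6, p=0.7 — the
    small fixture used for grid-search oracle checks."""
    rng = np.random.default_rng(40403)
    z = rng.random(40) < 0.6
    y = ((rng.random((40, 3)) < 0.7) & z[:, None]).astype(np.int8)
    return DetectionHistoryTable(tuple(f"S{i}" for i in range(40)), y)


@pytest.fixture
def lsd_fixture_20():
    """20 sites, one continuous covariate, labels drawn from a logistic
    model — used for the dense-grid-search oracle on the LSD fit."""
    rng = np.random.default_rng(2020)
    x = rng.normal(size=20)
    from scipy.special import expit

    z = (rng.random(20) < expit(0.3 + 1.2 * x)).astype(np.int8)
    # regenerate until both classes present (deterministic given the seed)
    assert 0 < z.sum() < 20
    ids = tuple(f"S{i}" for i in range(20))
    bundle = CovariateBundle(ids, {"x": x})
    return PersistenceLabels(ids, z), bundle
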