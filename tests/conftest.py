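import logging

import numpy as np
import pytest

import mklselect as m

# the spectral-clip warning fires on nearly every small fit; keep test output readable
logging.getLogger("mklselect.local_scaling").setLevel(logging.ERROR)


@pytest.fixture
def worked_ds():
    """Tiny fixed dataset (N=8, P=2, 1-D sources) with hand-enumerable distances."""
    return m.make_worked_example()


@pytest.fixture
def recovery_ds():
    """2 informative + 6 noise sources, n=200, fixed seed."""
    return m.make_multisource(m.recovery_spec(seed=7))


@pytest.fixture
def two_source_ds():
    """Small informative + noise pair for fast MKL fits."""
    rng = np.random.default_rng(11)
    n = 60
    y = np.array([1] * 30 + [-1] * 30)
    a = rng.normal(0, 1, (n, 3)) + np.where(y > 0, 1.5, -1.5)[:, None]
    b = rng.normal(0, 1, (n, 3))
    return m.MultiSourceDataset([a, b], ["informative", "noise"], y)


def fit_default(ds, **overrides):
    defaults = dict(C=1.0, p=1.0, K=5, tau=1e-3)
    defaults.update(overrides)
    return m.MKLSourceSelection(ds, m.MKLConfig(**defaults)).fit()
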