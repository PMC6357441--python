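import numpy as np
import pytest

from talenko import SimParams, make_paralog_family
from talenko._rng import child_rng


@pytest.fixture(scope="session")
def family():
    """Default three-copy family plus pseudogene."""
    return make_paralog_family(seed=11)


@pytest.fixture(scope="session")
def family_wide_pair(family):
    from talenko import classify_specificity, enumerate_pairs

    pairs = enumerate_pairs(family)
    for p in pairs:
        if classify_specificity(p, family).klass == "family_wide":
            return p
    raise RuntimeError("fixture family has no family-wide pair")


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture()
def params():
    return SimParams(seed=11)


@pytest.fixture()
def stream():
    return child_rng
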