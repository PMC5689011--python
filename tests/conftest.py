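import numpy as np
import pytest
from hypothesis import settings

import kturnfold as kf

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog() -> kf.simulate.FixtureCatalog:
    return kf.fixtures()


@pytest.fixture(scope="session")
def kt7_ann(catalog) -> kf.KTurnAnnotation:
    return kf.annotate_kturn(catalog["kt7_fret"])


@pytest.fixture(scope="session")
def boxcd_ann(catalog) -> kf.KTurnAnnotation:
    return kf.annotate_kturn(catalog["boxcd_fret"])


@pytest.fixture(scope="session")
def pair() -> kf.FluorophorePair:
    return kf.default_pair()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
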