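import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    from pepgram import load_table1_fixture

    return load_table1_fixture()


@pytest.fixture(scope="session")
def table1_embedding(table1):
    from pepgram import mds_embed

    return mds_embed(table1)


PAPER_CLASS_A = {"gtg1", "gvg1", "gfgg1", "gtgg1", "gvgg1"}
PAPER_CLASS_B = {"fgg1", "mgg1", "vgg1", "gfgg2", "gtgg2", "gvgg2"}
PAPER_CLASS_C = {"fgg2", "gtg2", "gvg2", "mgg2", "vgg2", "gfgg3", "gtgg3", "gvgg3"}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
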