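import hypothesis
import pytest

from forminproc import Conditions, MDIA1

hypothesis.settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50)
hypothesis.settings.load_profile("suite")


@pytest.fixture
def mdia1():
    return MDIA1


@pytest.fixture
def cond_1uM():
    return Conditions(actin=1.0, profilin=0.0)
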