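import pytest

from aquamip.residue_profile import ReferencePanel
from aquamip.seqio import make_aligner


@pytest.fixture(scope="session")
def panel():
    return ReferencePanel.default()


@pytest.fixture(scope="session")
def aligner():
    return make_aligner()


@pytest.fixture(scope="session")
def free_aligner():
    return make_aligner(free_end_gaps=True)
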