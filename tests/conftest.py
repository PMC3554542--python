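import pytest

from adaptrand.core import ParticipantProfile
from adaptrand.fixtures import example_spec, example_table_state


@pytest.fixture(scope="session")
def spec_21():
    """The didactic 2:1 trial (gender, center) with medium weights."""
    return example_spec()


@pytest.fixture(scope="session")
def table_state(spec_21):
    """The 12-participant state (overall 8:4) the worked example builds on."""
    return example_table_state(spec_21)


@pytest.fixture(scope="session")
def profile_fz():
    """The 13th arrival of the worked example: female, center Z."""
    return ParticipantProfile({"gender": "F", "center": "Z"})
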