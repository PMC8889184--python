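import pytest

from lifecycles import GameParams, SizeSchedule


@pytest.fixture
def neutral_params() -> GameParams:
    """Selection off: size effects only."""
    return GameParams(w=0.0)


@pytest.fixture
def default_params() -> GameParams:
    """The model's standard threshold-game parameters (w=0.1, b=10, c=1, m=0.01)."""
    return GameParams()


@pytest.fixture
def neutral_schedule() -> SizeSchedule:
    return SizeSchedule()
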