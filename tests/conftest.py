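import pytest

from treatcascade import ScheduleKind, build_schedule


@pytest.fixture
def constant42():
    """Constant 42% per-step response schedule."""
    return build_schedule(ScheduleKind.CONSTANT, 0.42, max_steps=100)


@pytest.fixture
def declining():
    """50% first-step response, 10% geometric decline per step."""
    return build_schedule(ScheduleKind.GEOMETRIC_DECLINE, 0.50, 0.10, max_steps=100)
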