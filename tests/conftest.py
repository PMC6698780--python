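import pytest

from screencomp import runtime


@pytest.fixture(autouse=True)
def clean_display():
    """Ensure no display context leaks between tests."""
    runtime.shutdown()
    yield
    runtime.shutdown()


@pytest.fixture
def headless_display():
    ctx = runtime.init((200, 100), backend="headless")
    yield ctx
    runtime.shutdown()
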