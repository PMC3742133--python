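import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ppmscreen.promoter_io import PromoterWindow, WindowSpec

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20130806)


@pytest.fixture
def window_spec():
    return WindowSpec()


def make_window(placements=(), length=450, fill="A", gene="G1", tids=("T1",)):
    """A promoter window of ``fill`` bases with substrings written at the
    given 0-based offsets: placements = [(offset, string), ...]."""
    chars = list(fill * length)
    for offset, text in placements:
        chars[offset : offset + len(text)] = text
    return PromoterWindow(gene, tids, "".join(chars), WindowSpec())


@pytest.fixture
def plant():
    return make_window
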