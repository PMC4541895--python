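import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from gaitmon.acquisition import SIGNAL_CHANNELS, STREAM_COLUMNS
from gaitmon.synthetic import GaitSimParams, build_training_corpus

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


def make_stream(n=64, sides=("left", "right"), seed=0, fs=50.0):
    """A small random-but-valid bilateral stream for layout-level tests."""
    rng = np.random.default_rng(seed)
    parts = []
    t = np.arange(n) / fs
    for side in sides:
        part = {"timestamp": t, "side": side}
        for ch in SIGNAL_CHANNELS:
            base = rng.uniform(0.5, 3.0)
            part[ch] = np.abs(base + rng.normal(0, 0.1, n))
        parts.append(pd.DataFrame(part))
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values(["timestamp", "side"], kind="stable").reset_index(
        drop=True
    )[list(STREAM_COLUMNS)]


@pytest.fixture(scope="session")
def default_corpus():
    """Full-scale training corpus (1200 vectors per activity, fixed seed)."""
    return build_training_corpus(1200, GaitSimParams(seed=11), seed=11)


@pytest.fixture(scope="session")
def small_corpus():
    """Reduced corpus (150 vectors per activity) for fast unit tests."""
    return build_training_corpus(150, GaitSimParams(seed=3), seed=3)
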