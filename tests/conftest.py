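import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_epochs(data, fs=10.0, t_start_ms=-100.0, **kwargs):
    """Build a small EpochSet whose span is inferred from the row count."""
    from sepnoise.epochs import EpochSet

    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    t_end = t_start_ms + (data.shape[0] - 1) * 1000.0 / fs
    return EpochSet(data, fs=fs, t_start_ms=t_start_ms, t_end_ms=t_end, **kwargs)
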