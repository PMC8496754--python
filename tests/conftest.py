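import numpy as np
import pytest

from ssvepvote import (
    DEFAULT_POOL_LABELS,
    SyntheticConfig,
    benchmark_grid,
    extract_window,
    generate_epoch,
)


@pytest.fixture(scope="session")
def grid():
    return benchmark_grid()


@pytest.fixture(scope="session")
def noiseless_epoch():
    """Planted SSVEP at target 5 (9.0 Hz), no noise."""
    cfg = SyntheticConfig(snr_db=np.inf)
    return generate_epoch(cfg, 5, seed=0)


@pytest.fixture(scope="session")
def high_snr_epoch():
    """Planted SSVEP at target 5 at +40 dB."""
    cfg = SyntheticConfig(snr_db=40.0)
    return generate_epoch(cfg, 5, seed=1)


@pytest.fixture(scope="session")
def pool_window(high_snr_epoch):
    """1.0 s onset-locked window restricted to the 21-electrode pool."""
    idx = high_snr_epoch.channel_indices(DEFAULT_POOL_LABELS)
    return extract_window(high_snr_epoch, 1.0)[idx]
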