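import numpy as np
import pytest

from preictal.synthetic import (
    PreictalSignature,
    SyntheticConfig,
    generate_recording,
)


@pytest.fixture(scope="session")
def small_recording():
    """10-minute, 2-channel recording with one seizure and no signature."""
    cfg = SyntheticConfig(
        n_channels=2,
        fs=256.0,
        duration_s=600.0,
        seizure_times=[(400.0, 430.0)],
        preictal_len_s=120.0,
        seed=11,
    )
    return generate_recording(cfg, record_id="fix01")


@pytest.fixture(scope="session")
def signature_recording():
    """Recording with a strong, detectable preictal signature (2 seizures)."""
    cfg = SyntheticConfig(
        n_channels=2,
        fs=256.0,
        duration_s=1200.0,
        seizure_times=[(500.0, 520.0), (1100.0, 1120.0)],
        preictal_len_s=200.0,
        signature=PreictalSignature(
            variance_ratio=0.3, kurtosis_boost=3.0, band_shift={"alpha": 3.0}
        ),
        seed=21,
    )
    return generate_recording(cfg, record_id="fix02")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
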