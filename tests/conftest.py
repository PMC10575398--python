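import numpy as np
import pytest

from emophysio import ecg as ecg_mod
from emophysio.synthetic import (
    CohortConfig,
    ProtocolSpec,
    generate_cohort,
    generate_ecg,
)


@pytest.fixture(scope="session")
def protocol():
    return ProtocolSpec()


@pytest.fixture(scope="session")
def strong_cohort(protocol):
    """Two artifact-free sessions with strong emotion/rest contrast."""
    cfg = CohortConfig(
        n_subjects=2,
        emotion_hr_shift=15.0,
        emotion_rmssd_scale=0.5,
        scr_amplitude=1.0,
        seed=101,
    )
    return cfg, generate_cohort(cfg, protocol)


@pytest.fixture(scope="session")
def clean_snippet_256():
    """30 s clean synthetic ECG at 256 Hz."""
    rec = generate_ecg(30.0, 800.0, 20.0, seed=5)
    return ecg_mod.downsample(rec, 256.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
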