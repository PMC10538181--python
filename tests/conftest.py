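import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import splinecg as sc

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_record():
    """40 clean beats at 800 ms RR, 1 kHz, positive QRS and T."""
    spec = sc.SyntheticECGSpec(n_beats=40, rr_ms=800.0, seed=1)
    signal, truth = sc.synthesize_record(spec)
    return spec, signal, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
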