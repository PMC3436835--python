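import numpy as np
import pytest

from mapqcal import (
    QualityModel,
    generate_reference,
    generate_repetitive_reference,
    simulate_reads,
)


@pytest.fixture(scope="session")
def small_ref():
    """1 kb uniform-random reference shared by aligner/pileup tests."""
    return generate_reference(1000, seed=11)


@pytest.fixture(scope="session")
def repeat_ref():
    """5 kb reference with two diverged repeat families."""
    return generate_repetitive_reference(
        5000, seed=12, n_families=2, repeat_length=300, copies_per_family=3, divergence=0.02
    )


@pytest.fixture(scope="session")
def clean_qmodel():
    """Noise-free quality model: flat quality 40, no N bases."""
    return QualityModel(
        intercept_mean=40, slope_mean=0.0, per_read_jitter_sd=0.0, per_base_noise_sd=0.0, n_rate=0.0
    )


@pytest.fixture(scope="session")
def sim_reads(small_ref, clean_qmodel):
    return simulate_reads(small_ref, 200, read_len=50, qmodel=clean_qmodel, seed=13)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
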