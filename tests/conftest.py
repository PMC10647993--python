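import pytest

from prmlung import synthetic


@pytest.fixture(scope="session")
def phantom_small():
    """Zero-noise, zero-warp phantom: classification must be exact."""
    cfg = synthetic.PhantomConfig(
        shape=(48, 48, 48), class_fractions=(0.1, 0.2, 0.7, 0.0), seed=7
    )
    return synthetic.generate_phantom_pair(cfg)


@pytest.fixture(scope="session")
def cohort_noiseless():
    cfg = synthetic.CohortConfig(n_subjects=500, fvc_noise_sd=0.0, pct_noise_sd=0.0, seed=11)
    return synthetic.generate_cohort(cfg)


@pytest.fixture(scope="session")
def cohort_noisy():
    cfg = synthetic.CohortConfig(n_subjects=500, seed=42)
    return synthetic.generate_cohort(cfg)
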