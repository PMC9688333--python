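import numpy as np
import pytest

import sers_chemo as sc


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Small but realistic synthetic cohort (case-1 scenario)."""
    cfg = sc.SimConfig(n_subjects_per_class=6, spectra_per_subject=8, seed=7)
    dataset, truth = sc.generate_dataset(cfg)
    return dataset, truth, cfg


@pytest.fixture(scope="session")
def preprocessed(small_dataset):
    dataset, truth, cfg = small_dataset
    return sc.preprocess_pipeline(dataset), truth


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free, baseline-free, spike-free: spectra equal the pure mixture."""
    cfg = sc.SimConfig(
        n_subjects_per_class=4, spectra_per_subject=3, noise_sd=0.0,
        spike_rate=0.0, subject_sd=0.0, baseline_amplitude=0.0, seed=11,
    )
    dataset, truth = sc.generate_dataset(cfg)
    return dataset, truth, cfg
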