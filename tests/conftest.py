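"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

from milknir.model_selection import make_cv_folds
from milknir.synthetic import SyntheticConfig, simulate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_noisy():
    """A compact noisy campaign: 30 cows x 4 samples on the 2000-2450 nm window."""
    cfg = SyntheticConfig(seed=11, n_cows=30, samples_per_cow=4)
    ds, comp, truth = simulate_dataset(cfg)
    return ds, comp, truth


@pytest.fixture(scope="session")
def small_noisefree():
    """Noise- and scatter-free absorbance spectra (exactly low-rank)."""
    cfg = SyntheticConfig(seed=12, n_cows=30, samples_per_cow=4,
                          noise_sd=0.0, scatter_slope_sd=0.0,
                          scatter_offset_sd=0.0, emit_mode="absorbance")
    ds, comp, truth = simulate_dataset(cfg)
    return ds, comp, truth


@pytest.fixture(scope="session")
def noisy_cal(small_noisy):
    """Calibration matrix, fat response and cow-blocked folds from the noisy set."""
    ds, comp, _ = small_noisy
    y = comp.component("fat")
    folds = make_cv_folds(ds.cow_ids, k=10, seed=11)
    return ds, y, folds
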