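"""Wavelength selectors and the parsimony choice among them."""

import numpy as np
import pytest

from milknir.errors import ConfigError
from milknir.model_selection import CVResult, SelectionConfig, make_cv_folds
from milknir.preprocessing import PreprocessChain
from milknir.variable_selection import (VariableSelectionConfig,
                                        WavelengthSubset, choose_selection,
                                        fipls, full_spectrum,
                                        jackknife_select, make_intervals,
                                        ripls, vip_select)


def _signal_problem(seed=0, n_cows=20, p=40, informative=(10, 11, 12)):
    """y depends on a few columns; the rest is pure noise. Cow-blocked."""
    rng = np.random.default_rng(seed)
    n = n_cows * 4
    cows = np.repeat([f"c{i}" for i in range(n_cows)], 4)
    X = rng.normal(size=(n, p))
    y = X[:, list(informative)].sum(axis=1) + 0.05 * rng.normal(size=n)
    folds = make_cv_folds(cows, k=10, seed=seed)
    return X, y, folds


def test_make_intervals_remainder_absorption():
    iv = make_intervals(23, 5)
    assert len(iv) == 5
    assert [len(x) for x in iv] == [4, 4, 4, 4, 7]
    assert np.concatenate(iv).tolist() == list(range(23))
    with pytest.raises(ConfigError):
        make_intervals(5, 9)


def test_vip_select_finds_informative_columns():
    X, y, folds = _signal_problem()
    cfg = VariableSelectionConfig(max_latent=5)
    sub = vip_select(PreprocessChain(), X, y, folds, cfg)
    assert {10, 11, 12} <= set(np.flatnonzero(sub.mask))
    assert sub.n_retained < X.shape[1]


def test_vip_threshold_zero_keeps_everything():
    X, y, folds = _signal_problem(seed=1)
    cfg = VariableSelectionConfig(max_latent=3, vip_threshold=0.0)
    sub = vip_select(PreprocessChain(), X, y, folds, cfg)
    assert sub.n_retained == X.shape[1]


def test_jackknife_retains_stable_signal_and_respects_symmetry():
    X, y, folds = _signal_problem(seed=2)
    cfg = VariableSelectionConfig(max_latent=5)
    sub = jackknife_select(PreprocessChain(), X, y, folds, cfg)
    assert {10, 11, 12} <= set(np.flatnonzero(sub.mask))
    # duplicated columns receive identical decisions
    Xd = np.column_stack([X, X[:, 10]])
    sub2 = jackknife_select(PreprocessChain(), Xd, y, folds, cfg)
    assert sub2.mask[10] == sub2.mask[-1]


def test_jackknife_null_retention_rate_is_calibrated():
    """On pure noise the per-wavelength retention rate is near alpha."""
    rng = np.random.default_rng(7)
    cfg = VariableSelectionConfig(max_latent=2, alpha=0.05)
    n_cows, p, reps = 10, 15, 60
    cows = np.repeat([f"c{i}" for i in range(n_cows)], 4)
    kept = total = 0
    for r in range(reps):
        X = rng.normal(size=(n_cows * 4, p))
        y = rng.normal(size=n_cows * 4)
        folds = make_cv_folds(cows, k=10, seed=r)
        sub = jackknife_select(PreprocessChain(), X, y, folds, cfg, n_latent=2)
        kept += int(np.asarray(sub.diagnostics["p"] <= cfg.alpha).sum())
        total += p
    rate = kept / total
    assert 0.005 < rate < 0.15


def test_fipls_first_pick_is_the_signal_interval():
    X, y, folds = _signal_problem(seed=3)
    cfg = VariableSelectionConfig(max_latent=5, n_intervals=8)
    sub = fipls(PreprocessChain(), X, y, folds, cfg)
    # grid of 40 split into 8 intervals of 5: columns 10-12 sit in interval 2
    assert 2 in sub.diagnostics["active"]
    assert sub.mask[10] and sub.mask[11] and sub.mask[12]
    # retained sets are unions of contiguous intervals
    spans = sub.retained_spans(np.arange(X.shape[1], dtype=float))
    assert len(spans) >= 1


def test_ripls_never_worse_than_full_spectrum():
    X, y, folds = _signal_problem(seed=4)
    cfg = VariableSelectionConfig(max_latent=5, n_intervals=5)
    full = full_spectrum(PreprocessChain(), X, y, folds, cfg)
    sub = ripls(PreprocessChain(), X, y, folds, cfg)
    assert sub.rmsecv <= full.rmsecv + 1e-12


def test_single_interval_is_returned_unchanged():
    X, y, folds = _signal_problem(seed=5)
    cfg = VariableSelectionConfig(max_latent=3, n_intervals=1)
    for fn in (ripls, fipls):
        sub = fn(PreprocessChain(), X, y, folds, cfg)
        assert sub.n_retained == X.shape[1]


def _subset_from_residuals(method, abs_res, n_retained, n_latent, p=30):
    n = abs_res.size
    mask = np.zeros(p, dtype=bool)
    mask[:n_retained] = True
    preds = np.column_stack([-abs_res] * n_latent)
    cv = CVResult(y=np.zeros(n), predictions=preds,
                  rmsecv=np.full(n_latent, np.sqrt((abs_res**2).mean())),
                  r2cv=np.zeros(n_latent), fold_of_sample=np.zeros(n, dtype=int))
    return WavelengthSubset(method=method, mask=mask, cv=cv, n_latent=n_latent,
                            rmsecv=float(cv.rmsecv[-1]))


BASE = np.array([0.10, 0.22, 0.15, 0.30, 0.12, 0.25,
                 0.18, 0.28, 0.20, 0.16, 0.24, 0.14])
WIGGLE = np.array([-0.01, 0.01, -0.02, 0.02, -0.01, 0.01,
                   -0.02, 0.02, 0.01, -0.01, 0.02, -0.02])


def test_choose_selection_smallest_equivalent_set_wins():
    full = _subset_from_residuals("FULL", BASE, 30, 4)
    vip = _subset_from_residuals("VIP", BASE + WIGGLE, 12, 4)
    jk = _subset_from_residuals("JK", BASE + 0.4, 6, 2)   # significantly worse
    picked = choose_selection([full, vip, jk], SelectionConfig())
    assert picked is vip
    assert jk.p_vs_best < 0.05


def test_choose_selection_full_when_dominant():
    full = _subset_from_residuals("FULL", BASE / 10.0, 30, 3)
    vip = _subset_from_residuals("VIP", BASE, 5, 1)
    assert choose_selection([full, vip], SelectionConfig()) is full


def test_choose_selection_identical_residuals_prefers_fewest_wavelengths():
    cands = [_subset_from_residuals(m, BASE.copy(), k, 2)
             for m, k in (("FULL", 30), ("VIP", 8), ("RiPLS", 15))]
    assert choose_selection(cands, SelectionConfig()).method == "VIP"
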