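"""Cow-blocked CV, latent-count selection and chain selection."""

import numpy as np
import pytest
from scipy import stats

from milknir.errors import DomainError
from milknir.model_selection import (CVResult, GridRow, SelectionConfig,
                                     cross_validate, make_cv_folds,
                                     paired_worse_pvalue, select_chain,
                                     select_n_latent)
from milknir.preprocessing import PreprocessChain


# ------------------------------------------------------------------- folds
def test_48_cows_deal_into_5s_and_4s():
    cows = [f"c{i}" for i in range(48) for _ in range(4)]
    folds = make_cv_folds(cows, k=10, seed=3)
    counts = sorted(folds.cow_counts())
    assert counts == [4, 4, 5, 5, 5, 5, 5, 5, 5, 5]


def test_folds_partition_samples_and_block_cows():
    rng = np.random.default_rng(0)
    cows = rng.choice([f"c{i}" for i in range(15)], size=70)
    folds = make_cv_folds(cows, k=10, seed=1)
    assert sorted(np.unique(folds.fold_of_sample)) == list(range(10))
    for cow in np.unique(cows):
        assert len(np.unique(folds.fold_of_sample[cows == cow])) == 1
    # determinism
    folds2 = make_cv_folds(cows, k=10, seed=1)
    np.testing.assert_array_equal(folds.fold_of_sample, folds2.fold_of_sample)
    with pytest.raises(DomainError):
        make_cv_folds(["a", "b"], k=10)


# ------------------------------------------------------------- cross_validate
def test_rmsecv_bookkeeping_identity(noisy_cal):
    ds, y, folds = noisy_cal
    cv = cross_validate(PreprocessChain(), ds.intensities, y, folds,
                        max_latent=5, wavelengths=ds.wavelengths_nm)
    n = len(y)
    for a in range(1, 6):
        assert cv.rmsecv[a - 1] ** 2 * n == pytest.approx(
            (cv.residuals(a) ** 2).sum(), rel=1e-12)


def test_null_response_rmsecv_stays_near_sd(noisy_cal):
    """Pure-noise y: out-of-fold error cannot drop much below SD(y)."""
    ds, _, folds = noisy_cal
    rng = np.random.default_rng(99)
    y = rng.normal(size=ds.n_samples)
    cv = cross_validate(PreprocessChain(step1="Log"), ds.intensities, y, folds,
                        max_latent=10, wavelengths=ds.wavelengths_nm)
    assert np.all(cv.rmsecv > 0.8 * y.std())


def test_cv_locality_of_fold_changes(noisy_cal):
    """Reassigning one cow between folds leaves untouched folds' predictions."""
    ds, y, folds = noisy_cal
    chain = PreprocessChain()
    cv1 = cross_validate(chain, ds.intensities, y, folds, max_latent=3,
                         wavelengths=ds.wavelengths_nm)
    moved_cow = list(folds.fold_of_cow)[0]
    src = folds.fold_of_cow[moved_cow]
    dst = (src + 1) % folds.k
    folds2 = make_cv_folds(ds.cow_ids, k=folds.k, seed=folds.seed)
    folds2.fold_of_cow[moved_cow] = dst
    folds2.fold_of_sample = np.array(
        [folds2.fold_of_cow[c] for c in ds.cow_ids])
    cv2 = cross_validate(chain, ds.intensities, y, folds2, max_latent=3,
                         wavelengths=ds.wavelengths_nm)
    untouched = ~np.isin(folds.fold_of_sample, [src, dst])
    np.testing.assert_allclose(cv1.predictions[untouched],
                               cv2.predictions[untouched], rtol=1e-10)


# --------------------------------------------------------------- selections
def _cv_from_abs_residuals(res_by_a: list[np.ndarray]) -> CVResult:
    """Build a CVResult whose residual vectors are exactly the given ones."""
    n = res_by_a[0].size
    y = np.zeros(n)
    preds = np.column_stack([-r for r in res_by_a])
    rmse = np.sqrt((preds**2).mean(axis=0))
    return CVResult(y=y, predictions=preds, rmsecv=rmse,
                    r2cv=np.zeros(len(res_by_a)),
                    fold_of_sample=np.zeros(n, dtype=int))


BASE = np.array([0.10, 0.22, 0.15, 0.30, 0.12, 0.25,
                 0.18, 0.28, 0.20, 0.16, 0.24, 0.14])
# zero-mean wiggle with positive correlation to BASE, so BASE+WIGGLE has a
# strictly larger RMS than BASE while the paired t on |residuals| stays null
WIGGLE = np.array([-0.01, 0.01, -0.02, 0.02, -0.01, 0.01,
                   -0.02, 0.02, 0.01, -0.01, 0.02, -0.02])
SHIFT = 0.40 + np.array([0.02, -0.01, 0.03, -0.02, 0.01, -0.03,
                         0.02, -0.01, 0.03, -0.02, 0.01, -0.03])


def _manual_one_sided_t(d: np.ndarray) -> float:
    return d.mean() / (d.std(ddof=1) / np.sqrt(d.size))


def test_select_n_latent_parsimony_fixture():
    """A=3 is best, A=2 statistically indistinguishable, A=1 clearly worse."""
    res = [BASE + SHIFT, BASE + WIGGLE, BASE]
    cv = _cv_from_abs_residuals(res)
    assert int(np.argmin(cv.rmsecv)) == 2        # A* = 3
    # manual paired-t oracle against the t(11) critical value 1.7959
    t_crit = 1.7959
    assert _manual_one_sided_t(np.abs(res[0]) - BASE) > t_crit       # A=1 worse
    assert _manual_one_sided_t(np.abs(res[1]) - BASE) < t_crit       # A=2 ok
    assert select_n_latent(cv, SelectionConfig(alpha=0.05, max_latent=3)) == 2


def test_select_n_latent_degenerate_cases():
    same = [BASE.copy(), BASE.copy(), BASE.copy()]
    assert select_n_latent(_cv_from_abs_residuals(same)) == 1
    assert select_n_latent(_cv_from_abs_residuals([BASE])) == 1


def test_select_n_latent_never_exceeds_argmin(noisy_cal):
    ds, y, folds = noisy_cal
    cv = cross_validate(PreprocessChain(step1="Log"), ds.intensities, y, folds,
                        max_latent=8, wavelengths=ds.wavelengths_nm)
    assert select_n_latent(cv) <= int(np.argmin(cv.rmsecv)) + 1


def _grid_row(chain: PreprocessChain, abs_res: np.ndarray, n_latent: int) -> GridRow:
    cv = _cv_from_abs_residuals([abs_res])
    cv.predictions = np.column_stack([-abs_res] * n_latent)
    cv.rmsecv = np.full(n_latent, np.sqrt((abs_res**2).mean()))
    return GridRow(chain=chain, cv=cv, n_latent=n_latent,
                   rmsecv=float(cv.rmsecv[-1]))


def test_select_chain_parsimony_fixture():
    """Hand-computed candidate set: the indistinguishable 2-LV chain wins."""
    best = _grid_row(PreprocessChain(step1="Log", step2="SNV"), BASE, 5)
    close = _grid_row(PreprocessChain(step1="Log"), BASE + WIGGLE, 2)
    worse = _grid_row(PreprocessChain(), BASE + SHIFT, 1)
    chosen = select_chain([best, close, worse], SelectionConfig())
    assert chosen is close
    assert worse.p_vs_best < 0.05 < close.p_vs_best


def test_select_chain_tie_breaks_lexicographic():
    a = _grid_row(PreprocessChain(step1="Raw", step2="Base"), BASE, 1)
    b = _grid_row(PreprocessChain(step1="Log", step2="Base"), BASE, 1)
    chosen = select_chain([a, b], SelectionConfig())
    assert chosen.label == min(a.label, b.label)


def test_select_chain_dominant_chain_wins():
    strong = _grid_row(PreprocessChain(step1="Log"), BASE / 20.0, 6)
    weak = _grid_row(PreprocessChain(), BASE, 1)
    assert select_chain([strong, weak], SelectionConfig()) is strong


def test_paired_worse_pvalue_matches_scipy(rng):
    a = np.abs(rng.normal(size=20)) + 0.3
    b = np.abs(rng.normal(size=20))
    expected = stats.ttest_rel(a, b, alternative="greater").pvalue
    assert paired_worse_pvalue(a, b) == pytest.approx(expected, rel=1e-12)


def test_osc_component_counts_in_total_complexity():
    row = _grid_row(PreprocessChain(step4="OSC"), BASE, 2)
    assert row.n_latent == 2 and row.n_latent_total == 3
    row2 = _grid_row(PreprocessChain(), BASE, 2)
    assert row2.n_latent_total == 2
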