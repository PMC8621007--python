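"""Preprocessing steps against independent oracles, plus the grid itself."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from milknir.errors import ConfigError, DomainError
from milknir.preprocessing import (PreprocessChain, apply_chain,
                                   baseline_correct, detrend,
                                   enumerate_chains, fast_chains,
                                   log_transform, mean_center_apply,
                                   mean_center_fit, msc_apply, msc_fit,
                                   osc_fit, savgol_derivative, snv)


# ---------------------------------------------------------------------- log
@pytest.mark.parametrize("t,a", [(1.0, 0.0), (0.1, 1.0), (0.5, np.log10(2.0))])
def test_log_transform_values(t, a):
    assert log_transform(np.array([[t]]))[0, 0] == pytest.approx(a, abs=1e-12)


def test_log_transform_rejects_nonpositive():
    with pytest.raises(DomainError, match="positive"):
        log_transform(np.array([[0.5, 0.0]]))


# ----------------------------------------------------------------- baseline
def test_baseline_offset():
    np.testing.assert_allclose(baseline_correct(np.array([2.0, 3.0, 5.0])),
                               [0.0, 1.0, 3.0])
    x = np.array([0.0, 1.0, 3.0])
    np.testing.assert_allclose(baseline_correct(x), x)  # idempotent
    rng = np.random.default_rng(1)
    out = baseline_correct(rng.normal(size=(5, 9)))
    np.testing.assert_allclose(out.min(axis=1), 0.0, atol=1e-15)


# ------------------------------------------------------------------ detrend
def test_detrend_removes_quadratic_exactly():
    wl = np.linspace(1000, 1500, 40)
    spec = 3.0 + 0.01 * wl - 2e-5 * wl**2
    np.testing.assert_allclose(detrend(spec, wl), 0.0, atol=1e-9)
    np.testing.assert_allclose(detrend(np.full(40, 2.5), wl), 0.0, atol=1e-9)


def test_detrend_matches_normal_equations_oracle(rng):
    wl = np.linspace(900, 1700, 25)
    x = rng.normal(size=25)
    V = np.vander((wl - wl.mean()) / wl.std(), 3, increasing=True)
    beta = np.linalg.solve(V.T @ V, V.T @ x)
    np.testing.assert_allclose(detrend(x, wl), x - V @ beta, atol=1e-10)


# ---------------------------------------------------------------------- snv
def test_snv_reference_and_affine_invariance(rng):
    np.testing.assert_allclose(snv(np.array([1.0, 2.0, 3.0])), [-1.0, 0.0, 1.0])
    x = rng.normal(size=(4, 11))
    np.testing.assert_allclose(snv(3.7 * x + 0.4), snv(x), atol=1e-10)
    five = rng.normal(size=5)
    expected = (five - five.mean()) / five.std(ddof=1)
    np.testing.assert_allclose(snv(five), expected, rtol=1e-12)
    with pytest.raises(DomainError, match="constant"):
        snv(np.full((1, 6), 3.0))


# ---------------------------------------------------------------------- msc
def test_msc_inverts_affine_distortion(rng):
    ref = np.sin(np.linspace(0, 3, 30)) + 2
    np.testing.assert_allclose(msc_apply(ref, ref), ref, atol=1e-12)
    np.testing.assert_allclose(msc_apply(2.0 * ref + 3.0, ref), ref, atol=1e-10)
    # slope/intercept against the closed-form simple-regression oracle
    x = rng.normal(size=30) + ref
    rc = ref - ref.mean()
    a = (x - x.mean()) @ rc / (rc @ rc)
    b = x.mean() - a * ref.mean()
    np.testing.assert_allclose(msc_apply(x, ref), (x - b) / a, rtol=1e-10)


def test_msc_fit_is_calibration_mean(rng):
    X = rng.normal(size=(6, 12))
    np.testing.assert_allclose(msc_fit(X), X.mean(axis=0), rtol=1e-12)


# ------------------------------------------------------------ Savitzky-Golay
def _sg_oracle(y, window, order):
    """Brute-force windowed quadratic fit, differentiated at the center."""
    half = window // 2
    n = y.size
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        t = np.arange(lo, hi) - i
        c = np.polynomial.polynomial.polyfit(t, y[lo:hi], 2)
        out[i] = c[1] if order == 1 else 2 * c[2]
    return out


def test_sg_exact_on_polynomials():
    i = np.arange(30, dtype=float)
    d1 = savgol_derivative(2.0 * i, order=1, window=7)
    np.testing.assert_allclose(d1, 2.0, atol=1e-9)
    d2 = savgol_derivative(i**2, order=2, window=9)
    np.testing.assert_allclose(d2, 2.0, atol=1e-8)


@pytest.mark.parametrize("order", [1, 2])
def test_sg_matches_windowed_polyfit_oracle(order, rng):
    y = rng.normal(size=60)
    got = savgol_derivative(y, order=order, window=13)
    expected = _sg_oracle(y, 13, order)
    np.testing.assert_allclose(got, expected, atol=1e-9)


def test_sg_parameter_validation():
    y = np.zeros(20)
    with pytest.raises(ConfigError):
        savgol_derivative(y, order=1, window=8)    # even window
    with pytest.raises(ConfigError):
        savgol_derivative(y, order=3, window=7)    # unsupported order
    with pytest.raises(ConfigError):
        savgol_derivative(y, order=1, window=21)   # window > grid


# ---------------------------------------------------------------------- osc
def _osc_oracle(X, y):
    """Literal transcription of the one-component Wold OSC procedure."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    xm = X.mean(axis=0)
    Xc = X - xm
    yc = y - y.mean()
    yn = yc / np.linalg.norm(yc)
    U, s, vt = np.linalg.svd(Xc, full_matrices=False)
    t = Xc @ vt[0]
    pinv = np.linalg.pinv(Xc)
    for _ in range(500):
        t_orth = t - yn * (yn @ t)
        w = pinv @ t_orth
        w = w / np.linalg.norm(w)
        t_new = Xc @ w
        if np.linalg.norm(t_new - np.sign(t_new @ t) * t) < 1e-12 * np.linalg.norm(t):
            t = t_new
            break
        t = t_new
    t = t - yn * (yn @ t)
    p = Xc.T @ t / (t @ t)
    return Xc - np.outer(t, p) + xm


def test_osc_identity_and_orthogonality(rng):
    X = rng.normal(size=(25, 9))
    y = rng.normal(size=25)
    X0, state0 = osc_fit(X, y, n_components=0)
    np.testing.assert_array_equal(X0, X)
    assert state0 is None
    _, state = osc_fit(X, y)
    assert abs(np.corrcoef(state.scores, y)[0, 1]) < 1e-6


def test_osc_matches_literal_wold_transcription(rng):
    X = rng.normal(size=(6, 4))
    y = rng.normal(size=6)
    got, _ = osc_fit(X, y)
    expected = _osc_oracle(X, y)
    np.testing.assert_allclose(got, expected, atol=1e-8)


# ------------------------------------------------------------- mean centering
def test_mean_centering_state_reuse(rng):
    cal = rng.normal(size=(8, 6))
    mean = mean_center_fit(cal)
    np.testing.assert_allclose(mean_center_apply(cal, mean).mean(axis=0), 0.0,
                               atol=1e-12)
    np.testing.assert_allclose(mean_center_apply(mean, mean), 0.0, atol=1e-12)
    new = rng.normal(size=(3, 6))
    np.testing.assert_allclose(mean_center_apply(new, mean), new - mean, rtol=1e-14)
    with pytest.raises(DomainError, match="mismatch"):
        mean_center_apply(rng.normal(size=(2, 5)), mean)


# -------------------------------------------------------------------- chains
def test_grid_has_420_unique_chains_ending_in_mncn():
    chains = enumerate_chains()
    labels = [c.label for c in chains]
    assert len(chains) == 420
    assert len(set(labels)) == 420
    assert all(lbl.endswith("|MNCN") for lbl in labels)


def test_chain_label_round_trip():
    for chain in enumerate_chains():
        assert PreprocessChain.from_label(chain.label) == chain
    assert PreprocessChain.from_label("Log|Detr|SG1D13|OSC|MNCN").sg == (1, 13)


def test_fast_grid_is_a_subset_of_the_full_grid():
    full = {c.label for c in enumerate_chains()}
    fast = [c.label for c in fast_chains()]
    assert len(fast) == 60
    assert set(fast) <= full


def test_apply_chain_mncn_only_is_column_centering(rng):
    X = rng.normal(size=(10, 7))
    chain = PreprocessChain()   # Raw|No|No|No|MNCN
    Xc, _, fitted = apply_chain(chain, X, None)
    np.testing.assert_allclose(Xc, X - X.mean(axis=0), rtol=1e-12)
    # a new spectrum equal to a calibration row is processed identically
    np.testing.assert_allclose(fitted.transform(X[3:4]), Xc[3:4], rtol=1e-12)


def test_apply_chain_matches_hand_composition(rng):
    T = np.abs(rng.normal(loc=1.0, scale=0.1, size=(12, 40))) + 0.2
    chain = PreprocessChain(step1="Log", step2="SNV", sg=(1, 13))
    Xc, _, _ = apply_chain(chain, T, None)
    manual = savgol_derivative(snv(log_transform(T)), order=1, window=13)
    manual = mean_center_apply(manual, mean_center_fit(manual))
    np.testing.assert_allclose(Xc, manual, atol=1e-10)


def test_chain_errors_carry_the_label():
    chain = PreprocessChain(step1="Log")
    with pytest.raises(DomainError, match=r"Log\|No\|No\|No\|MNCN"):
        chain.fit(np.array([[1.0, -1.0]]), None)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_no_leakage_validation_rows_processed_independently(seed):
    """Processing of one validation spectrum never depends on its neighbours."""
    rng = np.random.default_rng(seed)
    Xcal = np.abs(rng.normal(1.0, 0.1, size=(15, 25))) + 0.2
    y = rng.normal(size=15)
    Xval = np.abs(rng.normal(1.0, 0.1, size=(4, 25))) + 0.2
    chain = PreprocessChain(step1="Log", step2="MSC", sg=(2, 7), step4="OSC")
    _, Xv_all, fitted = apply_chain(chain, Xcal, y, Xval)
    alone = fitted.transform(Xval[2:3])
    np.testing.assert_allclose(alone, Xv_all[2:3], rtol=1e-10, atol=1e-12)
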