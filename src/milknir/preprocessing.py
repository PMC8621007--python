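"""Six-step spectral preprocessing chains and the full grid enumeration.

A chain is ``step1 | step2 | step3 | step4 | MNCN``:

1. ``Raw`` or ``Log`` (log10(1/T) transformation to absorbance);
2. ``No``, ``Base`` (offset baseline), ``Detr`` (2nd-order polynomial
   detrending), ``SNV`` or ``MSC`` scatter correction;
3. ``No`` or a Savitzky-Golay derivative ``SG{x}D{yy}`` of order x in {1,2}
   with a 2nd-order polynomial and odd window yy;
4. ``No`` or ``OSC`` (orthogonal signal correction, one component);
5. ``MNCN`` mean centering (always).

Trainable steps (MSC reference, OSC weights, centering mean) are estimated on
calibration data only and then applied unchanged to new spectra, so no
information leaks from a validation set into the model.

The grid is the Cartesian product 2 x 5 x (1 + 2*10) x 2 = 420 chains.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .errors import ConfigError, ConvergenceError, DomainError, NotFittedError

#: The ten odd Savitzky-Golay window lengths of the grid.
SG_WINDOWS = (3, 5, 7, 9, 11, 13, 15, 17, 19, 21)

STEP1 = ("Raw", "Log")
STEP2 = ("No", "Base", "Detr", "SNV", "MSC")
STEP4 = ("No", "OSC")


# ---------------------------------------------------------------------------
# individual operations
# ---------------------------------------------------------------------------

def log_transform(spectra: np.ndarray) -> np.ndarray:
    """Absorbance from transmittance/reflectance: A = log10(1/value)."""
    x = np.asarray(spectra, dtype=float)
    if np.any(x <= 0):
        i, j = np.argwhere(np.atleast_2d(x) <= 0)[0]
        raise DomainError(
            f"log transform requires positive values; first offender at "
            f"sample {i}, wavelength index {j}"
        )
    return -np.log10(x)


def baseline_correct(spectra: np.ndarray) -> np.ndarray:
    """Offset baseline: subtract each spectrum's minimum value."""
    x = np.atleast_2d(np.asarray(spectra, dtype=float))
    if x.shape[1] == 0:
        raise DomainError("empty spectra")
    out = x - x.min(axis=1, keepdims=True)
    return out if np.asarray(spectra).ndim > 1 else out[0]


def detrend(spectra: np.ndarray, wavelengths: np.ndarray | None = None) -> np.ndarray:
    """Subtract each spectrum's least-squares 2nd-order polynomial in wavelength."""
    x = np.atleast_2d(np.asarray(spectra, dtype=float))
    p = x.shape[1]
    if p < 3:
        raise DomainError("detrending needs at least 3 wavelengths")
    wl = np.arange(p, dtype=float) if wavelengths is None else np.asarray(wavelengths, float)
    # center/scale the abscissa for conditioning; projection is unaffected
    t = (wl - wl.mean()) / (wl.std() if wl.std() > 0 else 1.0)
    basis = np.vander(t, 3, increasing=True)           # (p, 3)
    q, _ = np.linalg.qr(basis)
    out = x - (x @ q) @ q.T
    return out if np.asarray(spectra).ndim > 1 else out[0]


def snv(spectra: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum (x - mean) / sample SD (n-1)."""
    x = np.atleast_2d(np.asarray(spectra, dtype=float))
    if x.shape[1] < 2:
        raise DomainError("SNV needs at least 2 wavelengths")
    sd = x.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise DomainError(
            f"SNV undefined for constant spectrum (row {int(np.argwhere(sd == 0)[0][0])})"
        )
    out = (x - x.mean(axis=1, keepdims=True)) / sd
    return out if np.asarray(spectra).ndim > 1 else out[0]


def msc_fit(calibration_spectra: np.ndarray) -> np.ndarray:
    """MSC reference spectrum = mean of the calibration spectra."""
    x = np.atleast_2d(np.asarray(calibration_spectra, dtype=float))
    if x.shape[0] < 2:
        raise DomainError("MSC reference needs at least 2 calibration spectra")
    return x.mean(axis=0)


def msc_apply(spectra: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Regress each spectrum on the reference (x ~ a*ref + b), return (x-b)/a."""
    x = np.atleast_2d(np.asarray(spectra, dtype=float))
    ref = np.asarray(reference, dtype=float)
    rc = ref - ref.mean()
    ss = rc @ rc
    if ss == 0:
        raise DomainError("MSC reference has zero variance")
    a = (x - x.mean(axis=1, keepdims=True)) @ rc / ss
    if np.any(a == 0):
        raise DomainError(
            f"MSC slope zero for sample row {int(np.argwhere(a == 0)[0][0])} "
            "(spectrum orthogonal to reference)"
        )
    b = x.mean(axis=1) - a * ref.mean()
    out = (x - b[:, None]) / a[:, None]
    return out if np.asarray(spectra).ndim > 1 else out[0]


@lru_cache(maxsize=128)
def _savgol_matrix(n: int, window: int, deriv: int) -> np.ndarray:
    """Dense (n, n) operator mapping a spectrum to its SG derivative.

    Interior points use the classic symmetric-window coefficients; points
    within half a window of an edge refit the quadratic on the truncated
    one-sided window.
    """
    half = window // 2
    mat = np.zeros((n, n))
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        t = np.arange(lo, hi, dtype=float) - i
        basis = np.vander(t, 3, increasing=True)       # columns 1, t, t^2
        pinv = np.linalg.pinv(basis)                   # (3, m)
        row = pinv[1] if deriv == 1 else 2.0 * pinv[2]
        mat[i, lo:hi] = row
    return mat


def savgol_derivative(spectra: np.ndarray, order: int, window: int,
                      poly: int = 2) -> np.ndarray:
    """Savitzky-Golay derivative (per index step) of each spectrum.

    ``order`` is the derivative order (1 or 2); the local fit is always a
    2nd-order polynomial.
    """
    if poly != 2:
        raise ConfigError("only the 2nd-order polynomial filter is supported")
    if order not in (1, 2):
        raise ConfigError(f"derivative order must be 1 or 2, got {order}")
    if window % 2 == 0 or window <= poly:
        raise ConfigError(f"window must be odd and > {poly}, got {window}")
    x = np.atleast_2d(np.asarray(spectra, dtype=float))
    n = x.shape[1]
    if window > n:
        raise ConfigError(f"window {window} exceeds the {n}-point grid")
    out = x @ _savgol_matrix(n, window, order).T
    return out if np.asarray(spectra).ndim > 1 else out[0]


@dataclass
class OSCState:
    """Fitted state of a one-component Wold orthogonal signal correction."""

    weight: np.ndarray       # (p,) spectral weight producing the score
    loading: np.ndarray      # (p,) loading removed by deflation
    x_mean: np.ndarray       # (p,) calibration column means
    scores: np.ndarray       # (n_cal,) fitted calibration scores
    n_iter: int


def osc_fit(X: np.ndarray, y: np.ndarray, n_components: int = 1,
            tol: float = 1e-10, max_iter: int = 500) -> tuple[np.ndarray, OSCState | None]:
    """Fit Wold-style OSC and return (deflated calibration X, state).

    With ``n_components=0`` this is the identity (state ``None``).  The single
    fitted component captures large spectral variance while its score is
    orthogonalized against the (centered) response, so the removed variation
    is by construction uncorrelated with the component of interest.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if n_components == 0:
        return X.copy(), None
    if n_components != 1:
        raise ConfigError("only one OSC component is supported")
    if np.std(y) == 0:
        raise DomainError("OSC requires a response with nonzero variance")

    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    yc = y - y.mean()
    yn = yc / np.linalg.norm(yc)

    # The iteration map t <- P_X (I - yn yn') t has eigenvalue 1 on the whole
    # subspace {t in col(X): t _|_ P_X yn} and decays only the component along
    # g = P_X yn, so its limit from the first principal score t0 is the
    # projection of t0 orthogonal to g.  Start there; the Wold loop then
    # certifies the fixed point within a couple of iterations.
    U, s, vt = np.linalg.svd(Xc, full_matrices=False)
    r = int((s > s[0] * 1e-12).sum()) if s.size and s[0] > 0 else 0
    if r == 0:
        raise DomainError("OSC on a zero matrix")
    Ur = U[:, :r]
    g = Ur @ (Ur.T @ yn)
    gg = g @ g
    t = None
    for j in range(r):
        cand = Ur[:, j] * s[j]
        if gg > 0:
            cand = cand - g * (g @ cand) / gg
        if np.linalg.norm(cand) > 1e-12 * s[0]:
            t = cand
            break
    if t is None:
        raise ConvergenceError("no spectral variance orthogonal to the response")
    w = vt[0]
    # rank-truncated pseudoinverse: keeps the iteration inside the numerically
    # determined column space instead of amplifying noise directions
    pinvX = (vt[:r].T / s[:r]) @ Ur.T
    for it in range(max_iter):
        t_orth = t - yn * (yn @ t)                      # orthogonalize vs response
        w_new = pinvX @ t_orth
        nw = np.linalg.norm(w_new)
        if nw == 0:
            raise ConvergenceError(f"OSC weight vector collapsed at iteration {it}")
        w_new /= nw
        if w_new @ w < 0:       # fix the sign indeterminacy of the direction
            w_new = -w_new
        t_new = Xc @ w_new
        # deflation depends only on the score direction, so convergence is
        # judged on the angle between successive scores; a norm-based check
        # would drown in round-trip error (~eps * condition number) on
        # ill-conditioned chains
        denom = np.linalg.norm(t_new) * np.linalg.norm(t)
        if denom > 0 and 1.0 - abs(t_new @ t) / denom <= tol:
            w, t = w_new, t_new
            break
        w, t = w_new, t_new
    else:
        raise ConvergenceError(f"OSC did not converge within {max_iter} iterations")
    # final exact orthogonalization defines the removed score
    t = t - yn * (yn @ t)
    tt = t @ t
    if tt == 0:
        raise ConvergenceError("OSC score vanished after orthogonalization")
    p_load = Xc.T @ t / tt
    X_deflated = Xc - np.outer(t, p_load) + x_mean
    state = OSCState(weight=w, loading=p_load, x_mean=x_mean, scores=t, n_iter=it + 1)
    return X_deflated, state


def osc_apply(X: np.ndarray, state: OSCState | None) -> np.ndarray:
    """Deflate new spectra with a fitted OSC state."""
    X = np.asarray(X, dtype=float)
    if state is None:
        return X.copy()
    Xc = X - state.x_mean
    t = Xc @ state.weight
    return Xc - np.outer(t, state.loading) + state.x_mean


def mean_center_fit(calibration_spectra: np.ndarray) -> np.ndarray:
    return np.atleast_2d(np.asarray(calibration_spectra, float)).mean(axis=0)


def mean_center_apply(spectra: np.ndarray, mean: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(spectra, dtype=float))
    mean = np.asarray(mean, dtype=float)
    if x.shape[1] != mean.size:
        raise DomainError(
            f"wavelength count mismatch: spectra have {x.shape[1]}, mean has {mean.size}"
        )
    out = x - mean
    return out if np.asarray(spectra).ndim > 1 else out[0]


# ---------------------------------------------------------------------------
# chains
# ---------------------------------------------------------------------------

_LABEL_RE = re.compile(
    r"^(Raw|Log)\|(No|Base|Detr|SNV|MSC)\|(No|SG([12])D(\d{2}))\|(No|OSC)\|MNCN$"
)


@dataclass(frozen=True)
class PreprocessChain:
    """Descriptor of one six-step preprocessing chain (unfitted)."""

    step1: str = "Raw"
    step2: str = "No"
    sg: tuple[int, int] | None = None   # (derivative order, window) or None
    step4: str = "No"

    def __post_init__(self) -> None:
        if self.step1 not in STEP1 or self.step2 not in STEP2 or self.step4 not in STEP4:
            raise ConfigError(f"invalid chain steps: {self}")
        if self.sg is not None:
            order, window = self.sg
            if order not in (1, 2) or window % 2 == 0 or window <= 2:
                raise ConfigError(f"invalid SG step {self.sg}")

    @property
    def label(self) -> str:
        sg = "No" if self.sg is None else f"SG{self.sg[0]}D{self.sg[1]:02d}"
        return f"{self.step1}|{self.step2}|{sg}|{self.step4}|MNCN"

    @property
    def uses_osc(self) -> bool:
        return self.step4 == "OSC"

    @classmethod
    def from_label(cls, label: str) -> "PreprocessChain":
        m = _LABEL_RE.match(label)
        if m is None:
            raise ConfigError(f"unparseable chain label {label!r}")
        sg = None if m.group(3) == "No" else (int(m.group(4)), int(m.group(5)))
        return cls(step1=m.group(1), step2=m.group(2), sg=sg, step4=m.group(6))

    def fit(self, X_cal: np.ndarray, y_cal: np.ndarray | None = None,
            wavelengths: np.ndarray | None = None) -> "FittedChain":
        """Estimate all trainable state on calibration data.

        Returns a :class:`FittedChain` whose ``X_cal_processed`` attribute is
        the chain output for the calibration spectra themselves.
        """
        if self.uses_osc and y_cal is None:
            raise ConfigError(f"chain {self.label}: OSC step requires y_cal")
        X = np.asarray(X_cal, dtype=float)
        try:
            X = self._stateless_head(X, wavelengths)
            state: dict = {}
            if self.step2 == "MSC":
                state["msc_ref"] = msc_fit(X)
                X = msc_apply(X, state["msc_ref"])
            X = self._sg_step(X)
            if self.step4 == "OSC":
                X, state["osc"] = osc_fit(X, np.asarray(y_cal, float))
            state["mean"] = mean_center_fit(X)
            X = mean_center_apply(X, state["mean"])
        except Exception as exc:
            raise type(exc)(f"chain {self.label}: {exc}") from exc
        return FittedChain(chain=self, state=state, wavelengths=wavelengths,
                           X_cal_processed=X)

    def _stateless_head(self, X: np.ndarray, wavelengths) -> np.ndarray:
        if self.step1 == "Log":
            X = log_transform(X)
        if self.step2 == "Base":
            X = baseline_correct(X)
        elif self.step2 == "Detr":
            X = detrend(X, wavelengths)
        elif self.step2 == "SNV":
            X = snv(X)
        return X

    def _sg_step(self, X: np.ndarray) -> np.ndarray:
        if self.sg is not None:
            X = savgol_derivative(X, order=self.sg[0], window=self.sg[1])
        return X


@dataclass
class FittedChain:
    """A chain plus its fitted state; applies identically to any new spectra."""

    chain: PreprocessChain
    state: dict
    wavelengths: np.ndarray | None
    X_cal_processed: np.ndarray = field(repr=False)

    @property
    def label(self) -> str:
        return self.chain.label

    def transform(self, X_new: np.ndarray) -> np.ndarray:
        if "mean" not in self.state:
            raise NotFittedError(f"chain {self.label} has no fitted state")
        X = np.atleast_2d(np.asarray(X_new, dtype=float))
        try:
            X = self.chain._stateless_head(X, self.wavelengths)
            if self.chain.step2 == "MSC":
                X = msc_apply(X, self.state["msc_ref"])
            X = self.chain._sg_step(X)
            if self.chain.step4 == "OSC":
                X = osc_apply(X, self.state["osc"])
            X = mean_center_apply(X, self.state["mean"])
        except Exception as exc:
            raise type(exc)(f"chain {self.label}: {exc}") from exc
        return X


def apply_chain(chain: PreprocessChain, X_cal: np.ndarray,
                y_cal: np.ndarray | None, X_new: np.ndarray | None = None,
                wavelengths: np.ndarray | None = None
                ) -> tuple[np.ndarray, np.ndarray | None, FittedChain]:
    """Fit a chain on calibration data and apply it to new spectra."""
    fitted = chain.fit(X_cal, y_cal, wavelengths=wavelengths)
    X_new_p = None if X_new is None else fitted.transform(X_new)
    return fitted.X_cal_processed, X_new_p, fitted


def enumerate_chains() -> list[PreprocessChain]:
    """The full preprocessing grid: 2 x 5 x 21 x 2 = 420 chains."""
    sg_options: list[tuple[int, int] | None] = [None] + [
        (order, window) for order in (1, 2) for window in SG_WINDOWS
    ]
    return [
        PreprocessChain(step1=s1, step2=s2, sg=sg, step4=s4)
        for s1, s2, sg, s4 in itertools.product(STEP1, STEP2, sg_options, STEP4)
    ]


def fast_chains() -> list[PreprocessChain]:
    """A reduced grid for quick runs: one SG window (11) at both orders.

    2 x 5 x 3 x 2 = 60 chains covering every step option at least once.
    """
    sg_options: list[tuple[int, int] | None] = [None, (1, 11), (2, 11)]
    return [
        PreprocessChain(step1=s1, step2=s2, sg=sg, step4=s4)
        for s1, s2, sg, s4 in itertools.product(STEP1, STEP2, sg_options, STEP4)
    ]
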