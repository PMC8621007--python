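"""Single-response partial least squares regression (PLS1, NIPALS form).

For one response the NIPALS factorization is non-iterative: each latent
variable takes the weight vector ``w_a = X_a' y_a`` (normalized), the score
``t_a = X_a w_a``, loading ``p_a = X_a' t_a / t_a't_a`` and response loading
``q_a = y_a't_a / t_a't_a``, then deflates ``X`` and ``y``.  Regression
coefficients for A components are ``b = W (P'W)^{-1} q``, and prediction is
affine in the (processed) spectrum: ``y_hat = y_mean + (x - x_mean) b``.

Variable importance in projection (VIP) scores are derived from the stored
weights and the response variance explained per component.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, RankError

_EPS = np.finfo(float).eps


@dataclass
class PLSRModel:
    """A fitted PLS1 model over the retained wavelengths."""

    n_latent: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray            # (p, A), columns unit norm
    loadings: np.ndarray           # (p, A)
    y_loadings: np.ndarray         # (A,)
    score_norms_sq: np.ndarray     # (A,) t_a' t_a
    coef: np.ndarray               # (p,) regression coefficients
    wavelength_mask: np.ndarray | None = None   # bool over the full grid
    chain_label: str = ""

    def to_dict(self) -> dict:
        return {
            "n_latent": int(self.n_latent),
            "x_mean": self.x_mean.tolist(),
            "y_mean": float(self.y_mean),
            "weights": self.weights.tolist(),
            "loadings": self.loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "score_norms_sq": self.score_norms_sq.tolist(),
            "coef": self.coef.tolist(),
            "wavelength_mask": None if self.wavelength_mask is None
            else np.asarray(self.wavelength_mask, bool).tolist(),
            "chain_label": self.chain_label,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "PLSRModel":
        return cls(
            n_latent=d["n_latent"],
            x_mean=np.array(d["x_mean"], float),
            y_mean=d["y_mean"],
            weights=np.array(d["weights"], float),
            loadings=np.array(d["loadings"], float),
            y_loadings=np.array(d["y_loadings"], float),
            score_norms_sq=np.array(d["score_norms_sq"], float),
            coef=np.array(d["coef"], float),
            wavelength_mask=None if d.get("wavelength_mask") is None
            else np.array(d["wavelength_mask"], bool),
            chain_label=d.get("chain_label", ""),
        )

    @classmethod
    def from_json(cls, s: str) -> "PLSRModel":
        return cls.from_dict(json.loads(s))


def _pls1_decompose(Xc: np.ndarray, yc: np.ndarray, a_max: int
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """NIPALS-PLS1 on centered data; stops early at rank exhaustion.

    Returns (W, P, q, tt, a_eff) with arrays truncated to the effective
    number of components extracted.
    """
    n, p = Xc.shape
    W = np.zeros((p, a_max))
    P = np.zeros((p, a_max))
    q = np.zeros(a_max)
    tt = np.zeros(a_max)
    Xd = Xc.copy()
    yd = yc.copy()
    scale = max(np.linalg.norm(Xc) * np.linalg.norm(yc), _EPS)
    a_eff = 0
    for a in range(a_max):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * scale:
            break
        w /= nw
        t = Xd @ w
        t_sq = t @ t
        if t_sq <= (1e-12 * max(np.linalg.norm(Xc), _EPS)) ** 2:
            break
        P[:, a] = Xd.T @ t / t_sq
        q[a] = yd @ t / t_sq
        W[:, a] = w
        tt[a] = t_sq
        Xd -= np.outer(t, P[:, a])
        yd = yd - q[a] * t
        a_eff += 1
    return W[:, :a_eff], P[:, :a_eff], q[:a_eff], tt[:a_eff], a_eff


def coefficient_path(X: np.ndarray, y: np.ndarray, a_max: int
                     ) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Regression coefficients for every component count 1..a_max at once.

    Returns ``(B, x_mean, y_mean, a_eff)`` where ``B[:, a-1]`` are the
    coefficients of the a-component model.  Counts beyond the effective rank
    repeat the last extractable model, so cross-validation over a fixed
    latent-count range stays well defined on low-rank data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, _, a_eff = _pls1_decompose(X - x_mean, y - y_mean, a_max)
    p = X.shape[1]
    B = np.zeros((p, a_max))
    for a in range(1, a_eff + 1):
        B[:, a - 1] = W[:, :a] @ np.linalg.solve(P[:, :a].T @ W[:, :a], q[:a])
    for a in range(a_eff, a_max):   # pad past rank exhaustion
        B[:, a] = B[:, a_eff - 1] if a_eff else 0.0
    return B, x_mean, y_mean, a_eff


def fit_plsr(X: np.ndarray, y: np.ndarray, n_latent: int,
             wavelength_mask: np.ndarray | None = None,
             chain_label: str = "") -> PLSRModel:
    """Fit a PLS1 model with exactly ``n_latent`` components."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise DomainError("X and y must be aligned (n_samples rows)")
    n, p = X.shape
    if n_latent < 1:
        raise DomainError(f"n_latent must be >= 1, got {n_latent}")
    if n_latent > min(n - 1, p):
        raise RankError(
            f"n_latent={n_latent} exceeds min(n_samples-1, n_wavelengths)={min(n - 1, p)}"
        )
    if np.std(y) == 0:
        raise DomainError("response has zero variance")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, tt, a_eff = _pls1_decompose(X - x_mean, y - y_mean, n_latent)
    if a_eff < n_latent:
        raise RankError(
            f"data supports only {a_eff} latent variables (requested {n_latent})"
        )
    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSRModel(
        n_latent=n_latent, x_mean=x_mean, y_mean=y_mean,
        weights=W, loadings=P, y_loadings=q, score_norms_sq=tt,
        coef=coef, wavelength_mask=wavelength_mask, chain_label=chain_label,
    )


def predict(model: PLSRModel, X_new: np.ndarray) -> np.ndarray:
    """Predict the response for new (already preprocessed) spectra."""
    X = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X.shape[1] != model.x_mean.size:
        raise DomainError(
            f"X_new has {X.shape[1]} columns, model expects {model.x_mean.size}"
        )
    out = model.y_mean + (X - model.x_mean) @ model.coef
    return out if np.asarray(X_new).ndim > 1 else float(out[0])


def vip_scores(model: PLSRModel) -> np.ndarray:
    """Variable importance in projection over the retained wavelengths.

    ``VIP_j = sqrt( p * sum_a SSY_a w_ja^2 / sum_a SSY_a )`` with unit-norm
    weight columns; the mean of the squared VIPs equals 1.
    """
    ssy = model.y_loadings**2 * model.score_norms_sq    # variance explained per LV
    total = ssy.sum()
    if total <= 0:
        raise DomainError("model explains no response variance; VIP undefined")
    p = model.weights.shape[0]
    return np.sqrt(p * (model.weights**2 @ ssy) / total)
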