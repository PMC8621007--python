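"""Cow-blocked cross-validation and statistically parsimonious model selection.

Three selections share one statistical rule: rank candidates by RMSECV and
take the most parsimonious one whose cross-validated absolute residuals are
not significantly worse than the best candidate's, judged by a one-sided
paired t-test (alpha = 0.05) pairing residuals by calibration sample.  The
rule is applied to the number of latent variables, to the preprocessing
chain, and (in :mod:`milknir.variable_selection`) to the wavelength-selection
method.

Cross-validation is group-wise with 10 folds of whole cows, so cow-specific
effects can never place the same animal on both sides of a fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DomainError
from .plsr import coefficient_path
from .preprocessing import PreprocessChain

__all__ = [
    "CVFolds", "CVResult", "SelectionConfig", "make_cv_folds",
    "cross_validate", "paired_worse_pvalue", "select_n_latent",
    "evaluate_grid", "select_chain", "GridRow",
]


@dataclass
class SelectionConfig:
    """Knobs of the parsimony selection procedure."""

    alpha: float = 0.05
    max_latent: int = 20
    k_folds: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.max_latent < 1 or self.k_folds < 2:
            raise ConfigError("max_latent must be >= 1 and k_folds >= 2")


@dataclass
class CVFolds:
    """Cow-blocked fold assignment: every cow's samples share one fold."""

    k: int
    fold_of_sample: np.ndarray   # (n_samples,) int fold index
    fold_of_cow: dict
    seed: int

    def indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = np.flatnonzero(self.fold_of_sample == fold)
        train = np.flatnonzero(self.fold_of_sample != fold)
        return train, test

    def cow_counts(self) -> list[int]:
        counts = [0] * self.k
        for f in self.fold_of_cow.values():
            counts[f] += 1
        return counts


def make_cv_folds(cow_ids, k: int = 10, seed: int = 0) -> CVFolds:
    """Shuffle cows deterministically and deal them round-robin into k folds."""
    cow_ids = np.asarray([str(c) for c in cow_ids])
    cows = sorted(set(cow_ids))
    if len(cows) < k:
        raise DomainError(f"need at least {k} cows for {k} folds, got {len(cows)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cows))
    fold_of_cow = {cows[j]: i % k for i, j in enumerate(order)}
    fold_of_sample = np.array([fold_of_cow[c] for c in cow_ids])
    return CVFolds(k=k, fold_of_sample=fold_of_sample, fold_of_cow=fold_of_cow, seed=seed)


@dataclass
class CVResult:
    """Out-of-fold predictions for every latent-variable count."""

    y: np.ndarray
    predictions: np.ndarray      # (n_samples, max_latent)
    rmsecv: np.ndarray           # (max_latent,)
    r2cv: np.ndarray             # (max_latent,)
    fold_of_sample: np.ndarray
    chain_label: str = ""
    max_effective_latent: int = 0

    def residuals(self, a: int) -> np.ndarray:
        """Signed out-of-fold residuals of the a-component model (a is 1-based)."""
        return self.y - self.predictions[:, a - 1]


def cross_validate(chain: PreprocessChain, X: np.ndarray, y: np.ndarray,
                   folds: CVFolds, max_latent: int = 20,
                   wavelengths: np.ndarray | None = None,
                   mask: np.ndarray | None = None) -> CVResult:
    """Cow-blocked CV of one preprocessing chain + PLSR latent-count path.

    All trainable state (MSC reference, OSC weights, centering means, PLSR
    factors) is re-estimated inside every fold from the training cows only.
    ``mask`` optionally restricts the PLSR to a wavelength subset *after*
    preprocessing, which is how wavelength selection is cross-validated.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    preds = np.full((n, max_latent), np.nan)
    a_eff_min = max_latent
    for f in range(folds.k):
        train, test = folds.indices(f)
        if test.size == 0:
            raise DomainError(f"fold {f} has no test samples")
        fitted = chain.fit(X[train], y[train], wavelengths=wavelengths)
        X_tr = fitted.X_cal_processed
        X_te = fitted.transform(X[test])
        if mask is not None:
            X_tr = X_tr[:, mask]
            X_te = X_te[:, mask]
        B, x_mean, y_mean, a_eff = coefficient_path(X_tr, y[train], max_latent)
        preds[test, :] = y_mean + (X_te - x_mean) @ B
        a_eff_min = min(a_eff_min, a_eff)
    resid = y[:, None] - preds
    rmsecv = np.sqrt((resid**2).mean(axis=0))
    sst = ((y - y.mean()) ** 2).sum()
    r2cv = 1.0 - (resid**2).sum(axis=0) / sst
    return CVResult(
        y=y, predictions=preds, rmsecv=rmsecv, r2cv=r2cv,
        fold_of_sample=folds.fold_of_sample.copy(),
        chain_label=chain.label, max_effective_latent=a_eff_min,
    )


def paired_worse_pvalue(abs_residuals: np.ndarray, abs_residuals_best: np.ndarray) -> float:
    """One-sided paired t-test p-value for 'candidate is worse than best'.

    Small p means the candidate's absolute residuals are significantly
    *greater* than the best model's.  Degenerate difference vectors (all
    zeros) are treated as 'not worse' (p = 1).
    """
    d = np.asarray(abs_residuals, float) - np.asarray(abs_residuals_best, float)
    if d.size < 2:
        return 1.0
    if np.ptp(d) == 0:   # constant difference: direction decides outright
        return 1.0 if d[0] <= 0 else 0.0
    res = stats.ttest_rel(abs_residuals, abs_residuals_best, alternative="greater")
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def select_n_latent(cv: CVResult, cfg: SelectionConfig | None = None) -> int:
    """Smallest latent count not significantly worse than the RMSECV optimum."""
    cfg = cfg or SelectionConfig()
    a_star = int(np.argmin(cv.rmsecv)) + 1
    abs_best = np.abs(cv.residuals(a_star))
    for a in range(1, a_star + 1):
        if a == a_star:
            return a_star
        if paired_worse_pvalue(np.abs(cv.residuals(a)), abs_best) > cfg.alpha:
            return a
    return a_star  # pragma: no cover - loop always returns


@dataclass
class GridRow:
    """One evaluated preprocessing chain in the ranked grid."""

    chain: PreprocessChain
    cv: CVResult = field(repr=False)
    n_latent: int = 0
    rmsecv: float = np.nan
    p_vs_best: float = np.nan

    @property
    def label(self) -> str:
        return self.chain.label

    @property
    def n_latent_total(self) -> int:
        """Model complexity including the OSC component when present.

        The parsimony comparisons use ``n_latent`` (the OSC component is not
        counted); reports record the total as well.
        """
        return self.n_latent + (1 if self.chain.uses_osc else 0)


def evaluate_grid(chains, X: np.ndarray, y: np.ndarray, folds: CVFolds,
                  cfg: SelectionConfig | None = None,
                  wavelengths: np.ndarray | None = None,
                  on_chain=None) -> list[GridRow]:
    """Cross-validate every chain and select its latent count.

    Chains are evaluated in deterministic label order.  ``on_chain`` is an
    optional callback ``(label, n_latent, rmsecv)`` for progress logging.
    """
    cfg = cfg or SelectionConfig()
    rows = []
    for chain in sorted(chains, key=lambda c: c.label):
        cv = cross_validate(chain, X, y, folds, max_latent=cfg.max_latent,
                            wavelengths=wavelengths)
        a = select_n_latent(cv, cfg)
        row = GridRow(chain=chain, cv=cv, n_latent=a,
                      rmsecv=float(cv.rmsecv[a - 1]))
        rows.append(row)
        if on_chain is not None:
            on_chain(row.label, row.n_latent, row.rmsecv)
    return rows


def select_chain(rows: list[GridRow], cfg: SelectionConfig | None = None) -> GridRow:
    """Parsimony pick among evaluated chains.

    Candidates are the chains whose absolute residuals (at their own selected
    latent count) are not significantly worse than the global RMSECV
    minimizer's; among them the fewest latent variables wins, with ties broken
    by lowest RMSECV and then lexicographic chain label.  Fills ``p_vs_best``
    on every row as a side effect.
    """
    if not rows:
        raise DomainError("no evaluated chains to select from")
    cfg = cfg or SelectionConfig()
    best = min(rows, key=lambda r: (r.rmsecv, r.label))
    abs_best = np.abs(best.cv.residuals(best.n_latent))
    candidates = []
    for row in rows:
        row.p_vs_best = paired_worse_pvalue(
            np.abs(row.cv.residuals(row.n_latent)), abs_best
        )
        if row.p_vs_best > cfg.alpha or row is best:
            candidates.append(row)
    return min(candidates, key=lambda r: (r.n_latent, r.rmsecv, r.label))


def grid_frame(rows: list[GridRow]) -> pd.DataFrame:
    """Machine-readable ranked grid (ascending RMSECV)."""
    frame = pd.DataFrame({
        "chain": [r.label for r in rows],
        "n_latent": [r.n_latent for r in rows],
        "n_latent_total": [r.n_latent_total for r in rows],
        "rmsecv": [r.rmsecv for r in rows],
        "r2cv": [float(r.cv.r2cv[r.n_latent - 1]) for r in rows],
        "p_vs_best": [r.p_vs_best for r in rows],
    })
    return frame.sort_values(["rmsecv", "chain"], kind="mergesort").reset_index(drop=True)
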