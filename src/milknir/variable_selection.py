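"""Wavelength selection: VIP, jack-knife, reversed and forward interval PLS.

All four selectors operate on the chain-processed calibration spectra and are
judged by the same cow-blocked cross-validation as the rest of the pipeline;
the final pick among the four subsets and the full-spectrum model reuses the
parsimony rule (one-sided paired t-test on absolute residuals), with
parsimony measured as the number of retained wavelengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DomainError
from .model_selection import (CVFolds, CVResult, SelectionConfig,
                              cross_validate, paired_worse_pvalue,
                              select_n_latent)
from .plsr import fit_plsr, vip_scores
from .preprocessing import PreprocessChain

__all__ = [
    "VariableSelectionConfig", "WavelengthSubset", "vip_select",
    "jackknife_select", "ripls", "fipls", "choose_selection",
    "make_intervals", "selection_frame",
]


@dataclass
class VariableSelectionConfig(SelectionConfig):
    """Selection knobs plus the selector-specific defaults.

    ``vip_threshold`` 1.0 is the greater-than-average-importance rule;
    ``n_intervals`` 20 splits the grid into contiguous interval-PLS blocks
    (the last interval absorbs the remainder).
    """

    vip_threshold: float = 1.0
    n_intervals: int = 20


@dataclass
class WavelengthSubset:
    """A retained wavelength set with its cross-validated performance."""

    method: str                       # VIP | JK | RiPLS | FiPLS | FULL
    mask: np.ndarray                  # bool over the processed grid
    cv: CVResult = field(repr=False)
    n_latent: int = 0
    rmsecv: float = np.nan
    diagnostics: dict = field(default_factory=dict)
    p_vs_best: float = np.nan

    @property
    def n_retained(self) -> int:
        return int(np.asarray(self.mask, bool).sum())

    def retained_spans(self, wavelengths: np.ndarray) -> list[tuple[float, float]]:
        """Contiguous nm ranges covered by the retained wavelengths."""
        idx = np.flatnonzero(self.mask)
        if idx.size == 0:
            return []
        spans = []
        start = prev = idx[0]
        for i in idx[1:]:
            if i != prev + 1:
                spans.append((float(wavelengths[start]), float(wavelengths[prev])))
                start = i
            prev = i
        spans.append((float(wavelengths[start]), float(wavelengths[prev])))
        return spans


def _cv_subset(method: str, mask: np.ndarray, chain: PreprocessChain,
               X: np.ndarray, y: np.ndarray, folds: CVFolds,
               cfg: SelectionConfig, wavelengths, diagnostics: dict | None = None
               ) -> WavelengthSubset:
    mask = np.asarray(mask, bool)
    cv = cross_validate(chain, X, y, folds, max_latent=cfg.max_latent,
                        wavelengths=wavelengths, mask=mask)
    a = select_n_latent(cv, cfg)
    return WavelengthSubset(method=method, mask=mask, cv=cv, n_latent=a,
                            rmsecv=float(cv.rmsecv[a - 1]),
                            diagnostics=diagnostics or {})


def full_spectrum(chain: PreprocessChain, X: np.ndarray, y: np.ndarray,
                  folds: CVFolds, cfg: VariableSelectionConfig | None = None,
                  wavelengths=None) -> WavelengthSubset:
    """The all-wavelengths reference model."""
    cfg = cfg or VariableSelectionConfig()
    mask = np.ones(X.shape[1], dtype=bool)
    return _cv_subset("FULL", mask, chain, X, y, folds, cfg, wavelengths)


def _fallback_top1(scores: np.ndarray, method: str) -> np.ndarray:
    warnings.warn(f"{method}: no wavelength passed the criterion; "
                  "falling back to the single best wavelength")
    mask = np.zeros(scores.size, dtype=bool)
    mask[int(np.argmax(scores))] = True
    return mask


def vip_select(chain: PreprocessChain, X: np.ndarray, y: np.ndarray,
               folds: CVFolds, cfg: VariableSelectionConfig | None = None,
               wavelengths=None, n_latent: int | None = None) -> WavelengthSubset:
    """Retain wavelengths with VIP >= threshold in the full-spectrum model."""
    cfg = cfg or VariableSelectionConfig()
    if n_latent is None:
        n_latent = select_n_latent(
            cross_validate(chain, X, y, folds, cfg.max_latent, wavelengths), cfg
        )
    fitted = chain.fit(X, y, wavelengths=wavelengths)
    model = fit_plsr(fitted.X_cal_processed, y, n_latent, chain_label=chain.label)
    vip = vip_scores(model)
    mask = vip >= cfg.vip_threshold
    if not mask.any():
        mask = _fallback_top1(vip, "VIP")
    return _cv_subset("VIP", mask, chain, X, y, folds, cfg, wavelengths,
                      diagnostics={"vip": vip, "threshold": cfg.vip_threshold,
                                   "n_latent_full": n_latent})


def jackknife_select(chain: PreprocessChain, X: np.ndarray, y: np.ndarray,
                     folds: CVFolds, cfg: VariableSelectionConfig | None = None,
                     wavelengths=None, n_latent: int | None = None) -> WavelengthSubset:
    """Martens-style jack-knife uncertainty test on the PLSR coefficients.

    The coefficient variance is estimated from the variation of the k
    segment models around the full-calibration model; wavelengths whose
    coefficient differs from zero at alpha are retained.
    """
    cfg = cfg or VariableSelectionConfig()
    if n_latent is None:
        n_latent = select_n_latent(
            cross_validate(chain, X, y, folds, cfg.max_latent, wavelengths), cfg
        )
    fitted = chain.fit(X, y, wavelengths=wavelengths)
    model = fit_plsr(fitted.X_cal_processed, y, n_latent, chain_label=chain.label)
    b_full = model.coef
    k = folds.k
    B = np.zeros((k, b_full.size))
    for f in range(k):
        train, _ = folds.indices(f)
        sub = chain.fit(X[train], y[train], wavelengths=wavelengths)
        B[f] = fit_plsr(sub.X_cal_processed, y[train], n_latent).coef
    s2 = ((B - b_full) ** 2).sum(axis=0) * (k - 1) / k
    se = np.sqrt(s2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(b_full) / se
    pvals = 2.0 * stats.t.sf(t, df=k - 1)
    # degenerate variance: identical coefficients across segments count as
    # significant whenever the coefficient itself is nonzero
    pvals = np.where(se == 0, np.where(b_full != 0, 0.0, 1.0), pvals)
    mask = pvals <= cfg.alpha
    if not mask.any():
        mask = _fallback_top1(-pvals, "JK")
    return _cv_subset("JK", mask, chain, X, y, folds, cfg, wavelengths,
                      diagnostics={"t": t, "p": pvals, "n_latent_full": n_latent})


def make_intervals(n_wavelengths: int, n_intervals: int) -> list[np.ndarray]:
    """Contiguous equal intervals; the last absorbs the remainder."""
    if n_intervals < 1 or n_intervals > n_wavelengths:
        raise ConfigError(
            f"n_intervals must be in [1, {n_wavelengths}], got {n_intervals}"
        )
    size = n_wavelengths // n_intervals
    bounds = [i * size for i in range(n_intervals)] + [n_wavelengths]
    return [np.arange(bounds[i], bounds[i + 1]) for i in range(n_intervals)]


def _interval_mask(intervals, active: set, n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for i in sorted(active):
        mask[intervals[i]] = True
    return mask


def _ipls_greedy(reverse: bool, chain: PreprocessChain, X, y, folds,
                 cfg: VariableSelectionConfig, wavelengths) -> WavelengthSubset:
    n = X.shape[1]
    intervals = make_intervals(n, min(cfg.n_intervals, n))
    n_int = len(intervals)
    method = "RiPLS" if reverse else "FiPLS"

    def evaluate(active: set) -> WavelengthSubset:
        return _cv_subset(method, _interval_mask(intervals, active, n),
                          chain, X, y, folds, cfg, wavelengths)

    if reverse:
        active = set(range(n_int))
        current = evaluate(active)
        while len(active) > 1:
            best_cand, best_idx = None, None
            for i in sorted(active):
                cand = evaluate(active - {i})
                if best_cand is None or cand.rmsecv < best_cand.rmsecv:
                    best_cand, best_idx = cand, i
            if best_cand.rmsecv < current.rmsecv:
                active.discard(best_idx)
                current = best_cand
            else:
                break
    else:
        active: set = set()
        current = None
        while len(active) < n_int:
            best_cand, best_idx = None, None
            for i in range(n_int):
                if i in active:
                    continue
                cand = evaluate(active | {i})
                if best_cand is None or cand.rmsecv < best_cand.rmsecv:
                    best_cand, best_idx = cand, i
            if current is None or best_cand.rmsecv < current.rmsecv:
                active.add(best_idx)
                current = best_cand
            else:
                break
    current.diagnostics = {"intervals": [iv.tolist() for iv in intervals],
                           "active": sorted(active)}
    return current


def ripls(chain: PreprocessChain, X, y, folds,
          cfg: VariableSelectionConfig | None = None, wavelengths=None,
          n_latent: int | None = None) -> WavelengthSubset:
    """Reversed interval PLS: greedily drop the interval whose removal most
    lowers RMSECV; stop when no removal improves.

    Each candidate interval set is cross-validated with its own latent-count
    selection, so ``n_latent`` (the full-spectrum choice) is accepted for
    interface symmetry but unused.
    """
    return _ipls_greedy(True, chain, X, y, folds, cfg or VariableSelectionConfig(),
                        wavelengths)


def fipls(chain: PreprocessChain, X, y, folds,
          cfg: VariableSelectionConfig | None = None, wavelengths=None,
          n_latent: int | None = None) -> WavelengthSubset:
    """Forward interval PLS: greedily add the interval that most lowers
    RMSECV; stop when no addition improves."""
    return _ipls_greedy(False, chain, X, y, folds, cfg or VariableSelectionConfig(),
                        wavelengths)


def choose_selection(candidates: list[WavelengthSubset],
                     cfg: SelectionConfig | None = None) -> WavelengthSubset:
    """Parsimony pick among wavelength subsets (and the FULL model).

    Candidate set: subsets not significantly worse than the lowest-RMSECV
    one; among them, fewest retained wavelengths wins; ties go to fewer
    latent variables, then lower RMSECV, then method name.
    """
    if not candidates:
        raise DomainError("no wavelength-selection candidates")
    cfg = cfg or SelectionConfig()
    best = min(candidates, key=lambda s: (s.rmsecv, s.method))
    abs_best = np.abs(best.cv.residuals(best.n_latent))
    eligible = []
    for cand in candidates:
        cand.p_vs_best = paired_worse_pvalue(
            np.abs(cand.cv.residuals(cand.n_latent)), abs_best
        )
        if cand.p_vs_best > cfg.alpha or cand is best:
            eligible.append(cand)
    return min(eligible, key=lambda s: (s.n_retained, s.n_latent, s.rmsecv, s.method))


def selection_frame(candidates: list[WavelengthSubset],
                    wavelengths: np.ndarray) -> pd.DataFrame:
    """Report table: method, retained count, nm spans, latent count, RMSECV."""
    rows = []
    for c in candidates:
        spans = c.retained_spans(np.asarray(wavelengths, float))
        rows.append({
            "method": c.method,
            "n_retained": c.n_retained,
            "spans_nm": "; ".join(f"{lo:g}-{hi:g}" for lo, hi in spans),
            "n_latent": c.n_latent,
            "rmsecv": c.rmsecv,
            "p_vs_best": c.p_vs_best,
        })
    return pd.DataFrame(rows)
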