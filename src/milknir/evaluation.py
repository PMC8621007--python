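"""Final-model evaluation: RMSE/R2, Williams classes, ICAR limits, and the
cross-spectrometer comparison (blocked two-way ANOVA + Tukey HSD with a
compact letter display).

ICAR (International Committee for Animal Recording) publishes RMSEP limits
for milk analyzers: 0.25 % w/w in-line, 0.20 % w/w at-line and 0.10 % w/w
laboratory, identical for fat, protein and lactose.  Williams' determination
coefficient bands grade a calibration as approximate-quantitative
(0.66-0.81), good (0.82-0.90) or excellent (>0.91).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError

__all__ = [
    "rmse", "r_squared", "williams_class", "IcarThresholds", "icar_check",
    "EvalResult", "evaluate_predictions", "ComparisonResult",
    "compare_spectrometers",
]


def rmse(residuals) -> float:
    """Root mean squared error: sqrt(mean(residual^2))."""
    r = np.asarray(residuals, dtype=float).ravel()
    if r.size == 0:
        raise DomainError("RMSE of an empty residual vector is undefined")
    return float(np.sqrt(np.mean(r**2)))


def r_squared(y_ref, y_pred) -> float:
    """Determination coefficient 1 - SSE/SST (SST about the mean of y_ref)."""
    y_ref = np.asarray(y_ref, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_ref.size != y_pred.size or y_ref.size == 0:
        raise DomainError("y_ref and y_pred must be non-empty and aligned")
    sst = float(((y_ref - y_ref.mean()) ** 2).sum())
    if sst == 0:
        raise DomainError("reference values have zero variance; R^2 undefined")
    sse = float(((y_ref - y_pred) ** 2).sum())
    return 1.0 - sse / sst


def williams_class(r2: float) -> str:
    """Williams prediction-quality band for a determination coefficient.

    Bands below 0.66 are 'insufficient'.  The printed bands leave the gaps
    0.81-0.82 and 0.90-0.91 unassigned; the lower band is extended upward, so
    e.g. r2 = 0.905 is 'good'.
    """
    if r2 > 1:
        raise DomainError(f"R^2 cannot exceed 1, got {r2}")
    if r2 > 0.91:
        return "excellent"
    if r2 >= 0.82:
        return "good"
    if r2 >= 0.66:
        return "approximate_quantitative"
    return "insufficient"


@dataclass(frozen=True)
class IcarThresholds:
    """RMSEP limits (% w/w) for the three ICAR analyzer levels."""

    in_line: float = 0.25
    at_line: float = 0.20
    laboratory: float = 0.10

    def __post_init__(self) -> None:
        if not self.laboratory < self.at_line < self.in_line:
            raise DomainError("expected laboratory < at_line < in_line limits")


def icar_check(rmsep: float, thresholds: IcarThresholds | None = None) -> dict[str, bool]:
    """Compliance flags per ICAR level: pass iff RMSEP <= limit."""
    if rmsep < 0:
        raise DomainError("RMSEP cannot be negative")
    t = thresholds or IcarThresholds()
    return {
        "in_line": rmsep <= t.in_line,
        "at_line": rmsep <= t.at_line,
        "laboratory": rmsep <= t.laboratory,
    }


@dataclass
class EvalResult:
    """Validation-set performance of one final model."""

    component: str
    spectrometer: str
    y_val: np.ndarray
    y_val_pred: np.ndarray
    rmsep: float
    r2p: float
    rmsecv: float
    r2cv: float
    williams_cv: str = ""
    williams_p: str = ""
    icar: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "spectrometer": self.spectrometer, "component": self.component,
            "rmsecv": self.rmsecv, "rmsep": self.rmsep,
            "r2cv": self.r2cv, "r2p": self.r2p,
            "williams_cv": self.williams_cv, "williams_p": self.williams_p,
            **{f"icar_{k}": v for k, v in self.icar.items()},
        }


def evaluate_predictions(component: str, spectrometer: str,
                         y_val, y_val_pred, rmsecv: float, r2cv: float,
                         thresholds: IcarThresholds | None = None) -> EvalResult:
    """Bundle validation predictions into an :class:`EvalResult`."""
    y_val = np.asarray(y_val, float).ravel()
    y_val_pred = np.asarray(y_val_pred, float).ravel()
    rp = rmse(y_val - y_val_pred)
    r2p = r_squared(y_val, y_val_pred)
    return EvalResult(
        component=component, spectrometer=spectrometer,
        y_val=y_val, y_val_pred=y_val_pred,
        rmsep=rp, r2p=r2p, rmsecv=float(rmsecv), r2cv=float(r2cv),
        williams_cv=williams_class(r2cv), williams_p=williams_class(r2p),
        icar=icar_check(rp, thresholds),
    )


# ---------------------------------------------------------------------------
# blocked two-way ANOVA + Tukey HSD
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    """Cross-spectrometer comparison on squared residuals."""

    anova: pd.DataFrame            # rows: spectrometer, sample, error
    spectrometer_p: float
    tukey: pd.DataFrame            # pairwise adjusted p-values
    letters: dict[str, str]        # compact letter display per spectrometer
    group_means: pd.Series

    @property
    def significant(self) -> bool:
        return bool(self.spectrometer_p <= self.alpha)

    alpha: float = 0.05


def _compact_letters(groups_by_mean: list[str], sig: set[frozenset]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``groups_by_mean`` is ordered best (lowest mean) first; two groups share a
    letter iff they are not significantly different.
    """
    sets: list[set] = [set(groups_by_mean)]
    for pair in sig:
        a, b = tuple(pair)
        for s in list(sets):
            if a in s and b in s:
                sets.remove(s)
                for drop in (a, b):
                    new = s - {drop}
                    if new and not any(new <= other for other in sets):
                        sets.append(new)
    # absorb: drop letter sets fully contained in another
    sets = [s for s in sets if not any(s < other for other in sets)]
    # order letters by the best group they contain
    rank = {g: i for i, g in enumerate(groups_by_mean)}
    sets.sort(key=lambda s: min(rank[g] for g in s))
    letters = {g: "" for g in groups_by_mean}
    for i, s in enumerate(sets):
        ch = chr(ord("a") + i)
        for g in groups_by_mean:
            if g in s:
                letters[g] += ch
    return letters


def compare_spectrometers(squared_residuals, alpha: float = 0.05,
                          labels=None) -> ComparisonResult:
    """Blocked two-way ANOVA + Tukey HSD on per-sample squared residuals.

    ``squared_residuals`` is a complete samples-by-spectrometers matrix (or a
    DataFrame with spectrometer columns): every sample must carry a residual
    for every spectrometer.  The sample term enters as a block effect, which
    for this balanced complete design gives the same F-test for the
    spectrometer factor as the paired/repeated-measures analysis.  Tukey's HSD
    uses the ANOVA error mean square; compact letters are assigned from the
    best (lowest mean squared residual) spectrometer onward.
    """
    if isinstance(squared_residuals, pd.DataFrame):
        labels = list(squared_residuals.columns)
        M = squared_residuals.to_numpy(float)
    else:
        M = np.asarray(squared_residuals, dtype=float)
        if labels is None:
            labels = [f"S{j}" for j in range(M.shape[1])]
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise DomainError("need a (n_samples >= 2) x (k >= 2) residual matrix")
    if not np.all(np.isfinite(M)):
        raise DomainError("missing or non-finite cells; the design must be complete")

    n, k = M.shape
    grand = M.mean()
    col_means = M.mean(axis=0)
    row_means = M.mean(axis=1)
    ss_spec = n * ((col_means - grand) ** 2).sum()
    ss_sample = k * ((row_means - grand) ** 2).sum()
    ss_total = ((M - grand) ** 2).sum()
    ss_err = ss_total - ss_spec - ss_sample
    df_spec, df_sample = k - 1, n - 1
    df_err = df_spec * df_sample
    # guard the degenerate scale: sums of squares that are pure floating-point
    # residue (e.g. identical columns) are treated as exact zeros
    tiny = 1e-12 * max(ss_total, 1e-300)
    ss_spec = 0.0 if ss_spec < tiny else ss_spec
    ss_err = 0.0 if ss_err < tiny else ss_err
    ms_spec = ss_spec / df_spec
    ms_sample = ss_sample / df_sample
    ms_err = ss_err / df_err

    def _f_and_p(ms_effect, df_effect):
        if ms_err > 0:
            f = ms_effect / ms_err
            return f, float(stats.f.sf(f, df_effect, df_err))
        return (np.inf, 0.0) if ms_effect > 0 else (0.0, 1.0)

    f_spec, p_spec = _f_and_p(ms_spec, df_spec)
    f_sample, p_sample = _f_and_p(ms_sample, df_sample)
    anova = pd.DataFrame(
        {
            "ss": [ss_spec, ss_sample, ss_err],
            "df": [df_spec, df_sample, df_err],
            "ms": [ms_spec, ms_sample, ms_err],
            "F": [f_spec, f_sample, np.nan],
            "p": [p_spec, p_sample, np.nan],
        },
        index=["spectrometer", "sample", "error"],
    )

    se = np.sqrt(ms_err / n) if ms_err > 0 else 0.0
    pairs = []
    sig: set[frozenset] = set()
    for i, j in itertools.combinations(range(k), 2):
        diff = abs(col_means[i] - col_means[j])
        if se > 0:
            q = diff / se
            p_adj = float(stats.studentized_range.sf(q, k, df_err))
        else:
            p_adj = 0.0 if diff > 0 else 1.0
        pairs.append({"a": labels[i], "b": labels[j],
                      "mean_diff": col_means[i] - col_means[j], "p_adj": p_adj})
        # pairwise differences only count once the omnibus test is significant
        if p_spec <= alpha and p_adj <= alpha:
            sig.add(frozenset((labels[i], labels[j])))
    order = [labels[j] for j in np.argsort(col_means, kind="stable")]
    letters = _compact_letters(order, sig)
    return ComparisonResult(
        anova=anova, spectrometer_p=p_spec,
        tukey=pd.DataFrame(pairs), letters=letters,
        group_means=pd.Series(col_means, index=labels), alpha=alpha,
    )
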