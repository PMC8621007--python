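"""Cow-blocked duplex partitioning into calibration and validation sets.

The duplex algorithm (Snee-style) alternately assigns the points farthest
from each growing set, yielding two subsets with similar coverage of the
composition space.  Here it operates on *cow-level* points — each cow is
represented by the mean of its autoscaled sample compositions — so that all
samples of one animal land in the same set and cow-specific effects cannot
leak from calibration into validation.

The target sizes follow the 2:1 convention: ``n_val = floor(n_cows / 3)``
and the remainder goes to calibration (71 cows -> 48 calibration,
23 validation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import COMPONENTS, CompositionTable
from .errors import DomainError


def autoscale(comp: CompositionTable) -> np.ndarray:
    """Center each component column to mean 0 and scale to (sample) SD 1."""
    x = comp.values()
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = COMPONENTS[int(np.argwhere(sd == 0)[0][0])]
        raise DomainError(f"cannot autoscale: component {bad!r} has zero variance")
    return (x - x.mean(axis=0)) / sd


@dataclass
class SplitResult:
    """Outcome of a cow-blocked duplex split."""

    calibration_sample_ids: np.ndarray
    validation_sample_ids: np.ndarray
    calibration_cows: np.ndarray
    validation_cows: np.ndarray
    stats: pd.DataFrame   # per set x component: mean, sd, min, max

    def assignment_frame(self) -> pd.DataFrame:
        """Two-column (sample_id, set) frame, calibration rows first."""
        return pd.DataFrame({
            "sample_id": np.concatenate(
                [self.calibration_sample_ids, self.validation_sample_ids]
            ),
            "set": ["cal"] * len(self.calibration_sample_ids)
            + ["val"] * len(self.validation_sample_ids),
        })


def _set_stats(comp: CompositionTable, ids, label: str) -> list[dict]:
    sub = comp.subset(ids).values()
    rows = []
    for j, name in enumerate(COMPONENTS):
        rows.append({
            "set": label, "component": name,
            "mean": sub[:, j].mean(), "sd": sub[:, j].std(ddof=1),
            "min": sub[:, j].min(), "max": sub[:, j].max(),
            "n": sub.shape[0],
        })
    return rows


def _farthest_pair(dist: np.ndarray, remaining: list[int]) -> tuple[int, int]:
    """Indices of the farthest pair among ``remaining``; ties by lowest indices."""
    best = (-np.inf, None)
    for ai, a in enumerate(remaining):
        for b in remaining[ai + 1:]:
            d = dist[a, b]
            if d > best[0]:
                best = (d, (a, b))
    return best[1]


def _farthest_from_set(dist: np.ndarray, remaining: list[int], members: list[int]) -> int:
    """Remaining point maximizing its min-distance to ``members``; ties by index."""
    best = (-np.inf, None)
    for a in remaining:
        d = dist[a, members].min()
        if d > best[0]:
            best = (d, a)
    return best[1]


def duplex_split(comp: CompositionTable, cow_ids) -> SplitResult:
    """Cow-blocked duplex split of samples into calibration and validation.

    Parameters
    ----------
    comp : CompositionTable
        Per-sample reference compositions (rows aligned with ``cow_ids``).
    cow_ids : sequence
        Per-sample cow identifier.
    """
    cow_ids = np.asarray(cow_ids)
    if len(cow_ids) != len(comp.sample_ids):
        raise DomainError("cow_ids must align with the composition table rows")
    cows = np.array(sorted(set(map(str, cow_ids))))
    n = len(cows)
    if n < 3:
        raise DomainError(f"duplex split needs at least 3 cows, got {n}")

    scaled = autoscale(comp)
    cow_points = np.vstack([
        scaled[np.asarray([str(c) for c in cow_ids]) == cow].mean(axis=0)
        for cow in cows
    ])
    diff = cow_points[:, None, :] - cow_points[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))

    n_val = n // 3
    n_cal = n - n_val
    remaining = list(range(n))
    cal: list[int] = []
    val: list[int] = []

    # seed each set with the farthest remaining pair (validation only if its
    # target size allows a pair)
    a, b = _farthest_pair(dist, remaining)
    cal += [a, b]
    remaining.remove(a)
    remaining.remove(b)
    if n_val >= 2 and remaining:
        a, b = _farthest_pair(dist, remaining)
        val += [a, b]
        remaining.remove(a)
        remaining.remove(b)

    # repeating 2:1 rounds, each assignment taking the point farthest from the
    # receiving set; a set that reached its target size is skipped
    pattern = ("cal", "cal", "val")
    step = 0
    while remaining:
        target = pattern[step % 3]
        step += 1
        if target == "cal" and len(cal) >= n_cal:
            continue
        if target == "val" and len(val) >= n_val:
            continue
        members = cal if target == "cal" else val
        if not members:   # degenerate: seed with the overall farthest point
            pick = _farthest_from_set(dist, remaining, cal + val)
        else:
            pick = _farthest_from_set(dist, remaining, members)
        members.append(pick)
        remaining.remove(pick)

    cal_cows = cows[sorted(cal)]
    val_cows = cows[sorted(val)]
    cow_str = np.asarray([str(c) for c in cow_ids])
    cal_mask = np.isin(cow_str, cal_cows)
    sample_ids = np.asarray(comp.sample_ids)
    stats = pd.DataFrame(
        _set_stats(comp, sample_ids, "all")
        + _set_stats(comp, sample_ids[cal_mask], "cal")
        + _set_stats(comp, sample_ids[~cal_mask], "val")
    )
    return SplitResult(
        calibration_sample_ids=sample_ids[cal_mask],
        validation_sample_ids=sample_ids[~cal_mask],
        calibration_cows=cal_cows,
        validation_cows=val_cows,
        stats=stats,
    )
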