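"""Alpha/beta diversity over time and longitudinal group comparison.

Alpha diversity is the Shannon index in nats; beta diversity is
Bray–Curtis dissimilarity. Longitudinal trajectories of two response
groups are compared with a permutation spline test: one local-linear
(tricube-weighted, span 0.75) smoother per group over the shared week
range, the test statistic being the mean absolute gap between the two
smoothers on an evenly spaced grid, with significance from permutations
that exchange whole patients between groups (respecting repeated
measures).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis, pdist
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "shannon",
    "bray_curtis",
    "group_dispersion",
    "DiversitySeries",
    "permuspline_test",
    "SplineTestResult",
]

_GRID_POINTS = 50
_SPAN = 0.75


def shannon(p) -> float:
    """Shannon diversity H = -sum q ln q of a non-negative vector (nats)."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("abundances must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("cannot compute Shannon index of an all-zero vector")
    q = p[p > 0] / total
    return float(-(q * np.log(q)).sum())


def bray_curtis(p, q) -> float:
    """Bray–Curtis dissimilarity 1 - 2 sum(min) / (sum p + sum q)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    if p.sum() <= 0 or q.sum() <= 0:
        raise ValueError("each vector must have positive total abundance")
    return float(braycurtis(p, q))


@dataclass
class DiversitySeries:
    """Per-(group, timepoint) collection of diversity values."""

    group: str
    week: int
    values: np.ndarray
    warning: str | None = None


def group_dispersion(
    abundance: pd.DataFrame,
    meta: pd.DataFrame,
    group: str,
    timepoint: str,
) -> DiversitySeries:
    """All within-group pairwise Bray–Curtis values at one visit."""
    sel = meta[(meta["response"] == group) & (meta["timepoint"] == timepoint)]
    week = int(sel["week"].iloc[0]) if len(sel) else -1
    if len(sel) < 2:
        return DiversitySeries(
            group=group,
            week=week,
            values=np.empty(0),
            warning=f"fewer than 2 samples for ({group}, {timepoint})",
        )
    mat = abundance.loc[sel.index].to_numpy(dtype=float)
    return DiversitySeries(group=group, week=week, values=pdist(mat, metric="braycurtis"))


@dataclass
class SplineTestResult:
    statistic: float
    p_value: float
    grid: np.ndarray
    smooth_a: np.ndarray
    smooth_b: np.ndarray


def _smooth(weeks, values, grid) -> np.ndarray:
    out = lowess(values, weeks, frac=_SPAN, xvals=grid)
    # lowess can return NaN off the data hull for tiny inputs; clamp by
    # nearest finite neighbour
    if np.isnan(out).any():
        idx = np.arange(len(out))
        finite = ~np.isnan(out)
        out = np.interp(idx, idx[finite], out[finite])
    return out


def permuspline_test(
    series_a: pd.DataFrame,
    series_b: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = 0,
) -> SplineTestResult:
    """Permutation spline test between two longitudinal groups.

    Each series is a DataFrame with columns ``week``, ``value`` and
    ``patient_id``. Group labels are permuted at the patient level; the
    p-value uses the add-one convention so it is always in (0, 1].
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    for name, s in (("A", series_a), ("B", series_b)):
        if s["week"].nunique() < 3:
            raise ValueError(f"group {name} needs observations at >= 3 distinct weeks")
    lo = max(series_a["week"].min(), series_b["week"].min())
    hi = min(series_a["week"].max(), series_b["week"].max())
    if lo >= hi:
        raise ValueError("no overlapping week range between groups")
    grid = np.linspace(lo, hi, _GRID_POINTS)

    pooled = pd.concat(
        [series_a.assign(_grp=0), series_b.assign(_grp=1)], ignore_index=True
    )
    weeks = pooled["week"].to_numpy(dtype=float)
    values = pooled["value"].to_numpy(dtype=float)
    grp = pooled["_grp"].to_numpy()
    # exchangeable unit: a patient within its group (IDs may repeat
    # across the two inputs without collapsing the units)
    patients = np.array(
        [f"{g}:{p}" for g, p in zip(grp, pooled["patient_id"].to_numpy())]
    )
    uniq_patients, first_idx = np.unique(patients, return_index=True)
    patient_grp = grp[first_idx]
    n_a_patients = int((patient_grp == 0).sum())

    def statistic(mask_a: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        sa = _smooth(weeks[mask_a], values[mask_a], grid)
        sb = _smooth(weeks[~mask_a], values[~mask_a], grid)
        return float(np.mean(np.abs(sa - sb))), sa, sb

    obs, sm_a, sm_b = statistic(grp == 0)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(uniq_patients))
        a_patients = set(uniq_patients[perm[:n_a_patients]])
        mask = np.fromiter((p in a_patients for p in patients), bool, len(patients))
        if mask.all() or not mask.any():
            continue
        stat, _, _ = statistic(mask)
        if stat >= obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return SplineTestResult(statistic=obs, p_value=p, grid=grid, smooth_a=sm_a, smooth_b=sm_b)


def alpha_series(abundance: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-sample Shannon index joined with group/week annotations."""
    vals = [shannon(row) for row in abundance.to_numpy(dtype=float)]
    return pd.DataFrame(
        {
            "value": vals,
            "week": meta.loc[abundance.index, "week"].to_numpy(),
            "timepoint": meta.loc[abundance.index, "timepoint"].to_numpy(),
            "response": meta.loc[abundance.index, "response"].to_numpy(),
            "patient_id": meta.loc[abundance.index, "patient_id"].to_numpy(),
        },
        index=abundance.index,
    )
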