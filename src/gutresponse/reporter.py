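"""Signed, background-corrected reporter scores for KO pathways.

Per KO, a two-sided Wilcoxon rank-sum test (normal approximation with
tie correction) compares relative abundance between a "better" and a
"worse" response group at one visit; the KO's z-score is the normal
quantile of its p-value signed toward the better group. A pathway with
member scores z_1..z_k aggregates them as Z = sum(z)/sqrt(k), and the
reporter score is the background-corrected (Z - mu_k)/sigma_k where
mu_k, sigma_k come from Monte-Carlo draws of k random KOs out of all
scored KOs. A positive reporter score therefore means enrichment in the
better response group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import PathwayMap

__all__ = [
    "CONTRASTS",
    "ko_differential",
    "rank_sum_z",
    "reporter_score",
    "significance_threshold",
    "score_consistency",
    "run_reporter",
]

#: Pairwise group contrasts, first member the better-response group.
CONTRASTS = (("PR", "SD"), ("PR", "PD"), ("SD", "PD"))

_Z_CAP = 8.0
_SIGMA_FLOOR = 1e-8


def significance_threshold(alpha: float) -> float:
    """Two-sided normal z cutoff for a given alpha (1.96 at 0.05)."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return float(stats.norm.ppf(1 - alpha / 2))


def rank_sum_z(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided Wilcoxon rank-sum over columns.

    ``a`` (n1 x m) and ``b`` (n2 x m) hold the two groups' values for m
    features. Returns ``(p, u)``: two-sided normal-approximation
    p-values with tie correction, and the Mann-Whitney U of group a.
    """
    n1, n2 = a.shape[0], b.shape[0]
    both = np.vstack([a, b]).astype(float)
    ranks = stats.rankdata(both, axis=0)
    r1 = ranks[:n1].sum(axis=0)
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    # tie correction: sum over tie groups of (t^3 - t) per column
    sorted_vals = np.sort(both, axis=0)
    tie_term = np.zeros(both.shape[1])
    for j in range(both.shape[1]):
        _, counts = np.unique(sorted_vals[:, j], return_counts=True)
        tie_term[j] = (counts**3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sd = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (u - mu) / sd
    z[sd == 0] = 0.0  # constant column across both groups
    p = 2 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return p, u


@dataclass
class KOTestResult:
    ko_id: str
    p: float
    direction: int
    z: float


def ko_differential(
    ko_abundance: pd.DataFrame,
    meta: pd.DataFrame,
    better_group: str,
    worse_group: str,
    timepoint: str | None = None,
) -> list[KOTestResult]:
    """Per-KO rank-sum scores between two response groups at one visit.

    Direction is the sign of (median in better - median in worse), with
    +1 on an exact zero difference; z = Phi^-1(1 - p/2) * direction,
    capped at +/-8. A KO constant across both groups gets p=1, z=0.
    """
    sel = meta.loc[ko_abundance.index]
    if timepoint is not None:
        sel = sel[sel["timepoint"] == timepoint]
    a_idx = sel.index[sel["response"] == better_group]
    b_idx = sel.index[sel["response"] == worse_group]
    if len(a_idx) < 3 or len(b_idx) < 3:
        raise ValueError(
            f"need >= 3 samples per group at {timepoint!r}: "
            f"{better_group}={len(a_idx)}, {worse_group}={len(b_idx)}"
        )
    a = ko_abundance.loc[a_idx].to_numpy(dtype=float)
    b = ko_abundance.loc[b_idx].to_numpy(dtype=float)
    p, _ = rank_sum_z(a, b)
    diff = np.median(a, axis=0) - np.median(b, axis=0)
    direction = np.where(diff >= 0, 1, -1)
    z = np.clip(stats.norm.ppf(1 - p / 2), 0.0, _Z_CAP) * direction
    constant = (a.std(axis=0) == 0) & (b.std(axis=0) == 0) & (diff == 0)
    z[constant] = 0.0
    p = p.copy()
    p[constant] = 1.0
    return [
        KOTestResult(ko_id=k, p=float(p[j]), direction=int(direction[j]), z=float(z[j]))
        for j, k in enumerate(ko_abundance.columns)
    ]


def reporter_score(
    ko_results: list[KOTestResult],
    pathway_map: PathwayMap,
    n_background: int = 1000,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Background-corrected reporter score per pathway.

    mu_k and sigma_k are estimated from ``n_background`` draws of k KOs
    without replacement from all scored KOs (shared across pathways of
    equal size). Pathways with no scored KO are dropped. sigma_k is
    floored so a degenerate all-zero background yields score 0.
    """
    if n_background < 100:
        raise ValueError("n_background must be >= 100")
    z_by_ko = {r.ko_id: r.z for r in ko_results}
    all_z = np.array(list(z_by_ko.values()), dtype=float)
    rng = np.random.default_rng(seed)

    scored: dict[str, np.ndarray] = {}
    for pid in sorted(pathway_map.members):
        zs = np.array([z_by_ko[k] for k in sorted(pathway_map[pid]) if k in z_by_ko])
        if zs.size:
            scored[pid] = zs

    # one background table per distinct k, in sorted-k order for
    # reproducibility independent of pathway naming
    background: dict[int, tuple[float, float]] = {}
    for k in sorted({v.size for v in scored.values()}):
        if k >= all_z.size:
            draws = np.full(n_background, all_z.sum() / np.sqrt(k))
        else:
            # k-subsets without replacement via the k smallest of random keys
            keys = rng.random((n_background, all_z.size))
            idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
            draws = all_z[idx].sum(axis=1) / np.sqrt(k)
        background[k] = (float(draws.mean()), float(draws.std()))

    rows = []
    for pid, zs in scored.items():
        k = zs.size
        raw = float(zs.sum() / np.sqrt(k))
        mu, sigma = background[k]
        corrected = 0.0 if sigma < _SIGMA_FLOOR else (raw - mu) / sigma
        rows.append(
            {
                "pathway_id": pid,
                "k": k,
                "raw_z": raw,
                "corrected_z": corrected,
                "significant_05": abs(corrected) > significance_threshold(0.05),
                "significant_01": abs(corrected) > significance_threshold(0.01),
            }
        )
    return pd.DataFrame(rows).set_index("pathway_id")


def score_consistency(scores_t: pd.Series, scores_ref: pd.Series) -> float:
    """Spearman rank correlation of reporter scores across shared pathways."""
    shared = scores_t.index.intersection(scores_ref.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared pathways")
    rho, _ = stats.spearmanr(scores_t.loc[shared], scores_ref.loc[shared])
    return float(rho)


def run_reporter(
    ko_abundance: pd.DataFrame,
    meta: pd.DataFrame,
    pathway_map: PathwayMap,
    *,
    timepoints: list[str] | None = None,
    n_background: int = 1000,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reporter table over all contrasts and visits plus M0 consistency.

    Returns ``(long_table, consistency)``: the long-format per-pathway
    table and, per (contrast, later visit), the Spearman rho of its
    corrected-z vector against baseline M0.
    """
    sel = meta.loc[ko_abundance.index]
    if timepoints is None:
        timepoints = list(dict.fromkeys(sel.sort_values("week")["timepoint"]))
    long_rows = []
    vectors: dict[tuple[str, str], pd.Series] = {}
    for tp in timepoints:
        for better, worse in CONTRASTS:
            try:
                kores = ko_differential(ko_abundance, meta, better, worse, timepoint=tp)
            except ValueError:
                continue
            table = reporter_score(kores, pathway_map, n_background=n_background, seed=seed)
            vectors[(f"{better}-{worse}", tp)] = table["corrected_z"]
            t = table.reset_index()
            t.insert(0, "timepoint", tp)
            t.insert(0, "contrast", f"{better}-{worse}")
            long_rows.append(t)
    long_table = (
        pd.concat(long_rows, ignore_index=True) if long_rows else pd.DataFrame()
    )
    cons_rows = []
    for (contrast, tp), vec in vectors.items():
        ref = vectors.get((contrast, timepoints[0]))
        if tp == timepoints[0] or ref is None:
            continue
        cons_rows.append(
            {
                "contrast": contrast,
                "timepoint": tp,
                "rho": score_consistency(vec, ref),
            }
        )
    consistency = pd.DataFrame(cons_rows)
    return long_table, consistency
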