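"""BMI-adjusted differential abundance testing of metagenomic species.

Per MGS, a BMI-adjusted one-way ANOVA across the PR/SD/PD response
groups: the p-value is the extra-sum-of-squares F test of
``value ~ group + bmi`` against ``value ~ bmi``. Pairwise contrasts of
significant MGSs use Tukey's HSD (studentized range, Tukey–Kramer for
unequal group sizes), and each significant MGS is labelled with the
response group of highest ("+") and lowest ("-") median abundance,
unless its occurrence is too low to call a direction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GROUP_ORDER

__all__ = [
    "bmi_adjusted_anova",
    "tukey_hsd",
    "enrichment_label",
    "log_transform",
    "run_differential",
]

PAIRS = (("PR", "SD"), ("PR", "PD"), ("SD", "PD"))


def _design(groups: np.ndarray, bmi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Full (intercept + group dummies + bmi) and reduced (intercept + bmi)."""
    levels = sorted(set(groups))
    n = len(groups)
    cols = [np.ones(n)]
    for lv in levels[1:]:
        cols.append((groups == lv).astype(float))
    cols.append(bmi)
    X1 = np.column_stack(cols)
    X0 = np.column_stack([np.ones(n), bmi])
    return X1, X0


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares per column of Y under OLS on X."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return (resid**2).sum(axis=0)


def anova_pvalues(
    Y: np.ndarray,
    groups: np.ndarray,
    bmi: np.ndarray,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorized BMI-adjusted ANOVA over the columns of Y.

    Returns one extra-sum-of-squares F-test p-value per column; columns
    that are (numerically) constant come back as NaN. Optional
    ``weights`` fit by weighted least squares (used when rows are
    per-patient means of unequal numbers of samples, where the row
    variance scales as 1/n).
    """
    groups = np.asarray(groups)
    bmi = np.asarray(bmi, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    levels, counts = np.unique(groups, return_counts=True)
    if len(levels) < 2 or (counts < 3).any():
        raise ValueError("need >= 2 groups with >= 3 samples each")
    if not np.isfinite(bmi).all():
        raise ValueError("bmi must be finite")
    X1, X0 = _design(groups, bmi)
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))[:, None]
        Y = Y * w
        X1 = X1 * w
        X0 = X0 * w
    df_diff = len(levels) - 1
    df_res = len(groups) - X1.shape[1]
    if df_res <= 0:
        warnings.warn("zero residual degrees of freedom; returning NaN", stacklevel=2)
        return np.full(Y.shape[1], np.nan)
    rss1 = _rss(X1, Y)
    rss0 = _rss(X0, Y)
    scale = (Y**2).sum(axis=0) + 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        F = ((rss0 - rss1) / df_diff) / (rss1 / df_res)
        p = stats.f.sf(F, df_diff, df_res)
    constant = Y.var(axis=0) <= 1e-24 * scale
    p[constant | ~np.isfinite(F)] = np.nan
    return p


def bmi_adjusted_anova(values, groups, bmi) -> float:
    """BMI-adjusted ANOVA p-value for a single feature (NaN if degenerate)."""
    return float(anova_pvalues(np.asarray(values, dtype=float), groups, bmi)[0])


def tukey_hsd(values, groups) -> dict[tuple[str, str], float]:
    """Tukey HSD pairwise p-values, keyed by group pair (order-free).

    Groups with a single sample make their pairs NaN; all groups
    entering the test need at least 2 samples.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(set(groups))
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    by_level = {lv: values[groups == lv] for lv in levels}
    ok = [lv for lv in levels if len(by_level[lv]) >= 2]
    out: dict[tuple[str, str], float] = {}
    pmat = None
    if len(ok) >= 2:
        res = stats.tukey_hsd(*(by_level[lv] for lv in ok))
        pmat = res.pvalue
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            if a in ok and b in ok and pmat is not None:
                p = float(pmat[ok.index(a), ok.index(b)])
            else:
                p = float("nan")
            out[(a, b)] = p
            out[(b, a)] = p
    return out


def enrichment_label(
    median_abund: dict[str, float],
    occurrence: dict[str, float],
    min_occurrence: float = 0.2,
) -> tuple[str | None, str | None]:
    """Label the groups with highest and lowest median abundance.

    Returns ``(None, None)`` when no group reaches ``min_occurrence``
    (occurrence too low to define an enrichment direction). Median ties
    break toward higher occurrence, then by the fixed preference order
    PR > SD > PD.
    """
    groups = [g for g in GROUP_ORDER if g in median_abund]
    if not groups:
        raise ValueError("no recognised response groups")
    if max(occurrence.get(g, 0.0) for g in groups) < min_occurrence:
        return None, None
    rank = {g: i for i, g in enumerate(GROUP_ORDER)}
    high = min(
        groups, key=lambda g: (-median_abund[g], -occurrence.get(g, 0.0), rank[g])
    )
    low = min(
        (g for g in groups if g != high),
        key=lambda g: (median_abund[g], -occurrence.get(g, 0.0), rank[g]),
    )
    return high, low


def log_transform(abundance: pd.DataFrame) -> pd.DataFrame:
    """log10(x + eps) with eps = half the smallest nonzero matrix value."""
    vals = abundance.to_numpy(dtype=float)
    nonzero = vals[vals > 0]
    if nonzero.size == 0:
        raise ValueError("abundance matrix is all zeros")
    eps = nonzero.min() / 2.0
    return pd.DataFrame(
        np.log10(vals + eps), index=abundance.index, columns=abundance.columns
    )


def run_differential(
    abundance: pd.DataFrame,
    meta: pd.DataFrame,
    *,
    alpha: float = 0.05,
    use_q: bool = False,
    min_occurrence: float = 0.2,
    timepoint: str | None = None,
    per_patient: bool = True,
) -> pd.DataFrame:
    """Differential table over all MGSs of a validated cohort.

    Fast-death samples are dropped; by default samples from all visits
    are pooled into one transformed-abundance mean per patient before
    testing — BMI and the response group are patient covariates, so
    patient aggregation avoids pseudo-replicating them across repeated
    visits (``per_patient=False`` tests individual samples; a per-visit
    mode is available via ``timepoint``). Benjamini–Hochberg q-values
    are computed over every tested MGS; "significant" means raw
    ``anova_p < alpha`` unless ``use_q``. Tukey contrasts and
    enrichment labels are filled for significant MGSs.
    """
    if abundance.shape[0] == 0 or abundance.shape[1] == 0:
        raise ValueError("empty abundance matrix")
    keep = meta.loc[abundance.index]
    keep = keep[keep["response"].isin(GROUP_ORDER)]
    if timepoint is not None:
        keep = keep[keep["timepoint"] == timepoint]
    sub = abundance.loc[keep.index]

    logged = log_transform(sub)
    weights = None
    if per_patient:
        pat = keep["patient_id"].to_numpy()
        logged = logged.groupby(pat).mean()
        sub = sub.groupby(pat).mean()
        # patient means over n visits have residual variance ~ sigma^2/n
        weights = pd.Series(pat).value_counts().loc[logged.index].to_numpy(dtype=float)
        keep = keep.drop_duplicates("patient_id").set_index("patient_id").loc[logged.index]
    groups = keep["response"].to_numpy()
    bmi = keep["bmi"].to_numpy(dtype=float)
    pvals = anova_pvalues(logged.to_numpy(), groups, bmi, weights=weights)

    qvals = np.full_like(pvals, np.nan)
    tested = np.isfinite(pvals)
    if tested.any():
        qvals[tested] = multipletests(pvals[tested], method="fdr_bh")[1]

    raw = sub.to_numpy(dtype=float)
    group_masks = {g: groups == g for g in GROUP_ORDER}
    occ = {
        g: (raw[m] > 0).mean(axis=0) if m.any() else np.zeros(raw.shape[1])
        for g, m in group_masks.items()
    }
    med = {
        g: np.median(raw[m], axis=0) if m.any() else np.full(raw.shape[1], np.nan)
        for g, m in group_masks.items()
    }

    crit = qvals if use_q else pvals
    table_rows = []
    for j, mgs in enumerate(sub.columns):
        row: dict[str, object] = {
            "mgs_id": mgs,
            "anova_p": pvals[j],
            "bh_q": qvals[j],
            "significant": bool(np.isfinite(crit[j]) and crit[j] < alpha),
        }
        for g in GROUP_ORDER:
            row[f"occurrence_{g}"] = occ[g][j]
            row[f"median_{g}"] = med[g][j]
        for a, b in PAIRS:
            row[f"tukey_{a}_{b}"] = np.nan
        row["enrich_high"] = None
        row["enrich_low"] = None
        if row["significant"]:
            tk = tukey_hsd(logged.iloc[:, j].to_numpy(), groups)
            for a, b in PAIRS:
                row[f"tukey_{a}_{b}"] = tk.get((a, b), np.nan)
            hi, lo = enrichment_label(
                {g: med[g][j] for g in GROUP_ORDER if group_masks[g].any()},
                {g: occ[g][j] for g in GROUP_ORDER if group_masks[g].any()},
                min_occurrence,
            )
            row["enrich_high"], row["enrich_low"] = hi, lo
        table_rows.append(row)
    table = pd.DataFrame(table_rows).set_index("mgs_id")
    return table.sort_values(["bh_q", "anova_p"], na_position="last")
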