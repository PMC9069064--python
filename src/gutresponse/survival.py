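"""Progression-free survival: responder labels, KM curves, log-rank tests.

Responders are patients whose PFS exceeds a cutoff (strictly beyond 3
months by default); a patient censored before the cutoff cannot be
called either way and is labelled missing. Curves are product-limit
(Kaplan-Meier) estimates via lifelines, with events preceding
censorings at tied times; two-group comparison is the standard 1-df
log-rank chi-square. Strata builders cover antibiotics exposure, the
TMB > 5.6 mutations/Mb cut, HLA-E high/low and the four-way
TMB x HLA-E combination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

__all__ = [
    "cohort_summary",
    "classify_responders",
    "km_estimate",
    "logrank",
    "SurvivalCurve",
    "build_strata",
    "patient_survival",
]

TMB_CUTOFF = 5.6
PFS_CUTOFF_MONTHS = 3.0


def cohort_summary(counts) -> pd.DataFrame:
    """Counts and integer-rounded percentages per category.

    ``counts`` maps category label -> patient count (e.g. response
    groups, or R/NR). Percentages are of the total, rounded to whole
    percent as a clinical summary table reports them.
    """
    counts = dict(counts)
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("counts must sum to a positive total")
    return pd.DataFrame(
        {
            "n": pd.Series(counts),
            "percent": pd.Series(
                {k: int(round(100.0 * v / total)) for k, v in counts.items()}
            ),
        }
    )


def classify_responders(
    pfs_months,
    events=None,
    cutoff: float = PFS_CUTOFF_MONTHS,
) -> np.ndarray:
    """Dichotomize PFS into responders (R) / non-responders (NR).

    R iff PFS is strictly beyond the cutoff. Subjects censored at or
    before the cutoff (event flag False) are undeterminable and
    labelled None. With no event flags everything is treated as
    observed.
    """
    pfs = np.asarray(pfs_months, dtype=float)
    if (pfs <= 0).any():
        raise ValueError("pfs_months must be > 0")
    if events is None:
        events = np.ones(len(pfs), dtype=bool)
    events = np.asarray(events, dtype=bool)
    out = np.where(pfs > cutoff, "R", "NR").astype(object)
    out[(~events) & (pfs <= cutoff)] = None
    return out


@dataclass
class SurvivalCurve:
    """Product-limit estimate: step times, survival, risk set, censor marks."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier curve (events before censorings at tied times)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if (times <= 0).any():
        raise ValueError("times must be > 0")
    kmf = KaplanMeierFitter().fit(times, event_observed=events)
    sf = kmf.survival_function_
    grid = sf.index.to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    return SurvivalCurve(
        times=grid,
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        at_risk=at_risk,
        censor_times=np.sort(times[~events]),
    )


def logrank(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(levels)}")
    for lv in levels:
        if not events[groups == lv].any():
            raise ValueError(f"group {lv!r} has no events")
    m = groups == levels[0]
    res = logrank_test(times[m], times[~m], events[m], events[~m])
    return float(res.test_statistic), float(res.p_value)


def patient_survival(meta: pd.DataFrame) -> pd.DataFrame:
    """One PFS record per patient from per-sample metadata."""
    per = meta.drop_duplicates("patient_id").set_index("patient_id")
    return per[["response", "atb", "bmi", "tmb", "hla_e", "pfs_months", "pfs_event"]]


def build_strata(patients: pd.DataFrame) -> dict[str, pd.Series]:
    """Named stratifications of a per-patient table.

    Returns label series keyed by stratification name: antibiotics
    yes/no, TMB above/below 5.6, HLA-E high/low, and the four-way
    TMB x HLA-E combination.
    """
    atb = patients["atb"].map({True: "ATB", False: "no ATB"})
    tmb = np.where(patients["tmb"] > TMB_CUTOFF, "TMB>5.6", "TMB<=5.6")
    hla = patients["hla_e"].map({"high": "HLA-E high", "low": "HLA-E low"})
    combo = pd.Series(tmb, index=patients.index) + " / " + hla
    return {
        "atb": atb,
        "tmb": pd.Series(tmb, index=patients.index),
        "hla_e": hla,
        "tmb_x_hla_e": combo,
    }
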