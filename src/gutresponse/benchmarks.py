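"""End-to-end benchmark experiments on synthetic cohorts.

Each function regenerates its input cohorts from a seed, runs one
pipeline stage at the study-scale conditions (effect sizes and planted
counts matching the emulated design) and measures a recovery or
calibration quantity:

- type-I error of the BMI-adjusted ANOVA and of reporter-score
  significance on null cohorts,
- sensitivity/false-discovery proportion of the differential-MGS stage
  on cohorts with 30 planted species at effect 1.5,
- detection rate of pathways whose 10 member KOs are shifted at
  effect 1.0,
- held-out one-vs-rest AUCs of the two-tiered classifier on strong
  (effect 2.0, 20 informative features) and null cohorts,
- model-order recovery of the Dirichlet-multinomial mixture.

Cohort sizes are scaled so that a full battery runs on a laptop in
minutes; all randomness flows from the ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .differential import run_differential
from .enterotype import select_k
from .io import validate_cohort
from .predictor import TieredResponseClassifier, roc_auc
from .reporter import ko_differential, reporter_score, significance_threshold
from .synthetic import CohortConfig, generate_cohort

__all__ = [
    "null_calibration",
    "differential_recovery",
    "reporter_planted_detection",
    "predictor_benchmark",
    "dmm_k_recovery",
    "simulate_dm_mixture",
]


def null_calibration(
    seed: int = 0,
    n_anova_seeds: int = 5,
    n_reporter_seeds: int = 10,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of ANOVA p-values and reporter scores on null cohorts.

    Returns observed significance rates at ``alpha`` together with the
    number of tests behind each rate.
    """
    pvals = []
    for s in range(n_anova_seeds):
        bundle = generate_cohort(
            CohortConfig.null(seed=seed * 1009 + s, n_mgs=300, n_ko=60,
                              n_pathways=5, n_differential_pathways=1)
        )
        val = validate_cohort(bundle.mgs_abundance, bundle.meta, exclude_atb=True)
        table = run_differential(val.abundance, val.meta)
        pvals.append(table["anova_p"].dropna().to_numpy())
    pvals = np.concatenate(pvals)

    cutoff = significance_threshold(alpha)
    flags = []
    for s in range(n_reporter_seeds):
        bundle = generate_cohort(
            CohortConfig.null(seed=seed * 2003 + s, n_mgs=300, n_ko=500,
                              n_pathways=50, n_differential_pathways=1)
        )
        val = validate_cohort(bundle.ko_abundance, bundle.meta, exclude_atb=True)
        kores = ko_differential(val.abundance, val.meta, "PR", "PD", timepoint="M0")
        table = reporter_score(kores, bundle.pathway_map, n_background=1000,
                               seed=seed * 2003 + s)
        flags.append(np.abs(table["corrected_z"].to_numpy()) > cutoff)
    flags = np.concatenate(flags)

    return {
        "anova_rate": float((pvals < alpha).mean()),
        "n_anova": int(len(pvals)),
        "reporter_rate": float(flags.mean()),
        "n_reporter": int(len(flags)),
    }


def differential_recovery(
    seed: int = 11,
    n_seeds: int = 5,
    n_mgs: int = 1500,
    n_planted: int = 30,
    effect: float = 1.5,
) -> dict:
    """Planted-truth recovery of the differential-MGS stage at q < 0.05."""
    sens, fdp = [], []
    for s in range(n_seeds):
        cfg = CohortConfig(seed=seed + s, n_mgs=n_mgs, n_differential_mgs=n_planted,
                           mgs_effect_size=effect, n_ko=60, n_pathways=5,
                           n_differential_pathways=1)
        bundle = generate_cohort(cfg)
        val = validate_cohort(bundle.mgs_abundance, bundle.meta, exclude_atb=True)
        table = run_differential(val.abundance, val.meta, use_q=True)
        truth = set(bundle.truth.differential_mgs)
        found = set(table.index[table["significant"]])
        sens.append(len(found & truth) / len(truth))
        fdp.append(len(found - truth) / max(len(found), 1))
    return {
        "sensitivity": float(np.mean(sens)),
        "fdr": float(np.mean(fdp)),
        "per_seed_sensitivity": sens,
        "per_seed_fdp": fdp,
        "n_seeds": n_seeds,
    }


def reporter_planted_detection(
    seed: int = 0,
    n_seeds: int = 100,
    pathway_size: int = 10,
    effect: float = 1.0,
) -> dict:
    """Fraction of planted pathways scoring above the 5% threshold.

    Each cohort plants pathways whose ``pathway_size`` member KOs are
    shifted toward the PR group at the given effect; detection means
    corrected_z > 1.96 for the PR-vs-PD contrast at baseline.
    """
    cutoff = significance_threshold(0.05)
    hits = total = 0
    for s in range(n_seeds):
        cfg = CohortConfig(seed=seed * 4001 + s, n_mgs=300, n_ko=400,
                           n_pathways=30, pathway_size_range=(pathway_size, pathway_size),
                           n_differential_pathways=3, pathway_effect_size=effect,
                           n_differential_mgs=10, mgs_effect_size=0.0)
        bundle = generate_cohort(cfg)
        val = validate_cohort(bundle.ko_abundance, bundle.meta, exclude_atb=True)
        kores = ko_differential(val.abundance, val.meta, "PR", "PD", timepoint="M0")
        table = reporter_score(kores, bundle.pathway_map, n_background=1000,
                               seed=seed * 4001 + s)
        for pid in bundle.truth.differential_pathways:
            total += 1
            hits += bool(table.loc[pid, "corrected_z"] > cutoff)
    return {"detection_rate": hits / total, "n_pathways": total}


def _predictor_cohort(seed: int, effect: float, n_patients: int = 80):
    cfg = CohortConfig(
        seed=seed,
        n_patients=n_patients,
        group_proportions={"PR": 0.25, "SD": 0.45, "PD": 0.30, "FD": 0.0},
        n_mgs=120,
        n_ko=160,
        n_differential_mgs=20,
        mgs_effect_size=effect,
        n_differential_pathways=3,
        pathway_effect_size=effect / 2,
        n_pathways=10,
        atb_rate=0.0,
    )
    bundle = generate_cohort(cfg)
    base = bundle.meta[
        (bundle.meta["timepoint"] == "M0")
        & bundle.meta["response"].isin(("PR", "SD", "PD"))
    ]
    X = pd.concat(
        [
            bundle.mgs_abundance.loc[base.index].add_prefix("mgs:"),
            bundle.ko_abundance.loc[base.index].add_prefix("ko:"),
        ],
        axis=1,
    )
    return X, base["response"].to_numpy()


def predictor_benchmark(
    seed: int = 0,
    n_seeds: int = 20,
    effect: float = 2.0,
    n_reps: int = 200,
) -> dict:
    """Held-out one-vs-rest AUC of the tiered classifier.

    Runs ``n_seeds`` cohorts with a strong planted MGS+KO signal and
    ``n_seeds`` null cohorts; reports per-class median AUC (strong) and
    the fraction of null seeds whose bootstrap AUC CI covers 0.5.
    """
    strong = {c: [] for c in ("PD", "SD", "PR")}
    cover = {c: 0 for c in ("PD", "SD", "PR")}
    for s in range(n_seeds):
        for label, eff in (("strong", effect), ("null", 0.0)):
            X, y = _predictor_cohort(seed * 5003 + s + (50000 if label == "null" else 0), eff)
            model = TieredResponseClassifier(
                n_reps=n_reps, random_state=seed * 5003 + s
            ).fit(X, y)
            held = model.held_out_ids_
            probs = model.predict_table(X.loc[held])
            yv = pd.Series(y, index=X.index).loc[held]
            for cls, col in (("PD", "p_pd"), ("SD", "p_sd"), ("PR", "p_pr")):
                auc, lo, hi = roc_auc(
                    probs[col].to_numpy(), (yv == cls).to_numpy(), seed=seed + s
                )
                if label == "strong":
                    strong[cls].append(auc)
                else:
                    cover[cls] += int(lo <= 0.5 <= hi)
    return {
        "strong_auc_median": {c: float(np.median(v)) for c, v in strong.items()},
        "strong_auc_all": strong,
        "null_ci_coverage": {c: cover[c] / n_seeds for c in cover},
        "n_seeds": n_seeds,
    }


def simulate_dm_mixture(rng, n, depth, alphas, weights=None):
    """Sample counts from a Dirichlet-multinomial mixture."""
    K = len(alphas)
    weights = weights if weights is not None else np.full(K, 1.0 / K)
    comps = rng.choice(K, size=n, p=weights)
    X = np.zeros((n, len(alphas[0])), dtype=int)
    for i, c in enumerate(comps):
        X[i] = rng.multinomial(depth, rng.dirichlet(alphas[c]))
    return X, comps


def dmm_k_recovery(
    seed: int = 0,
    n_seeds: int = 50,
    k_values: tuple[int, ...] = (1, 2, 3),
    n: int = 200,
    depth: int = 5000,
    n_taxa: int = 12,
) -> dict:
    """Fraction of runs where evidence-based selection picks the planted K."""
    base = np.full(n_taxa, 2.0)

    def comp_alpha(j):
        a = base.copy()
        a[j % n_taxa] = 30.0
        return a

    single = np.array([8, 4, 2, 1, 1, 1, 1, 1, 0.5, 0.5, 2, 3], dtype=float)[:n_taxa]
    rates = {}
    for k_true in k_values:
        correct = 0
        for s in range(n_seeds):
            rng = np.random.default_rng(seed * 7001 + 97 * k_true + s)
            alphas = (
                [single] if k_true == 1 else [comp_alpha(4 * j) for j in range(k_true)]
            )
            X, _ = simulate_dm_mixture(rng, n, depth, alphas)
            best, _ = select_k(X, range(1, 6), seed=seed * 7001 + 97 * k_true + s)
            correct += best == k_true
        rates[k_true] = correct / n_seeds
    return {"recovery_rate": rates, "n_seeds": n_seeds}
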