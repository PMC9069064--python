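"""Synthetic longitudinal NSCLC gut-microbiome cohort generator.

Emulates the data structure of an anti-PD-1 treatment cohort: patients
assigned to RECIST response groups (PR/SD/PD plus fast death), fecal
metagenomic samples on a biweekly-then-monthly grid with monotone
dropout, zero-inflated compositional MGS abundances with planted
group effects and a BMI covariate, KO profiles derived from the MGS
profiles through a binary MGS x KO incidence matrix, genus-level
enterotype structure, and censored progression-free survival driven by
group- and covariate-specific hazards.

Every stochastic choice flows from a single integer seed through named
sub-streams (one per patient), so adding or removing dropout never
perturbs another patient's abundance draws and identical configs give
bit-identical cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GROUP_ORDER, RESPONSE_GROUPS, TIMEPOINT_WEEKS, PathwayMap

__all__ = [
    "CohortConfig",
    "CohortTruth",
    "CohortBundle",
    "generate_cohort",
    "mgs_to_ko",
    "largest_remainder",
]

# Sub-stream tags: keep patient streams independent of global structure.
_TAG_GLOBAL = 101
_TAG_PATIENT = 202

# Per-group hazard multipliers (months^-1 scale): progressive disease
# and fast death progress quickly, partial responders slowly.
_GROUP_HAZARD = {"PR": 0.35, "SD": 0.8, "PD": 2.5, "FD": 8.0}

# Small plausible taxonomy universe for synthetic MGS annotation.
_GENUS_CLASS = {
    "Bacteroides": "Bacteroidia",
    "Prevotella": "Bacteroidia",
    "Alistipes": "Bacteroidia",
    "Parabacteroides": "Bacteroidia",
    "Faecalibacterium": "Clostridia",
    "Eubacterium": "Clostridia",
    "Clostridium": "Clostridia",
    "Enterocloster": "Clostridia",
    "Blautia": "Clostridia",
    "Roseburia": "Clostridia",
    "Ruminococcus": "Clostridia",
    "Dorea": "Clostridia",
    "Oscillibacter": "Clostridia",
    "Holdemania": "Erysipelotrichia",
    "Collinsella": "Coriobacteriia",
    "Akkermansia": "Verrucomicrobiae",
}
_GENERA = tuple(_GENUS_CLASS)

# Enterotype driver genera: E1 Bacteroides-, E2 Firmicutes-, E3
# Prevotella-dominated; further components cycle remaining genera.
_DRIVERS = (
    ("Bacteroides",),
    ("Faecalibacterium", "Eubacterium", "Clostridium"),
    ("Prevotella",),
    ("Ruminococcus",),
    ("Blautia",),
)

_KEGG_CATEGORIES = (
    "Metabolism",
    "Genetic Information Processing",
    "Environmental Information Processing",
    "Cellular Processes",
)


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters for cohort generation.

    Defaults mirror the emulated study: 85 patients split 13 PR / 24 SD
    / 43 PD / 5 FD, seven visits from baseline (M0) to month 4, an
    antibiotics-exposure rate of 12/85, and 1507 MGS features of which
    45 carry a planted group effect.
    """

    n_patients: int = 85
    group_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"PR": 13 / 85, "SD": 24 / 85, "PD": 43 / 85, "FD": 5 / 85}
    )
    timepoints: Sequence[tuple[str, int]] = tuple(TIMEPOINT_WEEKS.items())
    dropout_rate: float = 0.2
    n_mgs: int = 1507
    n_ko: int = 800
    n_pathways: int = 40
    pathway_size_range: tuple[int, int] = (5, 30)
    n_differential_mgs: int = 45
    mgs_effect_size: float = 1.0
    n_differential_pathways: int = 6
    pathway_effect_size: float = 1.0
    bmi_confounder_strength: float = 0.5
    enterotype_count: int = 3
    hazard_modifiers: Mapping[str, float] = field(
        default_factory=lambda: {"ATB": 2.5, "TMB_high": 0.5, "HLAE_high": 1.8}
    )
    censor_rate: float = 0.2
    seed: int = 0
    # secondary knobs (latent model shape)
    latent_sd: float = 1.0
    zero_inflation: float = 0.3
    detection_limit: float = 1e-6
    bmi_feature_fraction: float = 0.1
    enterotype_boost: float = 0.8
    atb_rate: float = 12 / 85
    tmb_cutoff: float = 5.6
    hla_e_high_rate: float = 0.4

    @classmethod
    def null(cls, seed: int = 0, **kwargs) -> "CohortConfig":
        """A cohort with every planted effect off.

        Group labels, visits, dropout and survival are generated as
        usual but abundances carry no group, BMI, pathway or
        enterotype-separation signal, so every downstream test sees its
        null hypothesis.
        """
        defaults = dict(
            mgs_effect_size=0.0,
            bmi_confounder_strength=0.0,
            pathway_effect_size=0.0,
            enterotype_boost=0.0,
            seed=seed,
        )
        defaults.update(kwargs)
        return cls(**defaults)

    def validate(self) -> None:
        total = sum(self.group_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"group_proportions sum to {total}, expected 1")
        for name, value in (
            ("n_patients", self.n_patients),
            ("n_mgs", self.n_mgs),
            ("n_ko", self.n_ko),
            ("n_pathways", self.n_pathways),
            ("enterotype_count", self.enterotype_count),
        ):
            if value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        for name, value in (
            ("dropout_rate", self.dropout_rate),
            ("censor_rate", self.censor_rate),
        ):
            if not 0 <= value < 1:
                raise ValueError(f"{name} must be in [0, 1), got {value}")
        if self.mgs_effect_size < 0 or self.pathway_effect_size < 0:
            raise ValueError("effect sizes must be >= 0")
        if self.n_differential_mgs > self.n_mgs:
            raise ValueError(
                f"n_differential_mgs ({self.n_differential_mgs}) exceeds n_mgs ({self.n_mgs})"
            )
        lo, hi = self.pathway_size_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid pathway_size_range {self.pathway_size_range}")
        unknown = set(self.group_proportions) - set(RESPONSE_GROUPS)
        if unknown:
            raise ValueError(f"unknown response groups {sorted(unknown)}")

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=seed)


@dataclass
class CohortTruth:
    """Planted ground truth, for recovery tests against the pipeline."""

    differential_mgs: dict[str, str]        # mgs_id -> enriched group
    differential_pathways: dict[str, str]   # pathway_id -> enriched group
    bmi_features: list[str]
    enterotype: dict[str, int]              # patient_id -> component
    group_hazard: dict[str, float]
    hazard_modifiers: dict[str, float]


@dataclass
class CohortBundle:
    """Everything one synthetic cohort produces."""

    mgs_abundance: pd.DataFrame
    ko_abundance: pd.DataFrame
    pathway_map: PathwayMap
    taxonomy: pd.DataFrame
    meta: pd.DataFrame
    truth: CohortTruth
    warnings: list[str] = field(default_factory=list)


def largest_remainder(proportions: Mapping[str, float], total: int) -> dict[str, int]:
    """Deterministic integer apportionment of ``total`` by proportions.

    Floors each share, then hands remaining units to the largest
    fractional parts; ties resolved by the mapping's key order.
    """
    keys = list(proportions)
    raw = {k: proportions[k] * total for k in keys}
    counts = {k: int(np.floor(raw[k])) for k in keys}
    leftover = total - sum(counts.values())
    order = sorted(keys, key=lambda k: -(raw[k] - counts[k]))
    for k in order[:leftover]:
        counts[k] += 1
    return counts


def mgs_to_ko(
    mgs_abundance: pd.DataFrame, incidence: pd.DataFrame
) -> pd.DataFrame:
    """Derive a KO-level profile from an MGS profile.

    KO abundance is the incidence-weighted sum of the abundances of the
    MGSs carrying that KO, renormalized per sample. All-zero KO columns
    are retained and listed in ``result.attrs["zero_kos"]``.
    """
    missing = [m for m in mgs_abundance.columns if m not in incidence.index]
    if missing:
        raise ValueError(f"incidence matrix lacks rows for MGSs {missing[:5]}")
    inc = incidence.loc[mgs_abundance.columns]
    raw = mgs_abundance.to_numpy(dtype=float) @ inc.to_numpy(dtype=float)
    sums = raw.sum(axis=1)
    if (sums <= 0).any():
        bad = mgs_abundance.index[int(np.argmax(sums <= 0))]
        raise ValueError(f"empty sample {bad!r}: no KO mass after projection")
    out = pd.DataFrame(
        raw / sums[:, None], index=mgs_abundance.index, columns=inc.columns
    )
    out.attrs["zero_kos"] = [k for k in out.columns[(raw == 0).all(axis=0)]]
    return out


def _patient_rng(seed: int, i: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, _TAG_PATIENT, i)))


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate one synthetic cohort bundle from a validated config."""
    config.validate()
    notes: list[str] = []
    for g in GROUP_ORDER:
        if config.group_proportions.get(g, 0.0) == 0.0:
            notes.append(f"response group {g} has proportion 0; downstream contrasts will miss it")

    g_rng = np.random.default_rng(np.random.SeedSequence((config.seed, _TAG_GLOBAL)))

    counts = largest_remainder(config.group_proportions, config.n_patients)
    groups: list[str] = []
    for g in config.group_proportions:
        groups += [g] * counts.get(g, 0)
    patient_ids = [f"P{i + 1:03d}" for i in range(config.n_patients)]

    # --- global structure -------------------------------------------------
    mgs_ids = [f"mgs{j:04d}" for j in range(config.n_mgs)]
    ko_ids = [f"K{j + 1:05d}" for j in range(config.n_ko)]
    genus_of = g_rng.integers(0, len(_GENERA), size=config.n_mgs)
    base_mean = g_rng.normal(-1.0, 1.5, size=config.n_mgs)

    # plant differential species among the detectable (above-median
    # baseline) features: a species nobody observes cannot be a marker
    eligible = np.nonzero(base_mean >= np.median(base_mean))[0]
    if len(eligible) < config.n_differential_mgs:
        eligible = np.arange(config.n_mgs)
    diff_idx = g_rng.choice(eligible, size=config.n_differential_mgs, replace=False)
    diff_group = {mgs_ids[j]: GROUP_ORDER[k % 3] for k, j in enumerate(diff_idx)}

    n_bmi = max(1, int(round(config.bmi_feature_fraction * config.n_mgs)))
    bmi_idx = g_rng.choice(config.n_mgs, size=n_bmi, replace=False)

    # incidence: each MGS carries a Poisson-sized random KO repertoire
    inc = np.zeros((config.n_mgs, config.n_ko), dtype=float)
    for j in range(config.n_mgs):
        k = min(config.n_ko, 1 + g_rng.poisson(7))
        inc[j, g_rng.choice(config.n_ko, size=k, replace=False)] = 1.0
    incidence = pd.DataFrame(inc, index=mgs_ids, columns=ko_ids)

    # pathway map over the KO universe
    lo, hi = config.pathway_size_range
    members: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    cats: dict[str, str] = {}
    for p in range(config.n_pathways):
        size = int(g_rng.integers(lo, hi + 1))
        kos = g_rng.choice(config.n_ko, size=min(size, config.n_ko), replace=False)
        pid = f"map{10000 + 10 * p}"
        members[pid] = frozenset(ko_ids[j] for j in kos)
        names[pid] = f"synthetic pathway {p}"
        cats[pid] = _KEGG_CATEGORIES[p % len(_KEGG_CATEGORIES)]
    pathway_map = PathwayMap(members=members, names=names, categories=cats)
    planted_pids = sorted(members)[: config.n_differential_pathways]
    diff_pathways = {pid: "PR" for pid in planted_pids}

    # taxonomy: ~30% of species names left unclassified
    unclassified = g_rng.random(config.n_mgs) < 0.3
    taxonomy = pd.DataFrame(
        {
            "class": [_GENUS_CLASS[_GENERA[g]] for g in genus_of],
            "genus": [_GENERA[g] for g in genus_of],
            "species": [
                "unclassified" if unclassified[j] else f"{_GENERA[genus_of[j]]} sp{j:04d}"
                for j in range(config.n_mgs)
            ],
        },
        index=pd.Index(mgs_ids, name="mgs_id"),
    )

    driver_mask = np.zeros((config.enterotype_count, config.n_mgs), dtype=bool)
    for e in range(config.enterotype_count):
        drivers = _DRIVERS[e % len(_DRIVERS)]
        idx = [i for i, gname in enumerate(_GENERA) if gname in drivers]
        driver_mask[e] = np.isin(genus_of, idx)

    # --- per-patient draws ------------------------------------------------
    tp_labels = [t for t, _ in config.timepoints]
    tp_weeks = dict(config.timepoints)
    rows = []
    sample_ids: list[str] = []
    latent_rows = []
    enterotype_of: dict[str, int] = {}

    seen_per_group: dict[str, int] = {}
    for i, (pid, grp) in enumerate(zip(patient_ids, groups)):
        rng = _patient_rng(config.seed, i)
        # enterotypes rotate within each response group: balanced by
        # design, encoding the observed independence of enterotype and
        # treatment response
        ent = seen_per_group.get(grp, 0) % config.enterotype_count
        seen_per_group[grp] = seen_per_group.get(grp, 0) + 1
        enterotype_of[pid] = ent
        bmi = float(np.clip(rng.normal(23.0, 3.0), 15.0, 40.0))
        atb = bool(rng.random() < config.atb_rate)
        tmb = float(rng.lognormal(mean=np.log(4.5), sigma=0.7))
        hla_e_high = bool(rng.random() < config.hla_e_high_rate)

        # retained visits: baseline always kept; monotone dropout after it
        visits = [tp_labels[0]]
        if grp != "FD":  # fast-death patients contribute only baseline
            for t in tp_labels[1:]:
                if rng.random() < config.dropout_rate:
                    break
                visits.append(t)

        # latent log-abundances drawn for EVERY visit so dropout never
        # shifts the stream; only retained visits are materialized
        mean = base_mean.copy()
        mean[driver_mask[ent]] += config.enterotype_boost
        mean[bmi_idx] += config.bmi_confounder_strength * (bmi - 23.0) / 3.0
        if config.mgs_effect_size > 0:
            for k, j in enumerate(diff_idx):
                if diff_group[mgs_ids[j]] == grp:
                    mean[j] += config.mgs_effect_size
        noise = rng.normal(0.0, config.latent_sd, size=(len(tp_labels), config.n_mgs))
        # abundance-coupled zero inflation: any latent boost (planted
        # effect, enterotype, BMI) raises occurrence as well as
        # abundance — differential species are also more detectable
        p_zero = config.zero_inflation * np.exp(-np.maximum(mean - base_mean, 0.0))
        keep_mask = rng.random((len(tp_labels), config.n_mgs)) >= p_zero[None, :]

        # progression-free survival from exponential hazards
        hazard = _GROUP_HAZARD[grp]
        if atb:
            hazard *= config.hazard_modifiers.get("ATB", 1.0)
        if tmb > config.tmb_cutoff:
            hazard *= config.hazard_modifiers.get("TMB_high", 1.0)
        if hla_e_high:
            hazard *= config.hazard_modifiers.get("HLAE_high", 1.0)
        t_event = float(rng.exponential(1.0 / hazard))
        t_event = max(t_event, 0.05)
        if rng.random() < config.censor_rate:
            pfs, event = float(rng.uniform(0.04, t_event)), False
        else:
            pfs, event = t_event, True

        for vi, t in enumerate(tp_labels):
            if t not in visits:
                continue
            sid = f"{pid}_{t}"
            sample_ids.append(sid)
            latent = np.exp(mean + noise[vi]) * keep_mask[vi]
            if latent.sum() <= 0:  # pathological full-zero draw: keep top feature
                latent[int(np.argmax(mean + noise[vi]))] = 1.0
            closed = latent / latent.sum()
            closed[closed < config.detection_limit] = 0.0  # sequencing floor
            latent_rows.append(closed)
            rows.append(
                {
                    "sample_id": sid,
                    "patient_id": pid,
                    "timepoint": t,
                    "week": tp_weeks[t],
                    "response": grp,
                    "atb": atb,
                    "bmi": round(bmi, 2),
                    "tmb": round(tmb, 3),
                    "hla_e": "high" if hla_e_high else "low",
                    "pfs_months": round(pfs, 3),
                    "pfs_event": event,
                }
            )

    mgs_abundance = pd.DataFrame(
        np.asarray(latent_rows), index=pd.Index(sample_ids, name="sample_id"), columns=mgs_ids
    )
    meta = pd.DataFrame(rows).set_index("sample_id")

    ko_abundance = mgs_to_ko(mgs_abundance, incidence)
    if config.pathway_effect_size > 0 and diff_pathways:
        vals = ko_abundance.to_numpy()
        better = meta["response"].to_numpy() == "PR"
        planted_kos = sorted(set().union(*(members[p] for p in planted_pids)))
        col_idx = [ko_abundance.columns.get_loc(k) for k in planted_kos]
        vals[np.ix_(better, col_idx)] *= float(np.exp(config.pathway_effect_size))
        vals /= vals.sum(axis=1, keepdims=True)
        ko_abundance = pd.DataFrame(
            vals, index=ko_abundance.index, columns=ko_abundance.columns
        )

    truth = CohortTruth(
        differential_mgs=diff_group,
        differential_pathways=diff_pathways,
        bmi_features=[mgs_ids[j] for j in bmi_idx],
        enterotype=enterotype_of,
        group_hazard=dict(_GROUP_HAZARD),
        hazard_modifiers=dict(config.hazard_modifiers),
    )
    bundle = CohortBundle(
        mgs_abundance=mgs_abundance,
        ko_abundance=ko_abundance,
        pathway_map=pathway_map,
        taxonomy=taxonomy,
        meta=meta,
        truth=truth,
        warnings=notes,
    )
    for note in notes:
        warnings.warn(note, stacklevel=2)
    return bundle
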