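"""Two-tiered random-forest prediction of anti-PD-1 response groups.

Stage A separates partial responders (PR) from progressive disease
(PD); stage B separates stable disease (SD) from everything else. Each
stage selects features by repeated stratified cross-validation: every
repetition draws a random candidate-feature subset, trains a CART
learner per fold, and credits each used feature with its impurity
importance weighted by the held-out fold accuracy. The top-ranked
features (k chosen by out-of-fold AUC over a small grid) feed a final
random forest per stage. Three-class probabilities come from the
multiplicative combination

    p_SD = p_B(SD),  p_PR = (1 - p_B(SD)) * p_A(PR),
    p_PD = (1 - p_B(SD)) * (1 - p_A(PR)),

which sums to one by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "cv_feature_select",
    "TieredResponseClassifier",
    "train_tiered",
    "combine_probabilities",
    "roc_auc",
    "fuse_multiomics",
]

CLASS_ORDER = ("PD", "SD", "PR")


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X)
    return pd.DataFrame(X, columns=[f"f{j}" for j in range(X.shape[1])])


def cv_feature_select(
    X,
    y,
    n_folds: int = 8,
    n_reps: int = 200,
    seed: int | None = 0,
    trees_per_rep: int = 1,
    candidate_factor: float = 4.0,
    metric: str = "importance_x_accuracy",
) -> pd.DataFrame:
    """Rank features by aggregated cross-validated contribution.

    Per repetition: a stratified ``n_folds`` split and a random
    candidate subset of ~``candidate_factor * sqrt(p)`` features; per
    fold, a tree (or small forest when ``trees_per_rep > 1``) is
    trained in-fold and each feature is credited with importance x
    held-out accuracy (or its selection frequency x accuracy under
    ``metric="frequency"``). Deterministic given the seed.
    """
    X = _as_frame(X)
    y = np.asarray(y)
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("y must contain two classes")
    folds = int(min(n_folds, counts.min()))
    if folds < 2:
        raise ValueError("smallest class must have >= 2 samples")
    p = X.shape[1]
    m = min(p, max(2, int(np.ceil(candidate_factor * np.sqrt(p)))))
    Xv = X.to_numpy(dtype=float)
    scores = np.zeros(p)
    ss = np.random.SeedSequence((0 if seed is None else seed, 7331))
    rep_seeds = ss.generate_state(n_reps * 2)
    for r in range(n_reps):
        rng = np.random.default_rng(rep_seeds[2 * r])
        cand = np.sort(rng.choice(p, size=m, replace=False))
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(rep_seeds[2 * r + 1] % 2**31)
        )
        for f, (tr, te) in enumerate(skf.split(Xv, y)):
            tree_seed = int((rep_seeds[2 * r] + f) % 2**31)
            if trees_per_rep > 1:
                learner = RandomForestClassifier(
                    n_estimators=trees_per_rep,
                    max_features="sqrt",
                    random_state=tree_seed,
                )
            else:
                learner = DecisionTreeClassifier(
                    max_features="sqrt", random_state=tree_seed
                )
            learner.fit(Xv[np.ix_(tr, cand)], y[tr])
            acc = float((learner.predict(Xv[np.ix_(te, cand)]) == y[te]).mean())
            imp = learner.feature_importances_
            if metric == "frequency":
                imp = (imp > 0).astype(float)
            scores[cand] += imp * acc
    out = pd.DataFrame({"feature": X.columns, "score": scores})
    out = out.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)
    out.index.name = "rank"
    return out


def combine_probabilities(p_a_pr, p_b_sd):
    """Combine stage probabilities into (p_pd, p_sd, p_pr); vectorized.

    ``p_a_pr`` is stage A's probability of PR (vs PD); ``p_b_sd`` is
    stage B's probability of SD. The result sums to 1 exactly.
    """
    p_a_pr = np.asarray(p_a_pr, dtype=float)
    p_b_sd = np.asarray(p_b_sd, dtype=float)
    if ((p_a_pr < 0) | (p_a_pr > 1)).any() or ((p_b_sd < 0) | (p_b_sd > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    p_sd = p_b_sd
    p_pr = (1.0 - p_b_sd) * p_a_pr
    p_pd = (1.0 - p_b_sd) * (1.0 - p_a_pr)
    return p_pd, p_sd, p_pr


def roc_auc(
    scores,
    labels,
    n_boot: int = 2000,
    seed: int | None = 0,
) -> tuple[float, float, float]:
    """AUC by the rank (Mann-Whitney) formulation with a bootstrap CI.

    Ties count one half. The 95% CI comes from a class-stratified
    bootstrap with ``n_boot`` resamples.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    def _auc(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
        both = np.concatenate([pos, neg], axis=-1)
        ranks = rankdata(both, axis=-1)
        r_pos = ranks[..., : pos.shape[-1]].sum(axis=-1)
        u = r_pos - pos.shape[-1] * (pos.shape[-1] + 1) / 2.0
        return u / (pos.shape[-1] * neg.shape[-1])

    pos, neg = scores[labels], scores[~labels]
    auc = float(_auc(pos, neg))
    rng = np.random.default_rng(seed)
    bpos = pos[rng.integers(0, n_pos, size=(n_boot, n_pos))]
    bneg = neg[rng.integers(0, n_neg, size=(n_boot, n_neg))]
    baucs = _auc(bpos, bneg)
    lo, hi = np.percentile(baucs, [2.5, 97.5])
    return auc, float(lo), float(hi)


def fuse_multiomics(
    results: list[pd.DataFrame], weights=None
) -> pd.DataFrame:
    """Weighted mean of per-dataset class-probability tables, renormalized.

    Each input has columns ``p_pd, p_sd, p_pr`` over identical samples;
    default weights are equal.
    """
    if not results:
        raise ValueError("need at least one prediction table")
    idx = results[0].index
    cols = ["p_pd", "p_sd", "p_pr"]
    for r in results[1:]:
        if not r.index.equals(idx):
            raise ValueError("prediction tables must cover identical samples")
    if weights is None:
        weights = np.ones(len(results))
    weights = np.asarray(weights, dtype=float)
    if (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("weights must be >= 0 with positive sum")
    acc = sum(w * r[cols].to_numpy(dtype=float) for w, r in zip(weights, results))
    acc /= acc.sum(axis=1, keepdims=True)
    return pd.DataFrame(acc, index=idx, columns=cols)


class TieredResponseClassifier(ClassifierMixin, BaseEstimator):
    """Two-tiered RF classifier over PR/SD/PD with CV feature selection.

    A seeded class-stratified training draw (default 8 PR + 8 PD for
    stage A; those 16 as the non-SD class against 16 SD for stage B)
    feeds per-stage feature selection; the per-stage k is picked from
    ``k_grid`` by out-of-fold AUC and the final 500-tree forests are
    refit on the full training draw. Samples left out of the draw are
    listed in ``held_out_ids_`` for testing.
    """

    def __init__(
        self,
        n_train_pr: int = 8,
        n_train_pd: int = 8,
        n_train_sd: int = 16,
        n_folds: int = 8,
        n_reps: int = 200,
        k_grid: tuple[int, ...] = (5, 10, 20, 30),
        n_trees_final: int = 500,
        k_eval_trees: int = 25,
        trees_per_rep: int = 1,
        selection_metric: str = "importance_x_accuracy",
        random_state: int | None = 0,
    ):
        self.n_train_pr = n_train_pr
        self.n_train_pd = n_train_pd
        self.n_train_sd = n_train_sd
        self.n_folds = n_folds
        self.n_reps = n_reps
        self.k_grid = k_grid
        self.n_trees_final = n_trees_final
        self.k_eval_trees = k_eval_trees
        self.trees_per_rep = trees_per_rep
        self.selection_metric = selection_metric
        self.random_state = random_state

    def _pick_k(self, Xv: np.ndarray, y: np.ndarray, ranking: pd.DataFrame, seed: int):
        """Out-of-fold AUC over the k grid; ties go to the smaller k."""
        _, counts = np.unique(y, return_counts=True)
        folds = int(min(4, counts.min()))  # coarse CV is enough to pick k
        best_k, best_auc = None, -np.inf
        col_index = ranking["feature"].to_numpy()
        for k in sorted(set(min(int(k), Xv.shape[1]) for k in self.k_grid)):
            feats = self._feature_positions(col_index[:k])
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % 2**31)
            oof = np.zeros(len(y))
            for f, (tr, te) in enumerate(skf.split(Xv, y)):
                rf = RandomForestClassifier(
                    n_estimators=self.k_eval_trees, random_state=(seed + f) % 2**31
                )
                rf.fit(Xv[np.ix_(tr, feats)], y[tr])
                pos = list(rf.classes_).index(True)
                oof[te] = rf.predict_proba(Xv[np.ix_(te, feats)])[:, pos]
            auc, _, _ = roc_auc(oof, y, n_boot=100, seed=seed)
            if auc > best_auc + 1e-12:
                best_k, best_auc = k, auc
        return best_k

    def _feature_positions(self, names) -> list[int]:
        return [self._columns_.get_loc(n) for n in names]

    def _fit_stage(self, Xv: np.ndarray, y: np.ndarray, seed: int):
        ranking = cv_feature_select(
            pd.DataFrame(Xv, columns=self._columns_),
            y,
            n_folds=self.n_folds,
            n_reps=self.n_reps,
            seed=seed,
            trees_per_rep=self.trees_per_rep,
            metric=self.selection_metric,
        )
        k = self._pick_k(Xv, y, ranking, seed + 17)
        features = list(ranking["feature"].iloc[:k])
        model = RandomForestClassifier(
            n_estimators=self.n_trees_final, random_state=seed % 2**31
        )
        model.fit(Xv[:, self._feature_positions(features)], y)
        return model, features, ranking

    def fit(self, X, y):
        X = _as_frame(X)
        y = pd.Series(np.asarray(y), index=X.index)
        need = {"PR": self.n_train_pr, "PD": self.n_train_pd, "SD": self.n_train_sd}
        for cls, n in need.items():
            have = int((y == cls).sum())
            if have < n:
                raise ValueError(f"class {cls} has {have} samples, needs >= {n}")
        self._columns_ = X.columns
        rng = np.random.default_rng(self.random_state)
        train_ids: dict[str, list] = {}
        for cls in ("PR", "PD", "SD"):  # fixed draw order for determinism
            ids = np.array(X.index[y == cls])
            train_ids[cls] = list(ids[rng.choice(len(ids), size=need[cls], replace=False)])
        a_ids = train_ids["PR"] + train_ids["PD"]
        b_ids = train_ids["SD"] + a_ids
        seed_a = int(rng.integers(0, 2**31 - 1))
        seed_b = int(rng.integers(0, 2**31 - 1))

        Xa = X.loc[a_ids].to_numpy(dtype=float)
        ya = (y.loc[a_ids] == "PR").to_numpy()
        self.model_a_, self.features_a_, self.selection_trace_a_ = self._fit_stage(
            Xa, ya, seed_a
        )
        Xb = X.loc[b_ids].to_numpy(dtype=float)
        yb = (y.loc[b_ids] == "SD").to_numpy()
        self.model_b_, self.features_b_, self.selection_trace_b_ = self._fit_stage(
            Xb, yb, seed_b
        )
        self.training_sample_ids_ = list(b_ids)
        self.held_out_ids_ = [s for s in X.index if s not in set(b_ids)]
        self.classes_ = np.array(CLASS_ORDER)
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Class probabilities in the order (PD, SD, PR)."""
        check_is_fitted(self)
        X = _as_frame(X)
        if set(self._columns_) <= set(X.columns):
            X = X.reindex(columns=self._columns_)
        Xv = X.to_numpy(dtype=float)
        pa = self.model_a_.predict_proba(
            Xv[:, self._feature_positions(self.features_a_)]
        )[:, list(self.model_a_.classes_).index(True)]
        pb = self.model_b_.predict_proba(
            Xv[:, self._feature_positions(self.features_b_)]
        )[:, list(self.model_b_.classes_).index(True)]
        p_pd, p_sd, p_pr = combine_probabilities(pa, pb)
        return np.column_stack([p_pd, p_sd, p_pr])

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def predict_table(self, X) -> pd.DataFrame:
        """Per-sample probability table with the argmax class."""
        X = _as_frame(X)
        probs = self.predict_proba(X)
        out = pd.DataFrame(probs, index=X.index, columns=["p_pd", "p_sd", "p_pr"])
        out["predicted"] = self.classes_[probs.argmax(axis=1)]
        return out


def train_tiered(
    X,
    labels,
    n_train_per_class: dict[str, int] | None = None,
    select_config: dict | None = None,
    seed: int | None = 0,
) -> TieredResponseClassifier:
    """Operation-style wrapper constructing and fitting the estimator."""
    n_train_per_class = n_train_per_class or {"PR": 8, "PD": 8, "SD": 16}
    kwargs = dict(select_config or {})
    model = TieredResponseClassifier(
        n_train_pr=n_train_per_class.get("PR", 8),
        n_train_pd=n_train_per_class.get("PD", 8),
        n_train_sd=n_train_per_class.get("SD", 16),
        random_state=seed,
        **kwargs,
    )
    return model.fit(X, labels)
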