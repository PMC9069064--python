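"""Enterotyping by Dirichlet-multinomial mixture (DMM) clustering.

Genus-level count profiles are modelled as a K-component mixture of
Dirichlet-multinomial (Polya) distributions, fitted by EM with the
Minka fixed-point update for the Dirichlet parameters. Model order is
chosen by a Laplace-approximated log model evidence (BIC available as
an alternative), mirroring the standard community-typing workflow in
which the evidence-optimal K defines the enterotypes.

The estimator follows scikit-learn conventions: ``fit`` / ``predict`` /
``predict_proba``, constructor-only hyperparameters, and fitted
attributes with trailing underscores.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp, polygamma, psi
from sklearn.base import BaseEstimator, DensityMixin
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "to_genus_counts",
    "DirichletMultinomialMixture",
    "fit_dmm",
    "select_k",
]

_ALPHA_MIN = 1e-8


def to_genus_counts(
    mgs_abundance: pd.DataFrame, taxonomy: pd.DataFrame, depth: int = 10000
) -> pd.DataFrame:
    """Aggregate MGS relative abundances to genus-level pseudo-counts.

    Sums abundances by genus, renormalizes per sample, scales by
    ``depth`` and rounds half-to-even; any rounding overshoot beyond
    ``depth`` is taken from the largest count so per-sample totals
    never exceed the depth.
    """
    if depth < 100:
        raise ValueError("depth must be >= 100")
    genus = taxonomy.loc[mgs_abundance.columns, "genus"]
    grouped = mgs_abundance.T.groupby(genus.to_numpy()).sum().T
    vals = grouped.to_numpy(dtype=float)
    sums = vals.sum(axis=1, keepdims=True)
    if (sums <= 0).any():
        raise ValueError("sample with zero total abundance")
    counts = np.rint(vals / sums * depth)
    over = counts.sum(axis=1) - depth
    for i in np.nonzero(over > 0)[0]:
        counts[i, int(np.argmax(counts[i]))] -= over[i]
    return pd.DataFrame(
        counts.astype(int), index=mgs_abundance.index, columns=grouped.columns
    )


def _dm_log_pmf(X: np.ndarray, alpha: np.ndarray, log_coeff: np.ndarray) -> np.ndarray:
    """Log Polya pmf of each row of X under each row of alpha (n x K)."""
    A = alpha.sum(axis=1)  # (K,)
    n = X.sum(axis=1)  # (n,)
    term = gammaln(X[:, None, :] + alpha[None, :, :]).sum(axis=2) - gammaln(alpha).sum(
        axis=1
    )
    return log_coeff[:, None] + gammaln(A)[None, :] - gammaln(n[:, None] + A[None, :]) + term


class DirichletMultinomialMixture(DensityMixin, BaseEstimator):
    """K-component Dirichlet-multinomial mixture fitted by EM.

    Parameters
    ----------
    n_components : number of mixture components (enterotypes).
    n_init : random restarts; responsibilities are initialized from
        k-means on the proportion profiles with varying seeds.
    tol : relative log-likelihood change declaring convergence.
    max_iter : EM iteration cap; non-convergence is flagged, the best
        fit so far is returned.
    alpha_iter : inner Minka fixed-point iterations per M-step.
    evidence : "laplace" (default) or "bic" model-selection score.
    random_state : seed for restarts.

    Attributes
    ----------
    weights_, alphas_, responsibilities_, labels_, log_likelihood_,
    log_evidence_, n_iter_, converged_
    """

    def __init__(
        self,
        n_components: int = 3,
        n_init: int = 5,
        tol: float = 1e-6,
        max_iter: int = 500,
        alpha_iter: int = 3,
        evidence: str = "laplace",
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.n_init = n_init
        self.tol = tol
        self.max_iter = max_iter
        self.alpha_iter = alpha_iter
        self.evidence = evidence
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _init_resp(self, P: np.ndarray, seed: int) -> np.ndarray:
        K = self.n_components
        if K == 1:
            return np.ones((len(P), 1))
        with warnings.catch_warnings():
            # duplicate-profile inputs legitimately yield < K clusters
            warnings.simplefilter("ignore", ConvergenceWarning)
            km = KMeans(n_clusters=K, n_init=3, random_state=seed).fit(P)
        resp = np.full((len(P), K), 0.1 / max(K - 1, 1))
        resp[np.arange(len(P)), km.labels_] = 0.9
        return resp / resp.sum(axis=1, keepdims=True)

    def _m_step(
        self, X: np.ndarray, resp: np.ndarray, alphas: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        n_tot = X.sum(axis=1)
        weights = resp.mean(axis=0)
        new_alphas = alphas.copy()
        for c in range(self.n_components):
            r = resp[:, c]
            a = new_alphas[c]
            for _ in range(self.alpha_iter):
                A = a.sum()
                num = (r[:, None] * (psi(X + a[None, :]) - psi(a)[None, :])).sum(axis=0)
                den = (r * (psi(n_tot + A) - psi(A))).sum()
                if den <= 0:
                    break
                a = np.maximum(a * num / den, _ALPHA_MIN)
            new_alphas[c] = a
        return weights, new_alphas

    def _fit_once(
        self, X: np.ndarray, P: np.ndarray, log_coeff: np.ndarray, seed: int
    ) -> dict:
        resp = self._init_resp(P, seed)
        weights = resp.mean(axis=0)
        # moment-style init: component mean proportions at concentration 50
        alphas = np.maximum(
            (resp.T @ P) / resp.sum(axis=0)[:, None] * 50.0, _ALPHA_MIN
        )
        prev = -np.inf
        loglik = -np.inf
        converged = False
        trace: list[float] = []
        for it in range(1, self.max_iter + 1):
            weights, alphas = self._m_step(X, resp, alphas)
            log_p = _dm_log_pmf(X, alphas, log_coeff) + np.log(weights)[None, :]
            norm = logsumexp(log_p, axis=1)
            resp = np.exp(log_p - norm[:, None])
            loglik = float(norm.sum())
            if np.isfinite(prev) and loglik - prev < -1e-6 * max(1.0, abs(prev)):
                # EM with inexact M-step; never tolerate a real decrease
                loglik = prev
                break
            trace.append(loglik)
            if np.isfinite(prev) and abs(loglik - prev) <= self.tol * max(1.0, abs(prev)):
                converged = True
                prev = loglik
                break
            prev = loglik
        return {
            "weights": weights,
            "alphas": alphas,
            "resp": resp,
            "loglik": loglik,
            "n_iter": it,
            "converged": converged,
            "trace": trace,
        }

    def _log_evidence(self, X: np.ndarray, fit: dict) -> float:
        n, J = X.shape
        K = self.n_components
        d = K * J + (K - 1)
        if self.evidence == "bic":
            return fit["loglik"] - 0.5 * d * np.log(n)
        # Laplace: log evidence ~ logL + log prior + d/2 log 2pi
        # - 1/2 log det(-H), with an analytic per-component Hessian of
        # the weighted Polya log-likelihood in log-alpha coordinates
        # (diag + rank-one), a weak N(0, 10) prior per log alpha, and a
        # BIC-style 0.5 log n per free weight.
        lam = np.log(np.maximum(fit["alphas"], _ALPHA_MIN))
        prior_var = 10.0
        log_prior = float(
            (-0.5 * np.log(2 * np.pi * prior_var) - lam**2 / (2 * prior_var)).sum()
        )
        n_tot = X.sum(axis=1)
        logdet = 0.0
        for c in range(K):
            r = fit["resp"][:, c]
            a = fit["alphas"][c]
            A = a.sum()
            q = (r[:, None] * (polygamma(1, X + a[None, :]) - polygamma(1, a)[None, :])).sum(
                axis=0
            )
            cc = (r * (polygamma(1, A) - polygamma(1, n_tot + A))).sum()
            # Hessian H = diag(q) - cc * 11^T in alpha coords (q <= 0, cc >= 0);
            # in lambda = log alpha coords: D_a H D_a (gradient term ~ 0 at optimum)
            # -H_lambda = diag(-q a^2) - cc (a)(a)^T; determinant lemma
            neg_diag = np.maximum(-q * a * a, 1e-12)
            corr = max(1.0 - cc * (a * a / neg_diag).sum(), 1e-12)
            logdet += np.log(neg_diag).sum() + np.log(max(corr, 1e-12))
        logdet += (K - 1) * np.log(n)
        return fit["loglik"] + log_prior + 0.5 * d * np.log(2 * np.pi) - 0.5 * logdet

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or (X < 0).any() or not np.allclose(X, np.rint(X)):
            raise ValueError("X must be a 2-D non-negative integer count matrix")
        if (X.sum(axis=1) <= 0).any():
            raise ValueError("every sample needs a positive row sum")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        P = X / X.sum(axis=1, keepdims=True)
        log_coeff = gammaln(X.sum(axis=1) + 1) - gammaln(X + 1).sum(axis=1)
        rng = np.random.default_rng(self.random_state)
        seeds = rng.integers(0, 2**31 - 1, size=self.n_init)
        best = None
        for s in seeds:
            fit = self._fit_once(X, P, log_coeff, int(s))
            if best is None or fit["loglik"] > best["loglik"]:
                best = fit
        self.weights_ = best["weights"]
        self.alphas_ = best["alphas"]
        self.responsibilities_ = best["resp"]
        self.labels_ = best["resp"].argmax(axis=1)
        self.log_likelihood_ = best["loglik"]
        self.log_likelihood_trace_ = np.asarray(best["trace"])
        self.n_iter_ = best["n_iter"]
        self.converged_ = best["converged"]
        self.log_evidence_ = self._log_evidence(X, best)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        log_coeff = gammaln(X.sum(axis=1) + 1) - gammaln(X + 1).sum(axis=1)
        log_p = _dm_log_pmf(X, self.alphas_, log_coeff) + np.log(self.weights_)[None, :]
        return np.exp(log_p - logsumexp(log_p, axis=1)[:, None])

    def predict(self, X):
        return self.predict_proba(X).argmax(axis=1)

    def score(self, X, y=None):
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        log_coeff = gammaln(X.sum(axis=1) + 1) - gammaln(X + 1).sum(axis=1)
        log_p = _dm_log_pmf(X, self.alphas_, log_coeff) + np.log(self.weights_)[None, :]
        return float(logsumexp(log_p, axis=1).sum())


def fit_dmm(
    counts,
    K: int,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    **kwargs,
) -> DirichletMultinomialMixture:
    """Fit a K-component DMM; thin wrapper over the estimator."""
    model = DirichletMultinomialMixture(
        n_components=K, tol=tol, max_iter=max_iter, random_state=seed, **kwargs
    )
    return model.fit(np.asarray(counts))


def select_k(
    counts,
    k_range=range(1, 6),
    seed: int | None = None,
    **kwargs,
) -> tuple[int, pd.DataFrame]:
    """Pick the component count maximizing log evidence.

    Returns ``(best_k, table)`` where the table has one row per K with
    its evidence, log-likelihood and convergence flag. Evidence ties
    resolve toward the smaller K.
    """
    k_list = sorted(set(int(k) for k in k_range))
    if not k_list:
        raise ValueError("k_range must be non-empty")
    rows = []
    fits = {}
    for i, k in enumerate(k_list):
        sub_seed = None if seed is None else (seed * 1000 + k) % (2**31 - 1)
        model = fit_dmm(counts, k, seed=sub_seed, **kwargs)
        fits[k] = model
        rows.append(
            {
                "K": k,
                "log_evidence": model.log_evidence_,
                "log_likelihood": model.log_likelihood_,
                "converged": model.converged_,
            }
        )
    table = pd.DataFrame(rows).set_index("K")
    best_k = int(table["log_evidence"].idxmax())
    return best_k, table
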