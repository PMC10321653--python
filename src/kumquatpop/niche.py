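"""Bioclimatic PCA and probabilistic niche overlap.

The niche region of a label is the alpha-probability ellipsoid of its
fitted multivariate-normal climate distribution; the directional overlap
A -> B is the probability that a draw from A's distribution lands inside
B's region, estimated by Monte Carlo. The Bayesian estimator propagates
parameter uncertainty by drawing (mu, Sigma) for each label from a
normal-inverse-Wishart posterior under a noninformative prior and reports
the posterior mean and central 95% interval of the overlap. Overlap is
directional and NOT symmetric; both directions are always reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

log = logging.getLogger("kumquatpop")


def pca_variance(tbl: pd.DataFrame, standardize: bool = True):
    """PCA of the climate variables; returns (loadings, percent_variance).

    Non-numeric columns (e.g. the label) are ignored; variables are
    z-scored before decomposition unless the table is already standardized
    (``standardize=False``). Constant columns are dropped with a warning.
    Percent variances sum to 100.
    """
    from sklearn.decomposition import PCA

    num = tbl.select_dtypes(include=[np.number])
    sd = num.std(ddof=1)
    const = sd[sd == 0].index.tolist()
    if const:
        log.warning("dropping constant columns: %s", const)
        num = num.drop(columns=const)
    if len(num) < 3:
        raise ValueError("PCA needs >= 3 records")
    X = num.to_numpy(float)
    if standardize:
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    p = PCA()
    p.fit(X)
    pct = 100.0 * p.explained_variance_ratio_
    loadings = pd.DataFrame(p.components_,
                            columns=num.columns,
                            index=[f"PC{i+1}" for i in range(len(pct))])
    return loadings, pct


@dataclass
class OverlapResult:
    """Directional niche-overlap probabilities A -> B and B -> A."""

    label_a: str
    label_b: str
    a_in_b: float
    b_in_a: float
    a_in_b_interval: tuple | None = None
    b_in_a_interval: tuple | None = None
    alpha: float = 0.95
    estimator: str = "plugin"
    draws: int = 0


def _fit(tbl, label_col, label):
    sub = tbl[tbl[label_col] == label].select_dtypes(include=[np.number])
    if len(sub) < 2:
        raise ValueError(f"label {label!r} has too few records")
    if len(sub) < 20:
        log.warning("label %r has only %d records; estimates will be noisy",
                    label, len(sub))
    X = sub.to_numpy(float)
    mu = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    sign, _ = np.linalg.slogdet(cov)
    if sign <= 0:
        raise ValueError(f"singular covariance for label {label!r}")
    return X, mu, cov


def _mc_overlap(rng, mu_a, cov_a, mu_b, cov_b, alpha, draws):
    d = len(mu_a)
    crit = chi2.ppf(alpha, df=d)
    x = rng.multivariate_normal(mu_a, cov_a, size=draws, method="cholesky")
    delta = x - mu_b
    sol = np.linalg.solve(cov_b, delta.T)
    maha = np.einsum("ij,ji->i", delta, sol)
    return float((maha <= crit).mean())


def _niw_draw(rng, X):
    """One (mu, Sigma) draw from the noninformative NIW posterior:
    Sigma ~ InvWishart(n-1, S), mu | Sigma ~ N(xbar, Sigma/n)."""
    n, d = X.shape
    xbar = X.mean(axis=0)
    S = (X - xbar).T @ (X - xbar)
    df = n - 1
    # inverse-Wishart via Bartlett decomposition of Wishart(df, S^-1)
    chol_Sinv = np.linalg.cholesky(np.linalg.inv(S))
    A = np.zeros((d, d))
    A[np.diag_indices(d)] = np.sqrt(rng.chisquare(df - np.arange(d)))
    A[np.tril_indices(d, -1)] = rng.standard_normal(d * (d - 1) // 2)
    W_chol = chol_Sinv @ A
    sigma = np.linalg.inv(W_chol @ W_chol.T)
    mu = rng.multivariate_normal(xbar, sigma / n, method="cholesky")
    return mu, sigma


def niche_overlap(tbl: pd.DataFrame, label_a: str, label_b: str,
                  alpha: float = 0.95, draws: int = 10_000,
                  estimator: str = "bayesian", posterior_draws: int = 1000,
                  seed: int = 0, label_col: str = "label") -> OverlapResult:
    """Directional niche overlap between two labels' climate clouds.

    plug-in: overlap(A->B) = P(X in region_B), X ~ N(mu_A, Sigma_A) with
    sample moments, via ``draws`` Monte Carlo points. bayesian: for each of
    ``posterior_draws`` NIW posterior draws per label, the overlap is
    estimated with ``draws // posterior_draws`` points (at least 100); the
    posterior mean and the central 95% interval are reported.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    Xa, mu_a, cov_a = _fit(tbl, label_col, label_a)
    Xb, mu_b, cov_b = _fit(tbl, label_col, label_b)

    if estimator == "plugin":
        ab = _mc_overlap(rng, mu_a, cov_a, mu_b, cov_b, alpha, draws)
        ba = _mc_overlap(rng, mu_b, cov_b, mu_a, cov_a, alpha, draws)
        return OverlapResult(label_a, label_b, ab, ba, alpha=alpha,
                             estimator="plugin", draws=draws)
    if estimator != "bayesian":
        raise ValueError("estimator must be 'plugin' or 'bayesian'")

    per = max(100, draws // posterior_draws)
    ab_s, ba_s = np.empty(posterior_draws), np.empty(posterior_draws)
    for k in range(posterior_draws):
        ma, Sa = _niw_draw(rng, Xa)
        mb, Sb = _niw_draw(rng, Xb)
        ab_s[k] = _mc_overlap(rng, ma, Sa, mb, Sb, alpha, per)
        ba_s[k] = _mc_overlap(rng, mb, Sb, ma, Sa, alpha, per)
    q = lambda v: (float(np.quantile(v, 0.025)), float(np.quantile(v, 0.975)))
    return OverlapResult(label_a, label_b, float(ab_s.mean()), float(ba_s.mean()),
                         q(ab_s), q(ba_s), alpha=alpha,
                         estimator="bayesian", draws=per * posterior_draws)
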