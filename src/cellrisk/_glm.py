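"""Regression utilities: logistic fits with a penalized fallback, Nagelkerke
R-squared, and Benjamini-Hochberg wrappers used across modules."""

from __future__ import annotations

import warnings

import numpy as np
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests


class LogitFit:
    __slots__ = ("params", "bse", "pvalues", "llf", "llnull", "method")

    def __init__(self, params, bse, pvalues, llf, llnull, method):
        self.params = params
        self.bse = bse
        self.pvalues = pvalues
        self.llf = llf
        self.llnull = llnull
        self.method = method


def fit_logit(X: np.ndarray, y: np.ndarray, max_abs_beta: float = 15.0) -> LogitFit:
    """Maximum-likelihood logistic fit with a Firth-penalized fallback.

    Falls back when the MLE does not converge or any coefficient runs away
    (quasi-complete separation). The fallback is flagged via ``method``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        if res.mle_retvals.get("converged", False) and np.all(
            np.abs(res.params) < max_abs_beta
        ) and np.all(np.isfinite(res.bse)):
            ll0 = _null_llf(y)
            return LogitFit(res.params, res.bse, res.pvalues, res.llf, ll0, "logit")
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        pass
    except Exception:  # statsmodels raises various errors on separation
        pass
    return firth_logit(X, y)


def firth_logit(
    X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8
) -> LogitFit:
    """Firth's bias-reduced logistic regression (Jeffreys-prior penalty).

    Finite estimates exist even under complete separation; used as the
    documented fallback for the enrichment and stratification regressions.
    """
    from scipy import stats as sps

    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        XtW = X.T * w
        info = XtW @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(info)
        # hat diagonal of the weighted design
        h = np.einsum("ij,jk,ik->i", X * w[:, None], info_inv, X)
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        beta_new = beta + step
        if np.max(np.abs(step)) < tol:
            beta = beta_new
            break
        beta = beta_new
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1 - mu)
    info = (X.T * w) @ X
    cov = np.linalg.pinv(info)
    bse = np.sqrt(np.diag(cov))
    zvals = beta / bse
    pvals = 2 * sps.norm.sf(np.abs(zvals))
    llf = float(np.sum(y * np.log(mu + 1e-300) + (1 - y) * np.log(1 - mu + 1e-300)))
    return LogitFit(beta, bse, pvals, llf, _null_llf(y), "firth")


def _null_llf(y: np.ndarray) -> float:
    p = y.mean()
    if p in (0.0, 1.0):
        return 0.0
    n = len(y)
    return float(n * (p * np.log(p) + (1 - p) * np.log(1 - p)))


def nagelkerke_r2(llf: float, llnull: float, n: int) -> float:
    """Nagelkerke pseudo R-squared from fitted and null log-likelihoods."""
    cox_snell = 1.0 - np.exp(2.0 * (llnull - llf) / n)
    max_r2 = 1.0 - np.exp(2.0 * llnull / n)
    if max_r2 <= 0:
        return 0.0
    return float(cox_snell / max_r2)


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def bh_flags(p: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    return multipletests(np.asarray(p, dtype=float), alpha=alpha, method="fdr_bh")[0]
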