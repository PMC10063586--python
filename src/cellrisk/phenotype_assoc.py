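"""Covariate-adjusted association of polygenic scores with phenotypes.

Quantitative phenotypes use ordinary least squares on the standardized score
(and standardized phenotype), adjusted for age, gender and disease duration;
binary outcomes (e.g. relapse within an interval) use logistic regression.
Multiple testing across the phenotype x score-universe grid is controlled by
Benjamini-Hochberg (Bonferroni available).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._glm import bh_flags, fit_logit
from .models import PhenotypeAssocResult


def _standardize(x: np.ndarray) -> tuple[np.ndarray, float]:
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("zero-variance input")
    return (x - np.mean(x)) / sd, sd


def _complete_cases(*arrays) -> np.ndarray:
    ok = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        m = np.asarray(a, dtype=float)
        if m.ndim == 1:
            ok &= ~np.isnan(m)
        else:
            ok &= ~np.isnan(m).any(axis=1)
    return ok


def assoc_linear(
    score: np.ndarray,
    phenotype: np.ndarray,
    covariates: pd.DataFrame | None = None,
    phenotype_name: str = "phenotype",
    universe: str = "combined",
) -> PhenotypeAssocResult:
    """OLS of the standardized phenotype on the standardized score plus
    covariates; beta is the score coefficient and R2 the incremental R2 over
    the covariates-only model."""
    score = np.asarray(score, dtype=float)
    phenotype = np.asarray(phenotype, dtype=float)
    cov = covariates.to_numpy(dtype=float) if covariates is not None else np.empty((len(score), 0))
    ok = _complete_cases(score, phenotype, cov)
    score, phenotype, cov = score[ok], phenotype[ok], cov[ok]
    n = len(score)
    zs, score_sd = _standardize(score)
    zp, pheno_sd = _standardize(phenotype)
    Xc = np.column_stack([np.ones(n), cov])
    Xf = np.column_stack([Xc, zs])
    full = sm.OLS(zp, Xf).fit()
    null = sm.OLS(zp, Xc).fit()
    beta = float(full.params[-1])
    return PhenotypeAssocResult(
        phenotype=phenotype_name,
        universe=universe,
        beta=beta,
        beta_raw=beta * pheno_sd / score_sd,
        se=float(full.bse[-1]),
        r2_incremental=float(max(full.rsquared - null.rsquared, 0.0)),
        p=float(full.pvalues[-1]),
        n=n,
        model="linear",
    )


def assoc_binary(
    score: np.ndarray,
    outcome: np.ndarray,
    covariates: pd.DataFrame | None = None,
    phenotype_name: str = "outcome",
    universe: str = "combined",
) -> PhenotypeAssocResult:
    """Logistic regression of a binary outcome on the standardized score;
    beta is the log-odds per SD of score. Separation falls back to the
    Firth-penalized fit (flagged via the model field)."""
    score = np.asarray(score, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    cov = covariates.to_numpy(dtype=float) if covariates is not None else np.empty((len(score), 0))
    ok = _complete_cases(score, outcome, cov)
    score, outcome, cov = score[ok], outcome[ok], cov[ok]
    if len(np.unique(outcome)) < 2:
        raise ValueError("outcome must contain both classes")
    n = len(score)
    zs, score_sd = _standardize(score)
    Xf = np.column_stack([np.ones(n), cov, zs])
    fit = fit_logit(Xf, outcome)
    from ._glm import nagelkerke_r2

    fit_cov = fit_logit(np.column_stack([np.ones(n), cov]), outcome)
    r2 = max(
        nagelkerke_r2(fit.llf, fit.llnull, n) - nagelkerke_r2(fit_cov.llf, fit_cov.llnull, n),
        0.0,
    )
    beta = float(fit.params[-1])
    return PhenotypeAssocResult(
        phenotype=phenotype_name,
        universe=universe,
        beta=beta,
        beta_raw=beta / score_sd,
        se=float(fit.bse[-1]),
        r2_incremental=r2,
        p=float(fit.pvalues[-1]),
        n=n,
        model="logistic" if fit.method == "logit" else "logistic_firth",
    )


def multiple_testing(
    results: list[PhenotypeAssocResult], alpha: float = 0.05, method: str = "bh"
) -> list[PhenotypeAssocResult]:
    """Flag results significant after correction across the grid (in place)."""
    if not results:
        raise ValueError("no results to correct")
    p = np.array([r.p for r in results])
    if method == "bh":
        flags = bh_flags(p, alpha)
    elif method == "bonferroni":
        flags = p < alpha / len(p)
    else:
        raise ValueError(f"unknown method {method!r}")
    for r, f in zip(results, flags):
        r.significant_after_correction = bool(f)
    return results


def results_to_frame(results: list[PhenotypeAssocResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "phenotype": r.phenotype,
                "universe": r.universe,
                "beta": r.beta,
                "beta_raw": r.beta_raw,
                "se": r.se,
                "r2_incremental": r.r2_incremental,
                "p": r.p,
                "n": r.n,
                "model": r.model,
                "significant_after_correction": r.significant_after_correction,
            }
            for r in results
        ]
    )
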