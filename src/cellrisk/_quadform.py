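"""Survival function of a weighted sum of independent 1-df chi-squares.

Q = sum_i lambda_i * chi2_1. The body of the distribution is computed with
Ruben's series — an exact representation of Q as a mixture of central
chi-squares with positive weights, so the truncation error is bounded by the
unaccumulated mixture mass. Very small tail probabilities use Kuonen's
saddlepoint approximation (good relative accuracy); Imhof's characteristic-
function inversion is kept as a fallback when the series converges too
slowly. Equal weights reduce to an ordinary scaled chi-square, handled
exactly.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, optimize
from scipy import stats as sps

_TINY = np.finfo(float).tiny


def wchi2_sf(x: float, lam: np.ndarray) -> float:
    """P(Q > x) for Q = sum lambda_i chi2_1, lambda_i >= 0."""
    lam = np.asarray(lam, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0 or x <= 0:
        return 1.0
    # eigenvalues carrying a negligible share of the total mass only slow
    # the series down; dropping them shifts Q by < 1e-7 of its mean
    lam = np.sort(lam)[::-1]
    keep = np.cumsum(lam[::-1])[::-1] > 1e-7 * lam.sum()
    keep[0] = True
    lam = lam[keep]
    if np.allclose(lam, lam[0], rtol=1e-10):
        return float(sps.chi2.sf(x / lam[0], lam.size))
    p = _ruben_sf(x, lam)
    if np.isnan(p):
        p = _imhof_sf(x, lam)
    if p < 1e-11 or p > 1 - 1e-11:
        p_s = _saddlepoint_sf(x, lam)
        if np.isfinite(p_s):
            p = p_s
    return float(min(max(p, _TINY), 1.0))


def _ruben_sf(x: float, lam: np.ndarray, max_terms: int = 5000, tol: float = 1e-13) -> float:
    """Ruben (1962) series: Q ~ mixture over j of beta * chi2_{k+2j}."""
    k = lam.size
    beta = lam.min()
    d = 1.0 - beta / lam  # all in [0, 1)
    a = np.empty(max_terms)
    a[0] = np.prod(np.sqrt(beta / lam))
    b = np.empty(max_terms)  # b[m] = sum_i d_i^m, m >= 1
    dpow = np.ones_like(d)
    mass = a[0]
    j_stop = max_terms
    for j in range(1, max_terms):
        dpow *= d
        b[j] = dpow.sum()
        a[j] = 0.5 / j * np.dot(b[1 : j + 1][::-1], a[:j])
        mass += a[j]
        if 1.0 - mass < tol:
            j_stop = j + 1
            break
    else:
        return np.nan  # not converged; caller falls back to Imhof
    degrees = k + 2 * np.arange(j_stop)
    cdf = float(np.dot(a[:j_stop], sps.chi2.cdf(x / beta, degrees)))
    return 1.0 - cdf


def _imhof_sf(x: float, lam: np.ndarray) -> float:
    def theta(u):
        return 0.5 * np.sum(np.arctan(lam[:, None] * u), axis=0) - 0.5 * x * u

    def rho(u):
        return np.prod((1.0 + (lam[:, None] * u) ** 2) ** 0.25, axis=0)

    def integrand(u):
        u = np.atleast_1d(u)
        out = np.empty_like(u)
        small = u < 1e-12
        out[small] = 0.5 * (np.sum(lam) - x)  # limit of sin(theta)/(u rho)
        ub = u[~small]
        out[~small] = np.sin(theta(ub)) / (ub * rho(ub))
        return out if out.size > 1 else float(out[0])

    with np.errstate(over="ignore"):
        val, _ = integrate.quad(
            integrand, 0.0, np.inf, limit=500, epsabs=1e-12, epsrel=1e-9
        )
    return 0.5 + val / np.pi


def _saddlepoint_sf(x: float, lam: np.ndarray) -> float:
    lmax = lam.max()
    mean = lam.sum()
    if abs(x - mean) < 1e-10 * mean:
        return 0.5

    def kprime(z):
        return np.sum(lam / (1.0 - 2.0 * z * lam))

    upper = 1.0 / (2.0 * lmax)
    lo, hi = (-1e2 / mean, upper * (1 - 1e-10)) if x > mean else (-1e6 / mean, 0.0)
    try:
        zhat = optimize.brentq(lambda z: kprime(z) - x, lo, hi, xtol=1e-14)
    except ValueError:
        return np.nan
    k0 = -0.5 * np.sum(np.log1p(-2.0 * zhat * lam))
    kpp = 2.0 * np.sum(lam**2 / (1.0 - 2.0 * zhat * lam) ** 2)
    w = np.sign(zhat) * np.sqrt(max(2.0 * (zhat * x - k0), 0.0))
    v = zhat * np.sqrt(kpp)
    if w == 0 or v == 0:
        return 0.5
    return float(sps.norm.sf(w + np.log(v / w) / w))
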