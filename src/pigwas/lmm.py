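"""Weighted single-SNP linear mixed-model association scan.

Model per marker: ``y_c = 1*mu + x*g + Z*u + e`` with polygenic effect
``u ~ N(0, A sigma2_u)`` and heteroscedastic residual
``e ~ N(0, D sigma2_e)``, ``D = diag(1/w_i)`` (``w_i`` the reliability
weight of record i). Variance components are estimated once by REML on
the null model (no SNP) and held fixed across markers (two-stage
EMMAX/GRAMMAR-style scan); each marker is then tested by generalized
least squares with a two-sided t-test on n-2 degrees of freedom.

REML is solved exactly by profiling the likelihood over the variance
ratio ``lambda = sigma2_u / sigma2_e`` on the eigenbasis of the
weight-standardised relationship matrix, so the estimate is
deterministic and boundary cases (sigma2_u -> 0) are handled by
clamping at zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats


class VarianceEstimationError(RuntimeError):
    """Degenerate input to the REML variance-component estimator."""


def bonferroni_threshold(n_markers: int, alpha: float) -> float:
    """-log10 of the Bonferroni-corrected per-test significance level.

    ``-log10(alpha / n_markers)``: e.g. 37,060 markers at alpha=0.05
    gives 5.87, at 0.01 gives 6.57.
    """
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return float(-np.log10(alpha / n_markers))


_CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # 0.4549364...


def genomic_inflation_lambda(p_values) -> float:
    """Genomic-control inflation factor.

    ``lambda = median(qchisq(1 - p, 1)) / qchisq(0.5, 1)``; values near 1
    indicate a well-calibrated scan, values > 1 suggest uncorrected
    population or family structure.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / _CHI2_1_MEDIAN)


def _reml_profile(
    y: np.ndarray, w: np.ndarray, A: np.ndarray
) -> tuple[float, float]:
    """Exact REML of (sigma2_u, sigma2_e) for y = 1 mu + u + e.

    Standardise by sqrt(w) so the residual covariance becomes
    sigma2_e * I, eigendecompose W^{1/2} A W^{1/2} once, and maximise
    the 1-D REML profile likelihood over lambda = sigma2_u / sigma2_e.
    """
    n = len(y)
    sw = np.sqrt(w)
    ys = sw * y
    Xs = sw.reshape(-1, 1)  # intercept column, standardised
    As = (sw[:, None] * A) * sw[None, :]
    s, U = linalg.eigh(As)
    s = np.clip(s, 0.0, None)
    yr = U.T @ ys
    Xr = U.T @ Xs
    p = 1

    def neg_reml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        d = lam * s + 1.0
        Wd = 1.0 / d
        xtx = float(np.sum(Xr[:, 0] ** 2 * Wd))
        xty = float(np.sum(Xr[:, 0] * yr * Wd))
        beta = xty / xtx
        rss = float(np.sum((yr - Xr[:, 0] * beta) ** 2 * Wd))
        if rss <= 0:
            return np.inf
        s2e = rss / (n - p)
        ll = -0.5 * (
            (n - p) * np.log(s2e)
            + np.sum(np.log(d))
            + np.log(xtx)
            + (n - p)
        )
        return -ll

    grid = np.linspace(-12.0, 12.0, 49)
    vals = np.array([neg_reml(g) for g in grid])
    k = int(np.argmin(vals))
    if vals[0] <= vals[k] + 1e-9:
        # flat or boundary profile (e.g. A = I makes u and e exchangeable,
        # or A contributes nothing): parsimony tie-break at sigma2_u = 0
        lam = 0.0
    else:
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(neg_reml, bounds=(lo, hi), method="bounded")
        candidates = [(res.fun, float(np.exp(res.x))), (vals[k], float(np.exp(grid[k])))]
        _, lam = min(candidates)
        if lam <= np.exp(-11.5):
            lam = 0.0
    d = lam * s + 1.0
    Wd = 1.0 / d
    xtx = float(np.sum(Xr[:, 0] ** 2 * Wd))
    xty = float(np.sum(Xr[:, 0] * yr * Wd))
    beta = xty / xtx
    rss = float(np.sum((yr - Xr[:, 0] * beta) ** 2 * Wd))
    s2e = rss / (n - p)
    return lam * s2e, s2e


def estimate_null_variance_components(
    y, A: np.ndarray, weights=None
) -> tuple[float, float]:
    """REML (sigma2_u, sigma2_e) for the weighted null model (no SNP term)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    if A.shape != (n, n):
        raise ValueError("relationship matrix shape does not match phenotypes")
    if float(np.var(y)) == 0.0:
        raise VarianceEstimationError(
            "phenotype has zero variance; variance components are undefined"
        )
    s2u, s2e = _reml_profile(y, w, A)
    return max(s2u, 0.0), s2e


def single_snp_scan(
    y,
    genotypes: np.ndarray,
    sigma2_u: float,
    sigma2_e: float,
    A: np.ndarray | None = None,
    weights=None,
    block_size: int = 2000,
) -> pd.DataFrame:
    """GLS scan of each marker under V = A*sigma2_u + D*sigma2_e (fixed).

    Per marker the standard error is rescaled by the marker-specific
    weighted residual variance estimate (weighted RSS / (n - 2)), so
    with sigma2_u = 0 and unit weights the scan reduces exactly to the
    closed-form simple-regression t-test. Monomorphic markers get an
    undefined effect and p = 1 with ``monomorphic = True``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(genotypes, dtype=float)
    n, m = X.shape
    if np.isnan(X).any():
        raise ValueError("genotypes contain missing values; impute first")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    D = 1.0 / w
    V = np.diag(D * sigma2_e)
    if sigma2_u > 0:
        if A is None:
            raise ValueError("sigma2_u > 0 requires a relationship matrix")
        V = V + sigma2_u * A
    cf = linalg.cho_factor(V, lower=True)
    ones = np.ones(n)
    Vi1 = linalg.cho_solve(cf, ones)
    Viy = linalg.cho_solve(cf, y)
    a11 = float(ones @ Vi1)
    b1 = float(ones @ Viy)
    yy = float(y @ Viy)

    eff = np.empty(m)
    se = np.empty(m)
    tstat = np.empty(m)
    pvals = np.empty(m)
    mono = X.std(axis=0) == 0.0
    df = n - 2
    for start in range(0, m, block_size):
        sl = slice(start, min(start + block_size, m))
        Xb = X[:, sl]
        ViX = linalg.cho_solve(cf, Xb)
        a1x = Xb.T @ Vi1
        axx = np.einsum("ij,ij->j", Xb, ViX)
        bx = Xb.T @ Viy
        det = a11 * axx - a1x**2
        with np.errstate(divide="ignore", invalid="ignore"):
            g = (a11 * bx - a1x * b1) / det
            mu = (axx * b1 - a1x * bx) / det
            rss = yy - mu * b1 - g * bx
            s2m = rss / df
            var_g = s2m * a11 / det
            se[sl] = np.sqrt(var_g)
            eff[sl] = g
            tstat[sl] = g / se[sl]
    bad = mono | ~np.isfinite(tstat)
    tstat[bad] = 0.0
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=df)
    eff[bad] = np.nan
    se[bad] = np.nan
    tstat[bad] = np.nan
    pvals[bad] = 1.0
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "effect": eff,
            "se": se,
            "t": tstat,
            "p": pvals,
            "neg_log10_p": -np.log10(pvals),
            "monomorphic": bad,
        }
    )


class MixedModelGWAS:
    """Scikit-learn-style estimator for the weighted single-SNP LMM scan.

    Parameters
    ----------
    alpha_levels : tuple of float
        Genome-wide significance levels for Bonferroni thresholds.
    sigma2_u, sigma2_e : float or None
        If both are given, REML is skipped and these are used directly.

    Fitted attributes: ``sigma2_u_``, ``sigma2_e_``, ``results_``
    (per-marker DataFrame with effect/se/t/p/-log10 p and significance
    flags), ``lambda_gc_`` and ``thresholds_``.
    """

    def __init__(
        self,
        alpha_levels: tuple[float, ...] = (0.05, 0.01),
        sigma2_u: float | None = None,
        sigma2_e: float | None = None,
    ) -> None:
        self.alpha_levels = alpha_levels
        self.sigma2_u = sigma2_u
        self.sigma2_e = sigma2_e

    def get_params(self, deep: bool = True) -> dict:
        return {
            "alpha_levels": self.alpha_levels,
            "sigma2_u": self.sigma2_u,
            "sigma2_e": self.sigma2_e,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y, A: np.ndarray | None = None, weights=None, marker_map=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, m = X.shape
        if self.sigma2_u is not None and self.sigma2_e is not None:
            self.sigma2_u_, self.sigma2_e_ = float(self.sigma2_u), float(self.sigma2_e)
        else:
            if A is None:
                A = np.zeros((n, n))
            self.sigma2_u_, self.sigma2_e_ = estimate_null_variance_components(
                y, A, weights
            )
        res = single_snp_scan(
            y, X, self.sigma2_u_, self.sigma2_e_, A=A, weights=weights
        )
        self.thresholds_ = {
            a: bonferroni_threshold(m, a) for a in self.alpha_levels
        }
        for a, thr in self.thresholds_.items():
            res[f"significant_at_{a}"] = res["neg_log10_p"] > thr
        if marker_map is not None:
            res = pd.concat(
                [marker_map.reset_index(drop=True), res], axis=1
            )
        self.results_ = res
        self.lambda_gc_ = genomic_inflation_lambda(res["p"].to_numpy())
        self.n_markers_ = m
        return self
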