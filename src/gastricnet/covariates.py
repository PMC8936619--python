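"""Cohort-level covariate statistics for coupling strength.

Robust (Huber) regressions of mean coupling strength on continuous
covariates, unpaired t tests for group factors, default-prior (JZS) and
BIC-approximated Bayes factors, Bonferroni / Benjamini-Hochberg p-value
adjustment, noncentral-t power and sample-size computation, region-wise
covariate scans with FDR correction, and voxelwise group GLMs with
max-statistic permutation FWE control.

Bayes factors are reported as BF10 (alternative over null); values below
1/3 are conventionally read as substantial evidence for the null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import integrate, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "robust_regression",
    "two_sample_t",
    "jzs_bf_two_sample",
    "bic_bf",
    "adjust_pvalues",
    "power_sample_size",
    "roi_covariate_scan",
    "voxelwise_glm",
]

DEFAULT_CAUCHY_SCALE = np.sqrt(2.0) / 2.0


@dataclass
class TestResult:
    """A single covariate test: estimate, t, df, p values, Bayes factor."""

    estimate: float
    t_value: float
    df: int
    p_uncorrected: float
    p_corrected: float | None = None
    bf10: float | None = None
    method: str = ""


class ConvergenceError(RuntimeError):
    pass


def robust_regression(y, x, max_iter: int = 50) -> TestResult:
    """Huber-weighted (tuning 1.345) IRLS regression of y on [1, x].

    The slope t statistic uses the robust standard error with df = n - 2
    and a two-sided t reference.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.size
    if n < 4:
        raise ValueError("need n >= 4 observations")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    X = sm.add_constant(x)
    model = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345))
    res = model.fit(maxiter=max_iter)
    if not np.all(np.isfinite(res.params)) or not np.all(np.isfinite(res.bse)):
        raise ConvergenceError(f"IRLS produced non-finite estimates within {max_iter} iterations")
    slope = float(res.params[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t_val = slope / float(res.bse[1])
    if np.isnan(t_val):
        t_val = 0.0 if slope == 0 else np.sign(slope) * np.inf
    df = n - 2
    p = 2.0 * float(stats.t.sf(abs(t_val), df))
    return TestResult(estimate=slope, t_value=t_val, df=df, p_uncorrected=p, method="robust_regression")


def two_sample_t(a, b) -> TestResult:
    """Unpaired pooled-variance t test, two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    est = float(a.mean() - b.mean())
    t_val = est / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
    p = 2.0 * float(stats.t.sf(abs(t_val), df))
    return TestResult(estimate=est, t_value=float(t_val), df=df, p_uncorrected=p, method="two_sample_t")


def jzs_bf_two_sample(
    t: float, n1: int, n2: int, scale: float = DEFAULT_CAUCHY_SCALE
) -> float:
    """Default-prior (JZS) Bayes factor BF10 for a two-sample t statistic.

    Cauchy prior with the given scale on the standardized effect and a
    Jeffreys prior on the variance; the marginal likelihood under the
    alternative integrates over the inverse-chi^2 mixing parameter g
    numerically.  Effective sample size N = n1 n2 / (n1 + n2),
    df = n1 + n2 - 2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    N = n1 * n2 / (n1 + n2)
    v = n1 + n2 - 2
    r2 = scale * scale
    t2 = t * t

    def integrand(g):
        a = 1.0 + N * g * r2
        return (
            a**-0.5
            * (1.0 + t2 / (a * v)) ** (-(v + 1) / 2.0)
            * (2.0 * np.pi) ** -0.5
            * g**-1.5
            * np.exp(-1.0 / (2.0 * g))
        )

    num, err = integrate.quad(integrand, 0.0, np.inf, limit=200)
    if not np.isfinite(num) or (num > 0 and err / num > 1e-4):
        raise RuntimeError(f"JZS integration failed: value={num}, abserr={err}")
    den = (1.0 + t2 / v) ** (-(v + 1) / 2.0)
    return float(num / den)


def _ols_bic(y: np.ndarray, X: np.ndarray) -> float:
    n = y.size
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    k = X.shape[1]
    # Gaussian ML: -2 logL = n log(RSS/n) + const; the constant cancels in BFs
    return n * np.log(rss / n) + k * np.log(n)


def bic_bf(y, x) -> float:
    """BIC-approximated BF10 for a slope: intercept+slope vs intercept only.

    BF01 ~ exp((BIC_full - BIC_null) / 2) from Gaussian OLS likelihoods;
    the returned BF10 is its reciprocal.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.size < 4:
        raise ValueError("need n >= 4 observations")
    n = y.size
    X_full = np.column_stack([np.ones(n), x])
    X_null = np.ones((n, 1))
    bf01 = np.exp((_ols_bic(y, X_full) - _ols_bic(y, X_null)) / 2.0)
    return float(1.0 / bf01)


def adjust_pvalues(p, method: str = "benjamini_hochberg") -> np.ndarray:
    """Multiple-comparison adjustment: Bonferroni or Benjamini-Hochberg."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p values must lie in (0, 1]")
    key = {"bonferroni": "bonferroni", "benjamini_hochberg": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError(f"unknown method {method!r}")
    return multipletests(p, method=key)[1]


def power_sample_size(
    d: float, alpha: float, power: float, design: str = "one_sample", max_n: int = 1_000_000
) -> int:
    """Smallest one-sample n achieving the target power (noncentral t).

    Finds the smallest n with
    P(T_{df=n-1, ncp=d sqrt(n)} > t_{1-alpha, n-1}) >= power, for a
    one-sided test at level ``alpha``.
    """
    if design != "one_sample":
        raise ValueError("only the one_sample design is implemented")
    if not (0 < alpha < 0.5):
        raise ValueError("alpha must lie in (0, 0.5)")
    if not (0 < power < 1):
        raise ValueError("power must lie in (0, 1)")
    if d <= 0:
        raise ValueError("d must be positive")
    for n in range(2, max_n + 1):
        tcrit = stats.t.ppf(1 - alpha, n - 1)
        if stats.nct.sf(tcrit, n - 1, d * np.sqrt(n)) >= power:
            return n
    raise ValueError(f"target power unreachable within n <= {max_n}")


def roi_covariate_scan(
    coupling_by_roi: pd.DataFrame,
    covariates: pd.DataFrame,
    covariate_names: list[str] | None = None,
) -> pd.DataFrame:
    """Robust regression of per-ROI coupling on each covariate, with FDR.

    Benjamini-Hochberg correction is applied across ROIs *within* each
    covariate (the number of tests per scan is the number of ROIs).  ROIs
    with fewer than 4 complete cases for a covariate are skipped with a
    warning.  Returns a tidy table with one row per (covariate, ROI).
    """
    if covariate_names is None:
        covariate_names = [c for c in covariates.columns if np.issubdtype(covariates[c].dtype, np.number)]
    rows = []
    for cov in covariate_names:
        x_all = covariates[cov].to_numpy(dtype=float)
        complete = np.isfinite(x_all)
        block = []
        for roi in coupling_by_roi.columns:
            y_all = coupling_by_roi[roi].to_numpy(dtype=float)
            ok = complete & np.isfinite(y_all)
            if ok.sum() < 4:
                warnings.warn(f"ROI {roi!r}: fewer than 4 complete cases for {cov!r}; skipped")
                continue
            res = robust_regression(y_all[ok], x_all[ok])
            block.append(
                {
                    "covariate": cov,
                    "roi": roi,
                    "n": int(ok.sum()),
                    "estimate": res.estimate,
                    "t": res.t_value,
                    "df": res.df,
                    "p": res.p_uncorrected,
                }
            )
        if block:
            padj = adjust_pvalues([r["p"] for r in block], "benjamini_hochberg")
            for r, pa in zip(block, padj):
                r["p_fdr"] = pa
            rows.extend(block)
    return pd.DataFrame(rows)


def voxelwise_glm(
    coupling_maps: np.ndarray,
    design: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
):
    """OLS per voxel with max-|t| permutation FWE p values per regressor.

    Covariate columns are mean-centered and an intercept is prepended.
    FWE control uses Freedman-Lane residual permutation: for each tested
    regressor, data are refit after permuting the residuals of the reduced
    model, and the maximum |t| over voxels is recorded per permutation.
    Returns ``(t_maps, p_fwe)`` with shapes (k, voxels).
    """
    Y = np.asarray(coupling_maps, dtype=float)
    n = Y.shape[0]
    Y = Y.reshape(n, -1)
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    X = X - X.mean(axis=0, keepdims=True)
    X = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient after mean-centering")
    k = X.shape[1]
    df = n - k
    rng = np.random.default_rng(seed)

    def fit_t(Xd, Yd):
        pinv = np.linalg.pinv(Xd)
        beta = pinv @ Yd
        resid = Yd - Xd @ beta
        sigma2 = np.sum(resid**2, axis=0) / df
        xtx_inv = np.linalg.inv(Xd.T @ Xd)
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
            return beta / se

    t_obs = fit_t(X, Y)
    p_fwe = np.ones_like(t_obs)
    for j in range(k):
        Z = np.delete(X, j, axis=1)
        hz = Z @ np.linalg.pinv(Z)
        fitted = hz @ Y
        resid = Y - fitted
        max_null = np.empty(n_perm)
        for p in range(n_perm):
            perm = rng.permutation(n)
            Yp = fitted + resid[perm]
            tp = fit_t(X, Yp)[j]
            max_null[p] = np.nanmax(np.abs(tp))
        p_fwe[j] = (1 + np.sum(max_null[None, :] >= np.abs(t_obs[j])[:, None], axis=1)) / (n_perm + 1)
    return t_obs, p_fwe
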