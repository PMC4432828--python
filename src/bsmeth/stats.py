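"""Shared statistical tests and the Gaussian-mixture EM engine.

The 2x2 tests, t-tests and OLS are the standard procedures (Fisher's exact
two-sided p by the minimum-likelihood rule, chi-square with Yates'
continuity correction, ratio-paired t as a paired t on log10 ratios, Welch
two-sample t, ordinary least squares with the slope t-test). The Yates
statistic is computed directly from its formula, with the correction floored
so |O-E|-0.5 never goes negative; everything else delegates to scipy.

``gaussian_em`` fits a 1- or 2-component univariate Gaussian mixture by
expectation-maximization with multiple seeded restarts; it is the engine
behind the one- vs two-population verdict on per-read CpG frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import logsumexp


class StatError(ValueError):
    """Invalid input for a statistical procedure."""


def _as_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise StatError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise StatError("contingency table cells must be non-negative")
    if t.sum() <= 0:
        raise StatError("contingency table is empty")
    return t


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p (minimum-likelihood method)."""
    t = _as_table(table)
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def chi_square_yates(table) -> tuple[float, float]:
    """Chi-square test with Yates' continuity correction on a 2x2 table.

    statistic = sum (max(|O-E| - 0.5, 0))^2 / E, p from the 1-df tail.
    """
    t = _as_table(table)
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    expected = row @ col / t.sum()
    if (expected <= 0).any():
        raise StatError("zero expected count; test undefined")
    adj = np.maximum(np.abs(t - expected) - 0.5, 0.0)
    stat = float((adj**2 / expected).sum())
    return stat, float(sps.chi2.sf(stat, df=1))


def ratio_paired_t(values_a, values_b) -> tuple[float, float]:
    """Ratio-paired t-test: paired t on log10-transformed pairs."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise StatError("paired samples must be equal-length 1-d arrays")
    if len(a) < 2:
        raise StatError("need at least 2 pairs")
    if (a <= 0).any() or (b <= 0).any():
        raise StatError("ratio-paired t requires strictly positive values")
    d = np.log10(a) - np.log10(b)
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            return 0.0, 1.0
        raise StatError("zero variance of log-ratios with nonzero mean; p undefined")
    res = sps.ttest_rel(np.log10(a), np.log10(b))
    return float(res.statistic), float(res.pvalue)


def two_sample_t(sample_a, sample_b, welch: bool = True) -> tuple[float, float]:
    """Two-sample t-test; Welch (unequal variances) by default."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatError("need n >= 2 in each sample")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0  # no variance, no difference: p = 1 by convention
        raise StatError("zero variance in both samples with unequal means")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


@dataclass
class OLSFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    stderr: float
    n: int


def ols_fit(x, y) -> OLSFit:
    """Ordinary least squares of y on x with R^2 and the two-sided slope test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise StatError("need >= 3 paired observations")
    if np.var(x) == 0:
        raise StatError("x has zero variance; slope undefined")
    if np.var(y) == 0:
        return OLSFit(0.0, float(y[0]), 0.0, 1.0, 0.0, len(x))
    res = sps.linregress(x, y)
    return OLSFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        stderr=float(res.stderr),
        n=len(x),
    )


# ---------------------------------------------------------------------------
# Gaussian mixture EM


@dataclass
class EMFit:
    """Maximum-likelihood univariate Gaussian mixture parameters."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    n_iter: int
    converged: bool
    ll_trace: list = None  # type: ignore[assignment]  # per-iteration LLs, best run

    @property
    def n_parameters(self) -> int:
        return 3 * self.k - 1  # k means, k SDs, k-1 free weights


def _mixture_loglik(x, weights, means, sds) -> float:
    log_comp = (
        np.log(weights)[:, None]
        + sps.norm.logpdf(x[None, :], means[:, None], sds[:, None])
    )
    return float(logsumexp(log_comp, axis=0).sum())


def gaussian_em(
    values,
    k: int,
    restarts: int = 10,
    seed=None,
    tol: float = 1e-8,
    max_iter: int = 500,
    min_component_count: float = 5.0,
) -> EMFit:
    """Fit a k-component univariate Gaussian mixture by maximum likelihood.

    k=1 is closed form (sample moments). k=2 runs EM from ``restarts``
    seeded initialisations (a k-means-style split of the sorted data at a
    random quantile), iterating until the relative log-likelihood change
    falls below ``tol`` or ``max_iter`` is reached, and keeps the best run.
    Component SDs are floored at 1e-4 of the data range. Because the
    unconstrained mixture likelihood is unbounded (a component can spike on
    a handful of points), a k=2 solution is admissible only if each
    component's effective count is at least ``min_component_count``; the
    best admissible restart wins, falling back to the best overall if none
    is admissible.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if k not in (1, 2):
        raise StatError(f"k must be 1 or 2, got {k}")
    if n < 10 * k:
        raise StatError(f"need n >= {10 * k} for k={k}, got {n}")
    data_range = float(x.max() - x.min())
    sd_floor = max(1e-4 * data_range, 1e-12)
    if data_range == 0:
        warnings.warn("zero-variance input; SD floored", stacklevel=2)
        sd_floor = 1e-8

    if k == 1:
        mu, sd = float(x.mean()), max(float(x.std(ddof=0)), sd_floor)
        ll = _mixture_loglik(x, np.array([1.0]), np.array([mu]), np.array([sd]))
        return EMFit(1, np.array([1.0]), np.array([mu]), np.array([sd]), ll, 0, True)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xs = np.sort(x)
    best: EMFit | None = None
    fallback: EMFit | None = None
    for _ in range(max(restarts, 1)):
        q = rng.uniform(0.2, 0.8)
        split = int(np.clip(round(q * n), 1, n - 1))
        lo, hi = xs[:split], xs[split:]
        weights = np.array([split / n, 1 - split / n])
        means = np.array([lo.mean(), hi.mean()])
        sds = np.maximum([lo.std(ddof=0), hi.std(ddof=0)], sd_floor)
        trace: list[float] = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            log_comp = (
                np.log(weights)[:, None]
                + sps.norm.logpdf(x[None, :], means[:, None], sds[:, None])
            )
            log_norm = logsumexp(log_comp, axis=0)
            ll = float(log_norm.sum())
            trace.append(ll)
            resp = np.exp(log_comp - log_norm[None, :])
            nk = resp.sum(axis=1)
            nk = np.maximum(nk, 1e-300)
            weights = nk / n
            means = (resp @ x) / nk
            var = (resp @ (x**2)) / nk - means**2
            sds = np.maximum(np.sqrt(np.maximum(var, 0.0)), sd_floor)
            if len(trace) > 1 and trace[-1] - trace[-2] < tol * max(abs(ll), 1.0):
                converged = True
                break
        ll = _mixture_loglik(x, weights, means, sds)
        order = np.argsort(means)
        fit = EMFit(
            2, weights[order], means[order], sds[order], ll, it, converged, trace
        )
        admissible = weights.min() * n >= min_component_count
        if admissible:
            if best is None or fit.log_likelihood > best.log_likelihood:
                best = fit
        elif fallback is None or fit.log_likelihood > fallback.log_likelihood:
            fallback = fit
    if best is None:
        best = fallback
    assert best is not None
    return best


def aicc(log_likelihood: float, n_parameters: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion."""
    p = n_parameters
    if n - p - 1 <= 0:
        return float("inf")
    return -2.0 * log_likelihood + 2 * p + 2 * p * (p + 1) / (n - p - 1)
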