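"""Per-k-mer inference: preferential affinity, contrast, and specificity.

Three Q-values are attached to every RC-collapsed k-mer of a
variant-vs-reference comparison:

- ``affinityQ``: is the k-mer preferentially bound at all?  The across-
  k-mer score distribution is modeled as a normal-exponential (normexp)
  convolution - normal measurement floor plus exponential true-binding
  component - fitted by maximum likelihood; each k-mer's exponential
  component is tested against zero with a one-sided normal p-value.
- ``contrastQ``: does the variant bind the k-mer differently?  The
  difference of the two affinity scores is tested with a variance that
  subtracts twice the estimated covariance (both alleles are scored on
  the same probes).
- ``specificityQ``: does the difference deviate from the global trend?
  A cross-k-mer trend of contrast difference vs reference affinity is
  fitted with weighted B-spline regressions; two candidate trends come
  from a per-bin two-component normal mixture (upper/lower clusters),
  and the trend with the smaller mean |residual| over the top half of
  k-mers by reference affinity is selected.  Residuals from the selected
  trend are tested with the contrast variance.

All p-values are Benjamini-Hochberg adjusted across k-mers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import BSpline
from scipy.special import log_ndtr
from statsmodels.stats.multitest import multipletests

Q_STRICT = 1e-6
MIN_KMERS_FOR_FIT = 1000


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up Q-values; NaN p-values propagate as NaN."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        if (p[ok] < 0).any() or (p[ok] > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# preferential affinity (normexp)


@dataclass
class NormexpParams:
    mu: float
    sigma: float
    alpha: float  # mean of the exponential signal component
    loglik: float = np.nan
    converged: bool = True


def normexp_logpdf(x: np.ndarray, mu: float, sigma: float, alpha: float) -> np.ndarray:
    """Log density of X = Normal(mu, sigma^2) + Exponential(mean alpha)."""
    z = (x - mu) / sigma - sigma / alpha
    return -np.log(alpha) + (mu - x) / alpha + sigma ** 2 / (2 * alpha ** 2) + log_ndtr(z)


def fit_normexp(x: np.ndarray, n_starts: int = 4) -> NormexpParams:
    """Maximum-likelihood normexp fit with moment-based multi-start.

    Optimized over (mu, log sigma, log alpha); raises if no start
    converges to a finite optimum.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    m, s = float(x.mean()), float(x.std())
    m3 = float(np.mean((x - m) ** 3))
    alpha_starts = [0.1 * s, 0.5 * s, s, 2.0 * s][:n_starts]
    if m3 > 0:
        alpha_starts.append((m3 / 2.0) ** (1.0 / 3.0))

    def nll(theta: np.ndarray) -> float:
        mu, log_sigma, log_alpha = theta
        val = -np.sum(normexp_logpdf(x, mu, np.exp(log_sigma), np.exp(log_alpha)))
        return val if np.isfinite(val) else 1e12

    best = None
    diagnostics = []
    for a0 in alpha_starts:
        sigma0 = max(np.sqrt(max(s ** 2 - a0 ** 2, (0.1 * s) ** 2)), 1e-6 * s)
        theta0 = np.array([m - a0, np.log(sigma0), np.log(max(a0, 1e-6 * s))])
        res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        diagnostics.append((a0, res.fun, res.success))
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(f"normexp MLE failed to converge; starts tried: {diagnostics}")
    mu, log_sigma, log_alpha = best.x
    return NormexpParams(
        mu=float(mu), sigma=float(np.exp(log_sigma)), alpha=float(np.exp(log_alpha)),
        loglik=float(-best.fun), converged=True,
    )


def normexp_signal(x: np.ndarray, params: NormexpParams) -> np.ndarray:
    """Posterior expected exponential component E[S | X = x] (closed form)."""
    mu_sf = x - params.mu - params.sigma ** 2 / params.alpha
    z = mu_sf / params.sigma
    # sigma * phi(z)/Phi(z), computed in log space for deep-left-tail stability
    log_ratio = stats.norm.logpdf(z) - log_ndtr(z)
    return mu_sf + params.sigma * np.exp(log_ratio)


def test_preferential_affinity(
    estimates: np.ndarray,
    min_kmers: int = MIN_KMERS_FOR_FIT,
    effect: str = "conditional_mean",
) -> tuple[pd.DataFrame, NormexpParams]:
    """Normexp-based preferential-affinity test across k-mers.

    p is the one-sided upper-tail probability of the score under the
    fitted normal noise component; the effect size is E[S|X=x]
    (or x - mu with effect="shift").
    """
    x = np.asarray(estimates, dtype=float)
    n_finite = int(np.isfinite(x).sum())
    if n_finite < min_kmers:
        raise ValueError(f"need >= {min_kmers} finite k-mer estimates, got {n_finite}")
    params = fit_normexp(x)
    z = (x - params.mu) / params.sigma
    p = stats.norm.sf(z)
    eff = normexp_signal(x, params) if effect == "conditional_mean" else x - params.mu
    return (
        pd.DataFrame({"estimate": x, "effect": eff, "p": p, "affinityQ": bh_adjust(p)}),
        params,
    )


# ---------------------------------------------------------------------------
# contrast


def test_contrast(
    ref_estimate: np.ndarray,
    ref_se: np.ndarray,
    var_estimate: np.ndarray,
    var_se: np.ndarray,
    covariance: np.ndarray,
    paired_var: np.ndarray | None = None,
    var_floor: float = 1e-12,
) -> pd.DataFrame:
    """Variant-minus-reference differential test with shared-probe covariance.

    `paired_var`, when given, is the direct per-k-mer variance of the mean
    paired probe difference; it floors the covariance-form variance, which
    can collapse when the estimated covariance overshoots.
    """
    d = np.asarray(var_estimate, float) - np.asarray(ref_estimate, float)
    var_d = np.asarray(var_se, float) ** 2 + np.asarray(ref_se, float) ** 2 - 2 * np.asarray(covariance, float)
    n_neg = int(np.sum(var_d < 0))
    if n_neg:
        warnings.warn(f"{n_neg} k-mer(s) had negative contrast variance before flooring")
    if paired_var is not None:
        var_d = np.maximum(var_d, np.asarray(paired_var, float))
    var_d = np.maximum(var_d, var_floor)
    z = d / np.sqrt(var_d)
    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {"contrast": d, "se": np.sqrt(var_d), "z": z, "p": p, "contrastQ": bh_adjust(p)}
    )


# ---------------------------------------------------------------------------
# specificity trend


def _bin_mixture_weights(
    x: np.ndarray, y: np.ndarray, n_bins: int, min_points: int,
    max_iter: int = 100, tol: float = 1e-8, var_floor: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Upper/lower cluster membership probabilities from per-bin 2-component EM.

    Bins are equal-width in x.  Bins with fewer than `min_points` points
    fall back to a single component (weight 1 to both trends).
    """
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    bin_ix = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
    w_upper = np.ones_like(y)
    w_lower = np.ones_like(y)
    for b in range(n_bins):
        sel = bin_ix == b
        yb = y[sel]
        if len(yb) < min_points:
            continue
        mu = np.array([np.quantile(yb, 0.25), np.quantile(yb, 0.75)])
        var = np.full(2, max(yb.var(), var_floor))
        pi = np.array([0.5, 0.5])
        prev = -np.inf
        for _ in range(max_iter):
            logp = (
                np.log(pi)[:, None]
                + stats.norm.logpdf(yb[None, :], mu[:, None], np.sqrt(var)[:, None])
            )
            tot = np.logaddexp(logp[0], logp[1])
            ll = tot.sum()
            gamma = np.exp(logp - tot[None, :])
            nk = gamma.sum(axis=1)
            pi = np.clip(nk / len(yb), 1e-6, 1 - 1e-6)
            mu = (gamma @ yb) / nk
            var = np.maximum((gamma @ (yb ** 2)) / nk - mu ** 2, var_floor)
            if abs(ll - prev) < tol * (abs(prev) + 1):
                break
            prev = ll
        upper_comp = int(np.argmax(mu))
        w_upper[sel] = gamma[upper_comp]
        w_lower[sel] = gamma[1 - upper_comp]
    return w_upper, w_lower


@dataclass
class TrendFit:
    """Selected B-spline trend of contrast difference vs reference affinity."""

    knots: np.ndarray
    coef_upper: np.ndarray
    coef_lower: np.ndarray
    selected: str            # "upper" or "lower"
    x_range: tuple[float, float]
    mean_abs_residual: dict  # trend label -> mean |residual| over top-50% k-mers
    degree: int = 3

    def _predict_one(self, coef: np.ndarray, x: np.ndarray) -> np.ndarray:
        lo, hi = self.x_range
        xc = np.clip(x, lo, hi)
        basis = BSpline.design_matrix(xc, self.knots, self.degree).toarray()
        y = basis @ coef
        # linear extrapolation beyond the fitted support
        eps = 1e-6 * (hi - lo)
        out_lo, out_hi = x < lo, x > hi
        if out_lo.any():
            b0 = BSpline.design_matrix(np.array([lo, lo + eps]), self.knots, self.degree).toarray() @ coef
            slope = (b0[1] - b0[0]) / eps
            y[out_lo] = b0[0] + slope * (x[out_lo] - lo)
        if out_hi.any():
            b1 = BSpline.design_matrix(np.array([hi - eps, hi]), self.knots, self.degree).toarray() @ coef
            slope = (b1[1] - b1[0]) / eps
            y[out_hi] = b1[1] + slope * (x[out_hi] - hi)
        return y

    def predict(self, x: np.ndarray, which: str | None = None) -> np.ndarray:
        coef = self.coef_upper if (which or self.selected) == "upper" else self.coef_lower
        return self._predict_one(coef, np.asarray(x, float))


def _spline_knots(x: np.ndarray, n_interior: int, degree: int) -> np.ndarray:
    interior = np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1])
    lo, hi = x.min(), x.max()
    return np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])


def fit_specificity_trend(
    ref_estimate: np.ndarray,
    contrast: np.ndarray,
    n_bins: int = 20,
    min_bin_points: int = 20,
    n_interior_knots: int = 5,
    min_kmers: int = MIN_KMERS_FOR_FIT,
) -> TrendFit:
    """Two-trend weighted B-spline fit to the contrast-vs-reference plot."""
    x = np.asarray(ref_estimate, float)
    d = np.asarray(contrast, float)
    ok = np.isfinite(x) & np.isfinite(d)
    if ok.sum() < min_kmers:
        raise ValueError(f"need >= {min_kmers} finite k-mers, got {int(ok.sum())}")
    xf, df_ = x[ok], d[ok]
    w_upper, w_lower = _bin_mixture_weights(xf, df_, n_bins, min_bin_points)
    degree = 3
    knots = _spline_knots(xf, n_interior_knots, degree)
    basis = BSpline.design_matrix(xf, knots, degree).toarray()

    def wls(w: np.ndarray) -> np.ndarray:
        sw = np.sqrt(w + 1e-12)
        coef, *_ = np.linalg.lstsq(basis * sw[:, None], df_ * sw, rcond=None)
        return coef

    coef_upper, coef_lower = wls(w_upper), wls(w_lower)
    trend = TrendFit(
        knots=knots, coef_upper=coef_upper, coef_lower=coef_lower,
        selected="upper", x_range=(float(xf.min()), float(xf.max())),
        mean_abs_residual={},
    )
    top = xf >= np.quantile(xf, 0.5)
    scores = {}
    for label in ("upper", "lower"):
        pred = trend.predict(xf[top], which=label)
        scores[label] = float(np.mean(np.abs(df_[top] - pred)))
    trend.selected = min(scores, key=scores.get)
    trend.mean_abs_residual = scores
    return trend


def test_specificity(
    contrast_result: pd.DataFrame,
    trend: TrendFit,
    ref_estimate: np.ndarray,
) -> pd.DataFrame:
    """Deviation-from-trend test; reuses the contrast variance per k-mer."""
    x = np.asarray(ref_estimate, float)
    lo, hi = trend.x_range
    outside = (x < lo) | (x > hi)
    if outside.any():
        warnings.warn(f"{int(outside.sum())} k-mer(s) outside trend support; extrapolated linearly")
    fitted = trend.predict(x)
    residual = contrast_result["contrast"].to_numpy() - fitted
    z = residual / contrast_result["se"].to_numpy()
    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "trend": fitted,
            "contrastResidual": residual,
            "z": z,
            "p": p,
            "specificityQ": bh_adjust(p),
            "extrapolated": outside,
        }
    )


def run_kmer_tests(
    kmer_fit,
    reference: str,
    variant: str,
    kmer_strings: list,
    n_bins: int = 20,
    min_kmers: int = MIN_KMERS_FOR_FIT,
) -> tuple[pd.DataFrame, dict]:
    """Full per-k-mer test stack for one variant-vs-reference comparison.

    Returns the combined results table (one row per canonical k-mer) and
    a dict of fitted model objects (normexp params per allele, trend).
    """
    aff_ref, params_ref = test_preferential_affinity(kmer_fit.estimate[reference], min_kmers=min_kmers)
    aff_var, params_var = test_preferential_affinity(kmer_fit.estimate[variant], min_kmers=min_kmers)
    pv = kmer_fit.paired_var.get((reference, variant), kmer_fit.paired_var.get((variant, reference)))
    contrast = test_contrast(
        kmer_fit.estimate[reference], kmer_fit.se[reference],
        kmer_fit.estimate[variant], kmer_fit.se[variant],
        kmer_fit.pair_covariance(reference, variant),
        paired_var=pv,
    )
    trend = fit_specificity_trend(
        kmer_fit.estimate[reference], contrast["contrast"].to_numpy(),
        n_bins=n_bins, min_kmers=min_kmers,
    )
    spec = test_specificity(contrast, trend, kmer_fit.estimate[reference])
    table = pd.DataFrame(
        {
            "kmer": kmer_strings,
            "ref_estimate": kmer_fit.estimate[reference],
            "var_estimate": kmer_fit.estimate[variant],
            "affinityQ_ref": aff_ref["affinityQ"].to_numpy(),
            "affinityQ_var": aff_var["affinityQ"].to_numpy(),
            "contrast": contrast["contrast"].to_numpy(),
            "contrast_se": contrast["se"].to_numpy(),
            "contrast_z": contrast["z"].to_numpy(),
            "contrastQ": contrast["contrastQ"].to_numpy(),
            "trend": spec["trend"].to_numpy(),
            "contrastResidual": spec["contrastResidual"].to_numpy(),
            "specificityQ": spec["specificityQ"].to_numpy(),
        }
    )
    models = {"normexp_ref": params_ref, "normexp_var": params_var, "trend": trend}
    return table, models
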