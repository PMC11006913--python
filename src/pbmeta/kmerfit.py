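"""Per-allele k-mer affinity scores by random-effects meta-analysis.

Three stages:

1. ``fit_probes`` - per-probe means and variances across replicates, with
   empirical-Bayes variance moderation (scaled inverse-chi-square prior
   fitted by moment matching on log sample variances, as in the limma
   smoothed variance estimator).
2. ``correct_position_bias`` - a per-offset, per-strand profile of probe
   deviations from their k-mer medians, subtracted from each probe's
   contribution so that binding measured near the attached probe end is
   comparable to binding near the free end.
3. ``fit_kmers`` - for each RC-collapsed k-mer, the two-step
   DerSimonian-Laird (DerSimonian-Kacker) estimator across all probes
   containing it: a first moment estimate of the between-probe variance
   tau^2 with inverse-variance weights, one re-estimation with the
   updated weights, then the weighted mean and its standard error.
   Cross-allele covariances per k-mer combine the empirical covariance of
   probe-level means (shrunk toward min(tau^2_a, tau^2_b)) with the DL
   weights, so that contrasts between alleles fitted on the same probes
   have approximately zero variance under the null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma

from .design import ArrayDesign

COV_SHRINK_PSEUDO_N = 10.0


# ---------------------------------------------------------------------------
# probe-level fits


@dataclass
class ProbeFit:
    """Probe-level summaries for one allele, aligned to the design probe order."""

    allele_id: str
    mean: np.ndarray          # NaN where a probe was observed in no replicate
    raw_var: np.ndarray       # NaN where < 2 replicates
    moderated_var: np.ndarray
    df: np.ndarray            # residual df per probe (n_reps - 1)
    n_reps: np.ndarray
    d0: float
    s0_sq: float
    position_profile: "PositionBiasProfile | None" = None

    @property
    def var_of_mean(self) -> np.ndarray:
        n = np.where(self.n_reps > 0, self.n_reps, np.nan)
        return self.moderated_var / n


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (y > 0)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(sample_vars: np.ndarray, dfs: np.ndarray) -> tuple[float, float]:
    """Moment-matching fit of (d0, s0^2) on log sample variances.

    Returns d0 = np.inf when the log variances are underdispersed relative
    to their chi-square sampling spread (complete shrinkage).
    """
    ok = np.isfinite(sample_vars) & (dfs > 0)
    s2 = np.maximum(sample_vars[ok], 1e-12)
    df = dfs[ok].astype(float)
    if len(s2) < 2:
        raise ValueError("need >=2 probes with replicate variance to fit the prior")
    z = np.log(s2)
    e = z - digamma(df / 2) + np.log(df / 2)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(np.mean(polygamma(1, df / 2)))
    if e_var <= 0:
        # underdispersed relative to chi-square sampling: complete shrinkage;
        # the geometric mean keeps identical sample variances a fixed point
        return np.inf, float(np.exp(z.mean()))
    d0 = 2 * _trigamma_inverse(e_var)
    s0_sq = float(np.exp(e_mean + digamma(d0 / 2) - np.log(d0 / 2)))
    return d0, s0_sq


def fit_probes(
    replicate_values: list[pd.Series],
    probe_index: pd.Index,
    allele_id: str = "allele",
    prior: tuple[float, float] | None = None,
) -> ProbeFit:
    """Probe means/variances across replicates with moderated variances.

    `replicate_values` holds one log2-signal series per replicate (masked
    probes absent).  If no probe has >=2 replicates, moderation is
    impossible: a supplied `prior` (d0, s0^2) is used directly, otherwise
    the overall variance of probe means stands in (pooled fallback) with
    a warning.
    """
    mat = pd.concat(
        [s.reindex(probe_index) for s in replicate_values], axis=1
    ).to_numpy(float)
    n = np.sum(np.isfinite(mat), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(mat, axis=1)
        raw_var = np.full(len(probe_index), np.nan)
        multi = n >= 2
        raw_var[multi] = np.nanvar(mat[multi], axis=1, ddof=1)
    df = np.maximum(n - 1, 0).astype(float)

    if multi.sum() >= 2:
        d0, s0_sq = fit_variance_prior(raw_var, df)
    elif prior is not None:
        d0, s0_sq = prior
    else:
        warnings.warn(
            "no probes with >=2 replicates and no prior: falling back to the "
            "pooled variance of probe means (conservative)"
        )
        d0, s0_sq = np.inf, float(np.nanvar(mean))
    if np.isinf(d0):
        moderated = np.full(len(probe_index), s0_sq)
    else:
        rv = np.where(np.isfinite(raw_var), raw_var, 0.0)
        moderated = (d0 * s0_sq + df * rv) / (d0 + df)
    return ProbeFit(
        allele_id=allele_id,
        mean=mean,
        raw_var=raw_var,
        moderated_var=moderated,
        df=df,
        n_reps=n,
        d0=float(d0),
        s0_sq=float(s0_sq),
    )


# ---------------------------------------------------------------------------
# position-bias correction


@dataclass
class PositionBiasProfile:
    """Additive log2 offset per (strand, offset-from-free-end); median 0."""

    profile: np.ndarray  # shape (2, n_offsets); NaN where never observed

    def at(self, strand: np.ndarray, offset: np.ndarray) -> np.ndarray:
        vals = self.profile[strand, offset]
        return np.where(np.isfinite(vals), vals, 0.0)


def correct_position_bias(pf: ProbeFit, design: ArrayDesign) -> tuple[ProbeFit, PositionBiasProfile]:
    """Estimate the per-offset profile and attach it to the probe fit.

    The profile value at (strand, offset) is the median over occurrences
    of (probe mean - that k-mer's median probe mean), median-centered for
    identifiability.  A k-mer's own probes enter the global profile like
    any others; its correction is not self-referential.
    """
    probe_mean = pf.mean[design.occ_probe_ix]
    ok = np.isfinite(probe_mean)
    occ = pd.DataFrame(
        {
            "kmer": design.occ_kmer_ix[ok],
            "strand": design.occ_strand[ok].astype(int),
            "offset": design.occ_offset[ok].astype(int),
            "value": probe_mean[ok],
        }
    )
    occ["kmer_median"] = occ.groupby("kmer")["value"].transform("median")
    occ["dev"] = occ["value"] - occ["kmer_median"]
    n_off = design.variable_length - design.k + 1
    prof = np.full((2, n_off), np.nan)
    grouped = occ.groupby(["strand", "offset"])["dev"].median()
    for (strand, offset), val in grouped.items():
        prof[strand, offset] = val
    prof -= np.nanmedian(prof)
    profile = PositionBiasProfile(profile=prof)
    pf.position_profile = profile
    return pf, profile


# ---------------------------------------------------------------------------
# DerSimonian-Laird k-mer fits


@dataclass
class KmerFitResult:
    """Per (allele, canonical k-mer) estimates plus pairwise covariances."""

    kmer_codes: np.ndarray
    k: int
    estimate: dict = field(default_factory=dict)  # allele -> array
    se: dict = field(default_factory=dict)
    tau2: dict = field(default_factory=dict)
    n_probes: dict = field(default_factory=dict)
    covariance: dict = field(default_factory=dict)  # (a, b) -> array
    # direct per-k-mer variance of the weighted mean paired difference:
    # a floor for the contrast variance, immune to covariance overshoot
    paired_var: dict = field(default_factory=dict)  # (a, b) -> array

    def alleles(self) -> list:
        return list(self.estimate)

    def pair_covariance(self, a: str, b: str) -> np.ndarray:
        if (a, b) in self.covariance:
            return self.covariance[(a, b)]
        return self.covariance[(b, a)]

    def to_frame(self, kmer_strings: list) -> pd.DataFrame:
        frames = []
        for allele in self.estimate:
            frames.append(
                pd.DataFrame(
                    {
                        "kmer": kmer_strings,
                        "allele": allele,
                        "estimate": self.estimate[allele],
                        "se": self.se[allele],
                        "tau2": self.tau2[allele],
                        "n_probes": self.n_probes[allele],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)


def dl_two_step(kix: np.ndarray, x: np.ndarray, s2: np.ndarray, n_kmers: int):
    """Grouped two-step DerSimonian-Laird estimates.

    `kix` assigns each observation (probe contribution) to a k-mer;
    `x`/`s2` are the observation values and their sampling variances.
    Returns (estimate, se, tau2, n, w2) with w2 the final per-observation
    weights.  Single-observation k-mers get tau2=0 and se=sqrt(s2).
    """
    n = np.bincount(kix, minlength=n_kmers).astype(float)
    w = 1.0 / s2
    sw = np.bincount(kix, weights=w, minlength=n_kmers)
    sww = np.bincount(kix, weights=w * w, minlength=n_kmers)
    mu = _safe_div(np.bincount(kix, weights=w * x, minlength=n_kmers), sw)
    q = np.bincount(kix, weights=w * (x - mu[kix]) ** 2, minlength=n_kmers)
    denom = sw - _safe_div(sww, sw)
    tau1 = np.clip(_safe_div(q - (n - 1), denom), 0.0, np.inf)

    a = 1.0 / (s2 + tau1[kix])
    sa = np.bincount(kix, weights=a, minlength=n_kmers)
    saa = np.bincount(kix, weights=a * a, minlength=n_kmers)
    mua = _safe_div(np.bincount(kix, weights=a * x, minlength=n_kmers), sa)
    qa = np.bincount(kix, weights=a * (x - mua[kix]) ** 2, minlength=n_kmers)
    sas2 = np.bincount(kix, weights=a * s2, minlength=n_kmers)
    saas2 = np.bincount(kix, weights=a * a * s2, minlength=n_kmers)
    denom2 = sa - _safe_div(saa, sa)
    expected_q = sas2 - _safe_div(saas2, sa)
    tau2 = np.clip(_safe_div(qa - expected_q, denom2), 0.0, np.inf)

    w2 = 1.0 / (s2 + tau2[kix])
    sw2 = np.bincount(kix, weights=w2, minlength=n_kmers)
    est = _safe_div(np.bincount(kix, weights=w2 * x, minlength=n_kmers), sw2)
    with np.errstate(divide="ignore"):
        se = np.where(sw2 > 0, 1.0 / np.sqrt(np.where(sw2 > 0, sw2, 1.0)), np.nan)
    est = np.where(n > 0, est, np.nan)
    return est, se, tau2, n, w2


def fit_kmers(
    probe_fits: dict[str, ProbeFit],
    design: ArrayDesign,
    pairs: list[tuple[str, str]] | None = None,
) -> KmerFitResult:
    """k-mer affinity estimates per allele plus covariances for given pairs."""
    n_kmers = design.n_kmers
    result = KmerFitResult(kmer_codes=design.kmer_codes, k=design.k)
    obs = {}
    for allele, pf in probe_fits.items():
        x = pf.mean[design.occ_probe_ix]
        if pf.position_profile is not None:
            x = x - pf.position_profile.at(
                design.occ_strand.astype(int), design.occ_offset.astype(int)
            )
        s2 = pf.var_of_mean[design.occ_probe_ix]
        ok = np.isfinite(x) & np.isfinite(s2) & (s2 > 0)
        kix = design.occ_kmer_ix[ok]
        est, se, tau2, n, w2 = dl_two_step(kix, x[ok], s2[ok], n_kmers)
        result.estimate[allele] = est
        result.se[allele] = se
        result.tau2[allele] = tau2
        result.n_probes[allele] = n.astype(int)
        obs[allele] = (ok, kix, x, w2)

    for a, b in pairs or []:
        ok_a, _, x_a, w2_a = obs[a]
        ok_b, _, x_b, w2_b = obs[b]
        shared = ok_a & ok_b
        kix = design.occ_kmer_ix[shared]
        xa, xb = x_a[shared], x_b[shared]
        ns = np.bincount(kix, minlength=n_kmers).astype(float)

        # weighted paired-difference variance of the contrast: probe
        # effects shared by the two alleles cancel in the differences, so
        # this is a directly calibrated estimate of Var(d)
        wa_full = np.zeros(len(design.occ_kmer_ix))
        wa_full[ok_a] = w2_a
        wb_full = np.zeros(len(design.occ_kmer_ix))
        wb_full[ok_b] = w2_b
        u = 0.5 * (wa_full[shared] + wb_full[shared])
        diff = xa - xb
        su = np.bincount(kix, weights=u, minlength=n_kmers)
        suu = np.bincount(kix, weights=u * u, minlength=n_kmers)
        dbar = _safe_div(np.bincount(kix, weights=u * diff, minlength=n_kmers), su)
        ss = np.bincount(kix, weights=u * (diff - dbar[kix]) ** 2, minlength=n_kmers)
        # weighted sample variance, then variance of the weighted mean
        s2w = _safe_div(ss, su) * _safe_div(ns, np.maximum(ns - 1, 0))
        n_eff = _safe_div(su * su, suu)
        paired = _safe_div(s2w, n_eff)
        result.paired_var[(a, b)] = paired

        # covariance consistent with the paired estimate: plugging it into
        # Var(d) = SE_a^2 + SE_b^2 - 2 cov recovers the paired variance
        sea2 = result.se[a] ** 2
        seb2 = result.se[b] ** 2
        cov = np.where(ns >= 2, 0.5 * (sea2 + seb2 - paired), 0.0)
        bound = result.se[a] * result.se[b]
        cov = np.clip(cov, -bound, bound)
        result.covariance[(a, b)] = cov
    return result
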