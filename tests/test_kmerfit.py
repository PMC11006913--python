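"""Moderated probe fits, position-bias profiles, and DerSimonian-Laird k-mer scores."""

import numpy as np
import pandas as pd
import pytest

from pbmeta import kmerfit as kf
from pbmeta.design import ArrayDesign


# ---------------------------------------------------------------------------
# independent scalar oracle for the two-step DL estimator


def dl_two_step_oracle(x, s2):
    """Hand-coded one-step-then-generalized-moment DL for a single k-mer."""
    x, s2 = np.asarray(x, float), np.asarray(s2, float)
    n = len(x)
    w = 1.0 / s2
    mu = np.sum(w * x) / np.sum(w)
    q = np.sum(w * (x - mu) ** 2)
    denom = np.sum(w) - np.sum(w ** 2) / np.sum(w)
    tau1 = max(0.0, (q - (n - 1)) / denom) if denom > 0 else 0.0
    a = 1.0 / (s2 + tau1)
    mua = np.sum(a * x) / np.sum(a)
    qa = np.sum(a * (x - mua) ** 2)
    expected = np.sum(a * s2) - np.sum(a ** 2 * s2) / np.sum(a)
    denom2 = np.sum(a) - np.sum(a ** 2) / np.sum(a)
    tau2 = max(0.0, (qa - expected) / denom2) if denom2 > 0 else 0.0
    w2 = 1.0 / (s2 + tau2)
    est = np.sum(w2 * x) / np.sum(w2)
    se = 1.0 / np.sqrt(np.sum(w2))
    return est, se, tau2


class TestDLTwoStep:
    def test_single_probe_degenerate(self):
        est, se, tau2, n, _ = kf.dl_two_step(np.array([0]), np.array([3.5]), np.array([0.25]), 1)
        assert est[0] == 3.5 and tau2[0] == 0.0 and se[0] == pytest.approx(0.5)

    def test_homogeneous_means_zero_tau(self):
        x = np.full(6, 2.0)
        est, se, tau2, *_ = kf.dl_two_step(np.zeros(6, int), x, np.full(6, 0.1), 1)
        assert est[0] == pytest.approx(2.0) and tau2[0] == 0.0

    def test_three_probe_example_matches_oracle(self):
        x = np.array([1.0, 2.0, 3.0])
        s2 = np.array([0.1, 0.1, 0.1])
        est, se, tau2, *_ = kf.dl_two_step(np.zeros(3, int), x, s2, 1)
        oe, ose, otau = dl_two_step_oracle(x, s2)
        assert est[0] == pytest.approx(oe, abs=1e-12)
        assert se[0] == pytest.approx(ose, abs=1e-12)
        assert tau2[0] == pytest.approx(otau, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_grouped_equals_scalar_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_kmers = 30
        kix = np.repeat(np.arange(n_kmers), rng.integers(1, 9, n_kmers))
        x = rng.normal(5, 2, len(kix))
        s2 = rng.uniform(0.02, 0.5, len(kix))
        est, se, tau2, *_ = kf.dl_two_step(kix, x, s2, n_kmers)
        for k in range(n_kmers):
            sel = kix == k
            oe, ose, otau = dl_two_step_oracle(x[sel], s2[sel])
            assert est[k] == pytest.approx(oe, abs=1e-10)
            assert se[k] == pytest.approx(ose, abs=1e-10)
            assert tau2[k] == pytest.approx(otau, abs=1e-10)

    def test_estimate_within_probe_mean_range(self):
        rng = np.random.default_rng(9)
        kix = np.repeat(np.arange(50), 6)
        x = rng.normal(0, 3, len(kix))
        s2 = rng.uniform(0.05, 1.0, len(kix))
        est, *_ = kf.dl_two_step(kix, x, s2, 50)
        for k in range(50):
            sel = kix == k
            assert x[sel].min() - 1e-9 <= est[k] <= x[sel].max() + 1e-9

    def test_se_decreases_with_more_equal_probes(self):
        ses = []
        for n in (2, 4, 8, 16):
            _, se, *_ = kf.dl_two_step(
                np.zeros(n, int), np.full(n, 1.0), np.full(n, 0.2), 1
            )
            ses.append(se[0])
        assert all(a >= b for a, b in zip(ses, ses[1:]))


class TestProbeFit:
    def test_mean_and_raw_variance(self):
        idx = pd.Index(["P0", "P1"], name="probe_id")
        reps = [pd.Series([10.0, 5.0], index=idx), pd.Series([12.0, 7.0], index=idx)]
        pf = kf.fit_probes(reps, idx)
        assert pf.mean[0] == pytest.approx(11.0)
        assert pf.raw_var[0] == pytest.approx(2.0)
        assert pf.n_reps.tolist() == [2, 2]

    def test_identical_variances_are_fixed_point(self):
        """When every probe has the same raw variance, shrinkage returns it."""
        rng = np.random.default_rng(0)
        idx = pd.Index([f"P{i}" for i in range(200)], name="probe_id")
        means = rng.normal(10, 1, 200)
        delta = 0.3  # same spread for every probe
        reps = [pd.Series(means - delta, index=idx), pd.Series(means + delta, index=idx)]
        pf = kf.fit_probes(reps, idx)
        np.testing.assert_allclose(pf.moderated_var, 2 * delta ** 2, rtol=1e-6)

    def test_prior_recovery_from_scaled_inv_chisq(self):
        """(d0, s0^2) recovered within 10% from 10,000 simulated variances."""
        rng = np.random.default_rng(42)
        d0_true, s0_true, df = 4.0, 2.0, 3
        n = 10_000
        true_vars = d0_true * s0_true / rng.chisquare(d0_true, n)
        sample_vars = true_vars * rng.chisquare(df, n) / df
        d0, s0 = kf.fit_variance_prior(sample_vars, np.full(n, float(df)))
        assert d0 == pytest.approx(d0_true, rel=0.10)
        assert s0 == pytest.approx(s0_true, rel=0.10)

    def test_single_replicate_uses_prior(self):
        idx = pd.Index(["P0", "P1"], name="probe_id")
        pf = kf.fit_probes([pd.Series([1.0, 2.0], index=idx)], idx, prior=(8.0, 0.04))
        np.testing.assert_allclose(pf.moderated_var, 0.04)

    def test_single_replicate_without_prior_warns(self):
        idx = pd.Index(["P0", "P1", "P2"], name="probe_id")
        with pytest.warns(UserWarning, match="pooled"):
            pf = kf.fit_probes([pd.Series([1.0, 2.0, 3.0], index=idx)], idx)
        assert np.isfinite(pf.moderated_var).all()


def tiny_design():
    """Hand-built design: 4 probes, 2 k-mers, controlled offsets/strands."""
    probes = pd.DataFrame(
        {"probe_id": ["P0", "P1", "P2", "P3"], "row": [1, 1, 2, 2], "col": [1, 2, 1, 2],
         "sequence": ["AAAA"] * 4}
    )
    return ArrayDesign(
        order=4, variable_length=4, seed=0, probes=probes,
        kmer_codes=np.array([0, 5]),
        occ_kmer_ix=np.array([0, 0, 1, 1, 1], dtype=np.int32),
        occ_probe_ix=np.array([0, 1, 1, 2, 3], dtype=np.int32),
        occ_offset=np.array([0, 1, 0, 1, 2], dtype=np.int16),
        occ_strand=np.array([0, 0, 1, 1, 0], dtype=np.int8),
    )


class TestPositionBias:
    def test_flat_effect_gives_zero_profile(self, design8):
        rng = np.random.default_rng(0)
        mean = rng.normal(10, 0.01, design8.n_probes)
        pf = kf.ProbeFit("a", mean, mean * 0, mean * 0 + 0.01, mean * 0 + 3,
                         np.full(design8.n_probes, 4), 4.0, 0.01)
        _, profile = kf.correct_position_bias(pf, design8)
        finite = profile.profile[np.isfinite(profile.profile)]
        assert np.abs(finite).max() < 0.02

    def test_planted_offset_trend_recovered(self):
        """Linear 0.05/position decay is recovered within 0.01 when each
        probe's mean reflects a single k-mer occurrence (the estimator's
        generative model; composite probes attenuate the profile)."""
        slope = 0.05
        n_kmers, n_off = 40, 8
        rng = np.random.default_rng(0)
        a = rng.normal(10, 1, n_kmers)
        probe_ids, means, occ_k, occ_p, occ_off = [], [], [], [], []
        p = 0
        for k in range(n_kmers):
            for j in range(n_off):
                probe_ids.append(f"P{p:04d}")
                means.append(a[k] - slope * j)
                occ_k.append(k)
                occ_p.append(p)
                occ_off.append(j)
                p += 1
        probes = pd.DataFrame(
            {"probe_id": probe_ids, "row": np.arange(p) // 20 + 1,
             "col": np.arange(p) % 20 + 1, "sequence": "ACGTACGT"}
        )
        design = ArrayDesign(
            order=10, variable_length=n_off + 7, seed=0, probes=probes,
            kmer_codes=np.arange(n_kmers),
            occ_kmer_ix=np.array(occ_k, dtype=np.int32),
            occ_probe_ix=np.array(occ_p, dtype=np.int32),
            occ_offset=np.array(occ_off, dtype=np.int16),
            occ_strand=np.zeros(len(occ_k), dtype=np.int8),
        )
        mean = np.array(means)
        pf = kf.ProbeFit("a", mean, mean * 0, mean * 0 + 0.01, mean * 0 + 3,
                         np.full(p, 4), 4.0, 0.01)
        _, profile = kf.correct_position_bias(pf, design)
        prof = profile.profile[0, :n_off]
        fitted_slope = np.polyfit(np.arange(n_off), prof, 1)[0]
        assert fitted_slope == pytest.approx(-slope, abs=0.01)
        # corrected contributions no longer trend with offset
        corrected = mean - profile.at(design.occ_strand.astype(int),
                                      design.occ_offset.astype(int))
        resid_slope = np.polyfit(np.array(occ_off), corrected - a[np.array(occ_k)], 1)[0]
        assert abs(resid_slope) < 0.005

    def test_correction_is_global_not_self_referential(self):
        """A k-mer whose probes sit at one offset is corrected by the global
        profile value there, computed from all k-mers."""
        design = tiny_design()
        mean = np.array([10.0, 11.0, 12.0, 13.0])
        pf = kf.ProbeFit("a", mean, mean * 0, mean * 0 + 0.01, mean * 0 + 1,
                         np.full(4, 2), 4.0, 0.01)
        _, profile = kf.correct_position_bias(pf, design)
        assert np.isfinite(profile.at(np.array([0]), np.array([0]))).all()


class TestKmerFitIntegration:
    def _pf(self, design, mean, var=0.01, n_reps=4):
        n = design.n_probes
        return kf.ProbeFit("x", np.asarray(mean, float), np.full(n, np.nan),
                           np.full(n, var), np.full(n, n_reps - 1.0),
                           np.full(n, n_reps), 4.0, var)

    def test_identical_alleles_have_null_contrast_variance(self, design8):
        rng = np.random.default_rng(1)
        mean = rng.normal(10, 1, design8.n_probes)
        fits = {"a": self._pf(design8, mean), "b": self._pf(design8, mean.copy())}
        res = kf.fit_kmers(fits, design8, pairs=[("a", "b")])
        cov = res.covariance[("a", "b")]
        var_d = res.se["a"] ** 2 + res.se["b"] ** 2 - 2 * cov
        multi = res.n_probes["a"] >= 2
        assert np.nanmax(var_d[multi]) < 1e-10
        np.testing.assert_allclose(res.estimate["a"], res.estimate["b"])

    def test_kmer_estimates_match_per_kmer_oracle(self, design6):
        rng = np.random.default_rng(2)
        mean = rng.normal(8, 0.5, design6.n_probes)
        pf = self._pf(design6, mean, var=0.04)
        res = kf.fit_kmers({"a": pf}, design6)
        s2 = 0.04 / 4
        for k in rng.choice(design6.n_kmers, 15, replace=False):
            sel = design6.occ_kmer_ix == k
            oe, ose, _ = dl_two_step_oracle(mean[design6.occ_probe_ix[sel]],
                                            np.full(sel.sum(), s2))
            assert res.estimate["a"][k] == pytest.approx(oe, abs=1e-10)
            assert res.se["a"][k] == pytest.approx(ose, abs=1e-10)

    def test_masked_probes_excluded(self, design6):
        mean = np.full(design6.n_probes, 5.0)
        mean[:10] = np.nan
        pf = self._pf(design6, mean)
        res = kf.fit_kmers({"a": pf}, design6)
        full = np.bincount(design6.occ_kmer_ix, minlength=design6.n_kmers)
        assert (res.n_probes["a"] <= full).all()
        assert np.isfinite(res.estimate["a"][res.n_probes["a"] > 0]).all()
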