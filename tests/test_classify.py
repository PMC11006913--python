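"""Levenshtein distances, empirical-null thresholds, and variant calls."""

import numpy as np
import pandas as pd
import pytest

from pbmeta import classify as cl
from pbmeta._util import revcomp


def dp_levenshtein(a, b):
    """Dynamic-programming matrix oracle, unit costs."""
    m, n = len(a), len(b)
    d = np.zeros((m + 1, n + 1), dtype=int)
    d[:, 0] = np.arange(m + 1)
    d[0, :] = np.arange(n + 1)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            d[i, j] = min(
                d[i - 1, j] + 1, d[i, j - 1] + 1,
                d[i - 1, j - 1] + (a[i - 1] != b[j - 1]),
            )
    return int(d[m, n])


class TestLevenshtein:
    def test_identity(self):
        assert cl.levenshtein("AATAAAGC", "AATAAAGC") == 0

    def test_single_substitution(self):
        assert cl.levenshtein("TAATCCAA", "TAAGCCAA") == 1

    def test_500_random_pairs_match_dp_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(4, 10)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(4, 10)))
            assert cl.levenshtein(a, b) == dp_levenshtein(a, b)

    def test_rc_collapsed_distance_is_min_over_orientation(self):
        a, b = "AAACCGGT", "ACCGGTTT"
        assert cl.levenshtein_rc(a, b) == min(
            dp_levenshtein(a, b), dp_levenshtein(a, revcomp(b))
        )
        assert cl.levenshtein_rc("AAAATTTC", revcomp("AAAATTTC")) == 0

    def test_non_dna_rejected(self):
        with pytest.raises(ValueError):
            cl.levenshtein("ACGT", "ACGN")


class TestNullEnumeration:
    def test_four_replicates_give_six(self):
        pairs = cl.enumerate_null_pairs({"REF": ["r1", "r2", "r3", "r4"]})
        assert len(pairs) == 6
        for _, ref_g, var_g in pairs:
            assert len(ref_g) == 2 and len(var_g) == 2
            assert not set(ref_g) & set(var_g)

    def test_two_replicates_give_one(self):
        assert len(cl.enumerate_null_pairs({"REF": ["r1", "r2"]})) == 1

    def test_additivity_with_provenance(self):
        pairs = cl.enumerate_null_pairs({"A": ["1", "2", "3", "4"], "B": ["x", "y"]})
        assert len(pairs) == 7
        assert sum(1 for p in pairs if p[0] == "A") == 6
        assert sum(1 for p in pairs if p[0] == "B") == 1

    def test_cap_subsamples_deterministically(self):
        ids = {"A": [str(i) for i in range(6)]}
        a = cl.enumerate_null_pairs(ids, max_pairs=5, seed=3)
        b = cl.enumerate_null_pairs(ids, max_pairs=5, seed=3)
        assert a == b and len(a) == 5

    def test_no_replicates_error(self):
        with pytest.raises(ValueError):
            cl.enumerate_null_pairs({"A": ["only"]})


def results_frame(n=200, affQ_ref=1.0, affQ_var=1.0, contrastQ=1.0, contrast=0.0,
                  specQ=1.0, residual=0.01, kmers=None):
    n = n if kmers is None else len(kmers)
    return pd.DataFrame(
        {
            "kmer": kmers if kmers is not None else ["AAAAAA"] * n,
            "affinityQ_ref": affQ_ref,
            "affinityQ_var": affQ_var,
            "contrastQ": contrastQ,
            "contrast": contrast,
            "specificityQ": specQ,
            "contrastResidual": residual,
        }
    )


class TestThresholdCalibration:
    def _nulls(self, counts):
        metrics = []
        for c in counts:
            m = {"n_preferential": 0, "frac_differential_neg": 0.0,
                 "frac_differential_pos": 0.0, "n_spec_kmers": 0,
                 "seeds": {"+": None, "-": None}}
            for sign in ("+", "-"):
                for combo in cl.DEFAULT_PANEL:
                    m[("edit", sign, combo)] = c
            metrics.append(m)
        return cl.NullComparisonSet(comparisons=[None] * len(counts), metrics=metrics)

    def test_all_zero_null_gives_zero_thresholds(self):
        panel = cl.calibrate_fdr_thresholds(self._nulls([0] * 20))
        assert set(panel.edit_thresholds.values()) == {0}

    def test_five_percent_quantile_sets_threshold(self):
        """One of 20 null comparisons at 9 with the rest at <=8: any count
        above 8 is significant at the 5% empirical FDR."""
        counts = [0, 1, 1, 2, 3, 8, 0, 2, 1, 0, 3, 2, 1, 0, 4, 2, 9, 1, 0, 2]
        panel = cl.calibrate_fdr_thresholds(self._nulls(counts))
        assert set(panel.edit_thresholds.values()) == {8}

    def test_order_invariance(self):
        counts = [0, 3, 7, 1, 2, 0, 5, 1, 9, 0, 4, 1, 2, 0, 6, 1, 3, 0, 2, 1]
        a = cl.calibrate_fdr_thresholds(self._nulls(counts))
        b = cl.calibrate_fdr_thresholds(self._nulls(counts[::-1]))
        assert a.edit_thresholds == b.edit_thresholds

    def test_empty_nulls_error(self):
        with pytest.raises(ValueError):
            cl.calibrate_fdr_thresholds(cl.NullComparisonSet([], []))


class TestAffinityCall:
    def _results(self, n_pref=100, n_diff_neg=0, n_diff_pos=0):
        df = results_frame(n=400)
        df.loc[: n_pref - 1, "affinityQ_ref"] = 1e-8
        df.loc[: n_diff_neg - 1, ["contrastQ", "contrast"]] = [1e-8, -1.0]
        lo = n_diff_neg
        df.loc[lo : lo + n_diff_pos - 1, ["contrastQ", "contrast"]] = [1e-8, 1.0]
        return df

    def test_sixteen_percent_negative_is_loss(self):
        call, ev = cl.call_affinity_change(self._results(100, 16, 0), cl.ThresholdPanel())
        assert call == "loss" and ev["frac_loss"] == pytest.approx(0.16)

    def test_exactly_fifteen_percent_is_none(self):
        call, _ = cl.call_affinity_change(self._results(100, 15, 0), cl.ThresholdPanel())
        assert call == "none"

    def test_positive_direction_is_gain(self):
        call, _ = cl.call_affinity_change(self._results(100, 0, 20), cl.ThresholdPanel())
        assert call == "gain"

    def test_empty_preferential_set_warns_none(self):
        with pytest.warns(UserWarning, match="empty"):
            call, _ = cl.call_affinity_change(self._results(0), cl.ThresholdPanel())
        assert call == "none"


class TestSpecificityCall:
    def _results(self, n_primary, kmers=None, specQ_cluster=None):
        rng = np.random.default_rng(0)
        kmers = kmers or ["".join(rng.choice(list("ACGT"), 6)) for _ in range(300)]
        df = results_frame(kmers=kmers)
        df["contrastResidual"] = 0.01
        if n_primary:
            df.loc[: n_primary - 1, ["affinityQ_ref", "specificityQ"]] = 1e-8
            df.loc[: n_primary - 1, "contrastResidual"] = 1.0
        return df

    def test_ten_qualifying_kmers_trigger_primary_rule(self):
        call, ev = cl.call_specificity_change(self._results(10), cl.ThresholdPanel())
        assert call == "altered" and ev["primary_rule"]

    def test_nine_kmers_and_no_clusters_is_none(self):
        panel = cl.ThresholdPanel(edit_thresholds={c: 50 for c in cl.DEFAULT_PANEL})
        call, ev = cl.call_specificity_change(self._results(9), panel)
        assert call == "none" and not ev["primary_rule"] and not ev["edit_rule"]

    def test_edit_rule_requires_every_panel_combination(self):
        """A tight sequence cluster fires the edit rule only when its counts
        beat the thresholds for all four (distance, Q) combinations."""
        cluster = ["TTACGTAC"[i : i + 6] for i in range(3)] * 4  # similar words
        filler = ["AAATTT", "CCCGGG", "ACACAC", "AGAGAG"] * 10
        kmers = cluster + filler
        df = results_frame(kmers=kmers)
        df["contrastResidual"] = 0.01
        df.loc[: len(cluster) - 1, "specificityQ"] = 1e-8
        df.loc[: len(cluster) - 1, "contrastResidual"] = 2.0
        call, ev = cl.call_specificity_change(df, cl.ThresholdPanel())
        assert call == "altered" and ev["edit_rule"]
        strict = cl.ThresholdPanel(edit_thresholds={c: 100 for c in cl.DEFAULT_PANEL})
        call, _ = cl.call_specificity_change(df, strict)
        assert call == "none"

    def test_seed_is_max_magnitude_residual_per_sign(self):
        df = self._results(12)
        df.loc[5, "contrastResidual"] = 3.0
        df.loc[7, "contrastResidual"] = -2.0
        _, ev = cl.call_specificity_change(df, cl.ThresholdPanel())
        assert ev["seed_pos"] == df.loc[5, "kmer"]
        assert ev["seed_neg"] == df.loc[7, "kmer"]

    def test_calls_deterministic(self):
        df = self._results(11)
        panel = cl.ThresholdPanel()
        a = cl.call_variant("v", df, panel)
        b = cl.call_variant("v", df.copy(), panel)
        assert (a.affinity_call, a.specificity_call) == (b.affinity_call, b.specificity_call)
        assert a.evidence == b.evidence
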