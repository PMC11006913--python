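"""GPR dialect IO and chamber preprocessing operations."""

import numpy as np
import pandas as pd
import pytest

from pbmeta.gpr import GprFormatError, read_gpr_frame, write_gpr
from pbmeta import preprocess as pp


def make_table(n=16, fg=1000, bg=100, cy3=500, grid=4):
    return pd.DataFrame(
        {
            "Block": 1,
            "Row": [i // grid + 1 for i in range(n)],
            "Column": [i % grid + 1 for i in range(n)],
            "ID": [f"P{i:03d}" for i in range(n)],
            "F_protein_Median": fg,
            "B_protein_Median": bg,
            "F_cy3_Median": cy3,
            "B_cy3_Median": 100,
            "Flags": 0,
        }
    )


META = {"FileType": "pbmeta-gpr-1", "PMTGain": "450"}


def to_probe_table(table, meta=META):
    return pp.probe_table_from_frame(table, meta)


class TestGprIO:
    def test_round_trip_bit_exact(self, tmp_path):
        path = tmp_path / "x.gpr"
        write_gpr(path, make_table(), META)
        raw = path.read_bytes()
        table, meta = read_gpr_frame(path)
        write_gpr(tmp_path / "y.gpr", table, meta)
        assert (tmp_path / "y.gpr").read_bytes() == raw

    def test_two_probe_fixture_loads_unmasked(self, tmp_path):
        path = tmp_path / "x.gpr"
        write_gpr(path, make_table(n=2, grid=2), META)
        tbl = pp.read_gpr(path)
        assert tbl.n_probes == 2
        assert not tbl.data["mask"].any()
        assert tbl.pmt_gain == 450

    def test_negative_flag_masks_probe(self, tmp_path):
        table = make_table(n=4, grid=2)
        table.loc[1, "Flags"] = -100
        path = tmp_path / "x.gpr"
        write_gpr(path, table, META)
        tbl = pp.read_gpr(path)
        assert tbl.data["mask"].tolist() == [False, True, False, False]
        assert tbl.data["mask_reason"].iloc[1] == "flagged"

    def test_missing_required_column_names_it(self, tmp_path):
        table = make_table().drop(columns=["B_protein_Median"])
        path = tmp_path / "x.gpr"
        path.write_text("FileType=t\nPMTGain=450\n" + table.to_csv(sep="\t", index=False))
        with pytest.raises(GprFormatError, match="B_protein_Median"):
            pp.read_gpr(path)

    def test_duplicate_probe_id_rejected(self, tmp_path):
        table = make_table(n=4, grid=2)
        table.loc[1, "ID"] = table.loc[0, "ID"]
        path = tmp_path / "x.gpr"
        write_gpr(path, table, META)
        with pytest.raises(GprFormatError, match="duplicate"):
            pp.read_gpr(path)


class TestScanSelection:
    def _scan(self, fractions_over, fraction_under, gain):
        n = 100
        fg = np.full(n, 1000.0)
        fg[: int(fractions_over * n)] = 60000
        fg[int(fractions_over * n) : int(fractions_over * n) + int(fraction_under * n)] = 10
        t = make_table(n=n, grid=10)
        t["F_protein_Median"] = fg
        return to_probe_table(t, {"FileType": "t", "PMTGain": str(gain)})

    def test_argmin_of_combined_saturation(self):
        scans = pp.ScanSet("c", [
            self._scan(0.20, 0.00, 350),
            self._scan(0.01, 0.00, 450),
            self._scan(0.00, 0.30, 550),
        ])
        pp.select_optimal_scan(scans)
        assert scans.chosen == 1

    def test_single_scan_chosen(self):
        scans = pp.ScanSet("c", [self._scan(0.1, 0.0, 450)])
        assert pp.select_optimal_scan(scans).chosen == 0

    def test_tie_goes_to_lower_gain(self):
        scans = pp.ScanSet("c", [
            self._scan(0.05, 0.0, 550),
            self._scan(0.05, 0.0, 350),
        ])
        assert pp.select_optimal_scan(scans).chosen == 1

    def test_permutation_invariant_choice(self):
        a, b, c = (self._scan(f, 0.0, g) for f, g in [(0.2, 350), (0.01, 450), (0.1, 550)])
        first = pp.select_optimal_scan(pp.ScanSet("c", [a, b, c]))
        second = pp.select_optimal_scan(pp.ScanSet("c", [c, a, b]))
        assert first.scans[first.chosen].pmt_gain == second.scans[second.chosen].pmt_gain


class TestBackgroundSubtract:
    def test_arithmetic_and_masking(self):
        t = make_table(n=4, grid=2)
        t["F_protein_Median"] = [1000, 50, 100, 2000]
        t["B_protein_Median"] = 100
        out = pp.background_subtract(to_probe_table(t))
        assert out.data["signal"].iloc[0] == 900
        assert out.data["mask"].tolist() == [False, True, True, False]  # fg<bg and fg==bg
        assert set(out.data.loc[out.data["mask"], "mask_reason"]) == {"fg_lt_bg"}


class TestSpatialAdjust:
    def _uniform(self, n=400, grid=20, value=500.0):
        t = make_table(n=n, grid=grid)
        t["F_protein_Median"] = value + 100
        return pp.background_subtract(to_probe_table(t))

    def test_uniform_signal_is_identity(self):
        tbl = self._uniform()
        out = pp.spatially_adjust(tbl, window=5)
        np.testing.assert_allclose(out.data["signal"], tbl.data["signal"])

    def test_planted_bright_block_corrected(self):
        """A 2x block is flattened to within 5% of the unbiased signal."""
        rng = np.random.default_rng(0)
        n, grid = 1600, 40
        base = rng.lognormal(np.log(500), 0.05, size=n)
        t = make_table(n=n, grid=grid)
        rows = t["Row"].to_numpy()
        cols = t["Column"].to_numpy()
        block = (rows <= 15) & (cols <= 15)
        t["F_protein_Median"] = np.rint(base * np.where(block, 2.0, 1.0)) + 100
        out = pp.spatially_adjust(pp.background_subtract(to_probe_table(t)), window=15)
        corrected = out.data["signal"].to_numpy()
        interior = block & (rows <= 8) & (cols <= 8)  # away from the block edge
        ratio = corrected[interior] / base[interior]
        assert np.median(np.abs(ratio - 1)) < 0.05

    def test_window_larger_than_grid_is_identity(self):
        tbl = self._uniform(n=16, grid=4)
        out = pp.spatially_adjust(tbl, window=99)
        np.testing.assert_allclose(out.data["signal"], tbl.data["signal"])

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            pp.spatially_adjust(self._uniform(), window=14)

    def test_global_median_preserved(self):
        rng = np.random.default_rng(1)
        t = make_table(n=900, grid=30)
        t["F_protein_Median"] = np.rint(rng.lognormal(np.log(400), 0.4, 900)) + 100
        tbl = pp.background_subtract(to_probe_table(t))
        out = pp.spatially_adjust(tbl, window=9)
        before = np.median(tbl.unmasked["signal"])
        after = np.median(out.unmasked["signal"])
        assert after == pytest.approx(before, rel=0.02)


class TestCy3Normalize:
    def _tbl(self, cy3):
        t = make_table(n=len(cy3), grid=int(np.ceil(np.sqrt(len(cy3)))))
        t["F_cy3_Median"] = np.asarray(cy3) + 100
        return pp.background_subtract(to_probe_table(t))

    def test_identity_when_observed_equals_expected(self):
        tbl = self._tbl([500.0] * 9)
        expected = pd.Series(500.0, index=tbl.data.index)
        out = pp.cy3_normalize(tbl, expected)
        assert not out.data["mask"].any()
        np.testing.assert_allclose(out.data["signal"], tbl.data["signal"])

    def test_outlier_ratio_masked(self):
        cy3 = [500.0] * 9
        cy3[3] = 500 * 2 ** 1.5
        tbl = self._tbl(cy3)
        out = pp.cy3_normalize(tbl, pd.Series(500.0, index=tbl.data.index))
        assert out.data["mask"].iloc[3]
        assert out.data["mask_reason"].iloc[3] == "cy3_outlier"

    def test_boundary_ratio_kept_and_rescaled(self):
        """observed = 2x expected everywhere: log2 ratio exactly 1 is kept."""
        tbl = self._tbl([1000.0] * 9)
        out = pp.cy3_normalize(tbl, pd.Series(500.0, index=tbl.data.index))
        assert not out.data["mask"].any()
        np.testing.assert_allclose(out.data["signal"], tbl.data["signal"] / 2)

    def test_probe_missing_from_expected_masked_with_warning(self):
        tbl = self._tbl([500.0] * 9)
        expected = pd.Series(500.0, index=tbl.data.index[:-1])
        with pytest.warns(UserWarning, match="absent"):
            out = pp.cy3_normalize(tbl, expected)
        assert out.data["mask"].iloc[-1]

    def test_nonpositive_expected_rejected(self):
        tbl = self._tbl([500.0] * 9)
        with pytest.raises(ValueError):
            pp.cy3_normalize(tbl, pd.Series(0.0, index=tbl.data.index))


def test_masking_is_monotone():
    """No preprocessing step ever unmasks a probe."""
    t = make_table(n=100, grid=10)
    t.loc[5, "Flags"] = -100
    t.loc[7, "F_protein_Median"] = 50
    tbl = to_probe_table(t)
    masked = set(tbl.data.index[tbl.data["mask"]])
    for step in (
        pp.mask_saturated,
        pp.background_subtract,
        lambda x: pp.spatially_adjust(x, window=5),
        lambda x: pp.cy3_normalize(x, pd.Series(400.0, index=x.data.index)),
    ):
        tbl = step(tbl)
        now = set(tbl.data.index[tbl.data["mask"]])
        assert masked <= now
        masked = now


def test_saturated_union_masking():
    t = make_table(n=16, grid=4)
    t.loc[2, "F_protein_Median"] = 60000
    tbl = to_probe_table(t)
    out = pp.mask_saturated(tbl)
    assert out.data["mask_reason"].iloc[2] == "saturated_excluded"
    other = pp.mask_saturated(to_probe_table(make_table(n=16, grid=4)),
                              probes=pp.saturated_probes(tbl))
    assert other.data["mask"].iloc[2]
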