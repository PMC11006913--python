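"""Chamber-level preprocessing of probe quantification tables.

Order of operations per chamber: pick the optimal PMT scan, subtract the
local background estimate, correct smooth spatial intensity bias with a
median-ratio filter, then normalize the protein channel by the Cy3
double-stranding channel against a pooled empirical reference.  Probes
are only ever masked, never unmasked; each masked probe carries the first
reason that excluded it (flagged, fg_lt_bg, cy3_outlier).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gpr import read_gpr_frame

OVERSATURATION_LIMIT = 2 ** 15.5
UNDERSATURATION_LIMIT = 2 ** 5


@dataclass
class ProbeIntensityTable:
    """One chamber/scan of probe-level intensities with masking state.

    ``data`` is indexed by probe_id with columns row, col, fg_protein,
    bg_protein, fg_cy3, bg_cy3, flag, signal, cy3_signal, mask,
    mask_reason.  ``signal`` is NaN until background subtraction.
    """

    data: pd.DataFrame
    pmt_gain: int
    meta: dict = field(default_factory=dict)

    @property
    def n_probes(self) -> int:
        return len(self.data)

    @property
    def unmasked(self) -> pd.DataFrame:
        return self.data.loc[~self.data["mask"]]

    def copy(self) -> "ProbeIntensityTable":
        return replace(self, data=self.data.copy())

    def _mask(self, where: pd.Series, reason: str) -> None:
        new = where & ~self.data["mask"]
        self.data.loc[new, "mask"] = True
        self.data.loc[new, "mask_reason"] = reason

    def mask_counts(self) -> dict:
        return self.data.loc[self.data["mask"], "mask_reason"].value_counts().to_dict()


def probe_table_from_frame(raw: pd.DataFrame, meta: dict) -> ProbeIntensityTable:
    """Build a :class:`ProbeIntensityTable` from a parsed dialect frame."""
    data = pd.DataFrame(
        {
            "row": raw["Row"].to_numpy(),
            "col": raw["Column"].to_numpy(),
            "fg_protein": raw["F_protein_Median"].to_numpy(float),
            "bg_protein": raw["B_protein_Median"].to_numpy(float),
            "fg_cy3": raw["F_cy3_Median"].to_numpy(float),
            "bg_cy3": raw["B_cy3_Median"].to_numpy(float),
            "flag": raw["Flags"].to_numpy(int),
            "signal": np.nan,
            "cy3_signal": np.nan,
            "mask": False,
            "mask_reason": "",
        },
        index=pd.Index(raw["ID"], name="probe_id"),
    )
    tbl = ProbeIntensityTable(data=data, pmt_gain=int(meta["PMTGain"]), meta=meta)
    tbl._mask(tbl.data["flag"] < 0, "flagged")
    return tbl


def read_gpr(path) -> ProbeIntensityTable:
    """Load one dialect file into a :class:`ProbeIntensityTable`."""
    raw, meta = read_gpr_frame(path)
    return probe_table_from_frame(raw, meta)


@dataclass
class ScanSet:
    chamber_id: str
    scans: list
    chosen: int | None = None

    def chosen_scan(self) -> ProbeIntensityTable:
        if self.chosen is None:
            raise ValueError("select_optimal_scan has not been run")
        return self.scans[self.chosen]


def saturation_score(tbl: ProbeIntensityTable) -> float:
    """Proportion over-saturated (>2^15.5) plus under-saturated (<2^5) probes."""
    fg = tbl.data["fg_protein"].to_numpy()
    return float(np.mean(fg > OVERSATURATION_LIMIT) + np.mean(fg < UNDERSATURATION_LIMIT))


def select_optimal_scan(scans: ScanSet) -> ScanSet:
    """Pick the scan minimizing combined over/under-saturation; ties -> lowest gain."""
    if not scans.scans:
        raise ValueError("empty scan set")
    keys = [(saturation_score(s), s.pmt_gain) for s in scans.scans]
    scans.chosen = int(min(range(len(keys)), key=lambda i: keys[i]))
    return scans


def saturated_probes(tbl: ProbeIntensityTable) -> pd.Index:
    """Probe ids whose foreground exceeds the over-saturation limit (2^15.5)."""
    return tbl.data.index[tbl.data["fg_protein"] > OVERSATURATION_LIMIT]


def mask_saturated(tbl: ProbeIntensityTable, probes: pd.Index | None = None) -> ProbeIntensityTable:
    """Mask over-saturated probes (or an explicit probe set).

    Scan selection minimizes, but cannot always eliminate, saturation;
    clipped probes bias bright k-mers downward.  Pass the union of
    saturated probes across the chambers of an allelic replicate so the
    exclusion is symmetric between the alleles being compared - dropping
    a bright probe from only one allele shifts every k-mer on that probe.
    """
    out = tbl.copy()
    if probes is None:
        probes = saturated_probes(out)
    out._mask(out.data.index.isin(probes), "saturated_excluded")
    return out


def background_subtract(tbl: ProbeIntensityTable) -> ProbeIntensityTable:
    """signal = fg - bg per channel; probes with protein fg <= bg are masked."""
    out = tbl.copy()
    out.data["signal"] = out.data["fg_protein"] - out.data["bg_protein"]
    out.data["cy3_signal"] = out.data["fg_cy3"] - out.data["bg_cy3"]
    out._mask(out.data["fg_protein"] <= out.data["bg_protein"], "fg_lt_bg")
    return out


def _local_median_field(values: np.ndarray, rows: np.ndarray, cols: np.ndarray, window: int) -> np.ndarray:
    """Median of `values` over a window x window grid neighbourhood of each probe.

    NaN marks masked/absent grid cells; windows truncate at array edges.
    """
    half = window // 2
    r0, c0 = rows.min(), cols.min()
    grid = np.full((rows.max() - r0 + 1, cols.max() - c0 + 1), np.nan)
    grid[rows - r0, cols - c0] = values
    padded = np.pad(grid, half, constant_values=np.nan)
    win = np.lib.stride_tricks.sliding_window_view(padded, (window, window))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        med = np.nanmedian(win, axis=(2, 3))
    return med[rows - r0, cols - c0]


def spatially_adjust(tbl: ProbeIntensityTable, window: int = 15) -> ProbeIntensityTable:
    """Divide each signal by its local-median / global-median ratio.

    Computed over unmasked probes only; a window covering the whole grid
    degenerates to the identity.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    out = tbl.copy()
    un = ~out.data["mask"].to_numpy()
    vals = np.where(un, out.data["signal"].to_numpy(float), np.nan)
    rows = out.data["row"].to_numpy(int)
    cols = out.data["col"].to_numpy(int)
    global_med = np.nanmedian(vals)
    if window > max(rows.max() - rows.min(), cols.max() - cols.min()) + 1:
        return out  # window exceeds the grid: identity
    local = _local_median_field(vals, rows, cols, window)
    ratio = local / global_med
    ratio = np.where(np.isfinite(ratio) & (ratio > 0), ratio, 1.0)
    out.data["signal"] = out.data["signal"] / ratio
    return out


def pooled_cy3_reference(tables: list[ProbeIntensityTable]) -> pd.Series:
    """Empirical expected Cy3 per probe: median of cy3 signal across chambers."""
    if len(tables) < 2:
        raise ValueError("pooled Cy3 reference requires >=2 chambers")
    stack = pd.concat([t.data["cy3_signal"] for t in tables], axis=1)
    ref = stack.median(axis=1)
    if (ref <= 0).any():
        ref = ref.clip(lower=ref[ref > 0].min())
    return ref


def cy3_normalize(
    tbl: ProbeIntensityTable,
    expected_cy3: pd.Series,
    threshold: float = 1.0,
) -> ProbeIntensityTable:
    """Mask Cy3 outliers and rescale protein signal by observed/expected Cy3.

    Probes with |log2(observed/expected)| strictly greater than the
    threshold are masked; the boundary is kept.  Probes absent from the
    expected map are masked with a warning.
    """
    if (expected_cy3 <= 0).any():
        raise ValueError("expected Cy3 values must be strictly positive")
    out = tbl.copy()
    expected = expected_cy3.reindex(out.data.index)
    absent = expected.isna()
    if absent.any():
        warnings.warn(f"{int(absent.sum())} probe(s) absent from expected Cy3 map; masked")
        out._mask(absent, "cy3_outlier")
    ratio = out.data["cy3_signal"] / expected
    with np.errstate(divide="ignore", invalid="ignore"):
        log2r = np.log2(ratio.to_numpy(float))
    bad = pd.Series(~np.isfinite(log2r) | (np.abs(log2r) > threshold), index=out.data.index)
    out._mask(bad & ~absent, "cy3_outlier")
    keep = ~out.data["mask"]
    out.data.loc[keep, "signal"] = out.data.loc[keep, "signal"] / ratio[keep]
    return out


def preprocess_chamber(
    scans: ScanSet,
    expected_cy3: pd.Series | None = None,
    window: int = 15,
    cy3_threshold: float = 1.0,
) -> ProbeIntensityTable:
    """Full chamber preprocessing: scan choice, subtraction, spatial, Cy3."""
    select_optimal_scan(scans)
    tbl = mask_saturated(scans.chosen_scan())
    tbl = background_subtract(tbl)
    tbl = spatially_adjust(tbl, window=window)
    if expected_cy3 is not None:
        tbl = cy3_normalize(tbl, expected_cy3, threshold=cy3_threshold)
    return tbl


def log2_signal(tbl: ProbeIntensityTable) -> pd.Series:
    """log2 of positive unmasked signals, indexed by probe_id."""
    un = tbl.unmasked
    vals = un["signal"]
    vals = vals[vals > 0]
    return np.log2(vals)
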