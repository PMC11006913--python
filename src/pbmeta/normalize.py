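"""Within- and across-replicate normalization of chamber log2 signals.

An *allelic replicate* is the set of chambers on one slide assaying one
allelic series.  Within a replicate, each non-anchor sample gets an
additive log2 shift from the trimmed mean of M-values (TMM) against the
anchor (typically the reference allele).  Across replicates, each
replicate gets an additive shift (median difference of its anchor vs the
cross-replicate anchor mean) and a multiplicative scale (median ratio of
rank-ordered, median-centered values - the slope of the log-scale QQ
plot).  Replicates whose reference sample has a collapsed upper tail
(90th-99th percentile width under 25% of the maximum across replicates,
50% for stripped arrays) are dropped before the final pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MIN_SHARED_PROBES = 50


@dataclass
class AllelicReplicate:
    replicate_id: str
    slide_id: str
    samples: dict  # allele_id -> pd.Series of log2 signal indexed by probe_id
    anchor_allele: str
    stripped: bool = False

    def __post_init__(self) -> None:
        if self.anchor_allele not in self.samples:
            raise ValueError(f"anchor {self.anchor_allele!r} missing from replicate {self.replicate_id}")

    def copy(self) -> "AllelicReplicate":
        return replace(self, samples={k: v.copy() for k, v in self.samples.items()})


@dataclass
class NormalizationFactors:
    within: dict = field(default_factory=dict)   # (replicate_id, allele_id) -> shift
    across_shift: dict = field(default_factory=dict)  # replicate_id -> additive
    across_scale: dict = field(default_factory=dict)  # replicate_id -> multiplicative

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"replicate": r, "allele": a, "kind": "within_shift", "value": v}
            for (r, a), v in self.within.items()
        ]
        rows += [
            {"replicate": r, "allele": "", "kind": "across_shift", "value": v}
            for r, v in self.across_shift.items()
        ]
        rows += [
            {"replicate": r, "allele": "", "kind": "across_scale", "value": v}
            for r, v in self.across_scale.items()
        ]
        return pd.DataFrame(rows)


def tmm_shift(sample: pd.Series, anchor: pd.Series, trim_m: float = 0.30, trim_a: float = 0.05) -> float:
    """Trimmed mean of M-values of `sample` against `anchor` (log2 scale).

    Trims the stated total fractions of extreme M (log-ratio) and A
    (average) values symmetrically before averaging M.
    """
    shared = sample.index.intersection(anchor.index)
    if len(shared) < MIN_SHARED_PROBES:
        raise ValueError(
            f"insufficient overlap with anchor: {len(shared)} < {MIN_SHARED_PROBES} probes"
        )
    m = (sample[shared] - anchor[shared]).to_numpy()
    a = ((sample[shared] + anchor[shared]) / 2).to_numpy()
    lo_m, hi_m = np.quantile(m, [trim_m / 2, 1 - trim_m / 2])
    lo_a, hi_a = np.quantile(a, [trim_a / 2, 1 - trim_a / 2])
    keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
    return float(m[keep].mean())


def normalize_within_replicate(
    rep: AllelicReplicate, factors: NormalizationFactors | None = None
) -> tuple[AllelicReplicate, NormalizationFactors]:
    """Shift every non-anchor sample so its trimmed mean M vs anchor is ~0."""
    if len(rep.samples) < 2:
        raise ValueError("replicate must contain >=2 alleles")
    factors = factors or NormalizationFactors()
    out = rep.copy()
    anchor = out.samples[out.anchor_allele]
    factors.within[(rep.replicate_id, rep.anchor_allele)] = 0.0
    for allele, series in out.samples.items():
        if allele == rep.anchor_allele:
            continue
        shift = tmm_shift(series, anchor)
        out.samples[allele] = series - shift
        factors.within[(rep.replicate_id, allele)] = shift
    return out, factors


def _qq_scale(sample: np.ndarray, reference: np.ndarray) -> float:
    """Median ratio of rank-ordered, median-centered values (QQ-plot slope)."""
    s = np.sort(sample) - np.median(sample)
    r = np.sort(reference) - np.median(reference)
    ok = np.abs(r) > 1e-9
    if not ok.any():
        raise ValueError("anchor sample has zero spread")
    return float(np.median(s[ok] / r[ok]))


def normalize_across_replicates(
    reps: list[AllelicReplicate],
    anchor_alleles: list[str] | None = None,
    factors: NormalizationFactors | None = None,
) -> tuple[list[AllelicReplicate], NormalizationFactors]:
    """Align replicates to the cross-replicate anchor reference by shift and scale.

    With multiple anchor alleles the per-anchor factors are averaged.  All
    samples of a replicate are transformed identically:
    x' = (x - center) / scale + center - shift, with center the mean of
    the replicate's anchor medians.
    """
    factors = factors or NormalizationFactors()
    anchors = anchor_alleles or [reps[0].anchor_allele]
    for anc in anchors:
        for rep in reps:
            if anc not in rep.samples:
                raise ValueError(f"anchor {anc!r} absent from replicate {rep.replicate_id}")

    # cross-replicate reference per anchor: per-probe log-scale mean over replicates
    references = {}
    for anc in anchors:
        shared = reps[0].samples[anc].index
        for rep in reps[1:]:
            shared = shared.intersection(rep.samples[anc].index)
        stack = pd.concat([rep.samples[anc][shared] for rep in reps], axis=1)
        ref = stack.mean(axis=1)
        if float(ref.std()) < 1e-9:
            raise ValueError(f"anchor {anc!r} reference has zero spread")
        references[anc] = ref

    out_reps = []
    for rep in reps:
        shifts, scales, centers = [], [], []
        for anc in anchors:
            ref = references[anc]
            anchor_vals = rep.samples[anc][ref.index].to_numpy()
            shifts.append(float(np.median(anchor_vals) - np.median(ref.to_numpy())))
            scales.append(_qq_scale(anchor_vals, ref.to_numpy()))
            centers.append(float(np.median(anchor_vals)))
        shift = float(np.mean(shifts))
        scale = float(np.mean(scales))
        if scale <= 0:
            raise ValueError(f"non-positive scale factor for replicate {rep.replicate_id}")
        center = float(np.mean(centers))
        new = rep.copy()
        for allele, series in new.samples.items():
            new.samples[allele] = (series - center) / scale + center - shift
        out_reps.append(new)
        factors.across_shift[rep.replicate_id] = shift
        factors.across_scale[rep.replicate_id] = scale
    return out_reps, factors


def tail_width(values: pd.Series, lo: float = 0.90, hi: float = 0.99) -> float:
    """Upper-tail width: difference of the 99th and 90th percentiles."""
    arr = values.to_numpy(float)
    return float(np.quantile(arr, hi) - np.quantile(arr, lo))


def filter_low_quality_replicates(
    reps: list[AllelicReplicate],
    reference_allele: str | None = None,
    fresh_fraction: float = 0.25,
    stripped_fraction: float = 0.50,
) -> tuple[list[AllelicReplicate], pd.DataFrame]:
    """Drop replicates whose reference sample's upper tail is collapsed.

    Widths are compared against the maximum across replicates; stripped
    arrays get the laxer 50% cutoff.  Call on within-normalized data,
    before the across-replicate pass (which would equalize the widths it
    judges), then re-run across-replicate normalization on the survivors.
    """
    if not reps:
        raise ValueError("no replicates supplied")
    ref = reference_allele or reps[0].anchor_allele
    widths = [tail_width(rep.samples[ref]) for rep in reps]
    max_width = max(widths)
    report_rows, retained = [], []
    for rep, width in zip(reps, widths):
        frac = stripped_fraction if rep.stripped else fresh_fraction
        dropped = width < frac * max_width
        report_rows.append(
            {
                "replicate": rep.replicate_id,
                "tail_width": width,
                "stripped": rep.stripped,
                "cutoff": frac * max_width,
                "dropped": dropped,
            }
        )
        if not dropped:
            retained.append(rep)
    if not retained:
        raise ValueError("all replicates dropped by the tail-width filter")
    return retained, pd.DataFrame(report_rows)
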