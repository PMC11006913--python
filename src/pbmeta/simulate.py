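"""Simulated universal-PBM experiments with known ground truth.

Each probe's foreground is a normal background draw plus a gain-scaled
signal term: the sum over the probe's k-mer occurrences of (truth
affinity x position decay), modulated by a smooth multiplicative spatial
bias field, a per-probe double-stranding (dsDNA amount) factor shared
with the Cy3 channel, and log-normal measurement noise; values are
clipped to the 16-bit scanner range.  Several scans per chamber are
written at different PMT gains, and the Cy3 channel carries
sequence-dependent expected values so the empirical Cy3 normalization in
the preprocessing module has something real to remove.

Outputs are the tab-separated GPR dialect of :mod:`pbmeta.gpr`, a sample
sheet and a truth manifest; all draws derive from the config seed, so a
fixed (seed, config) reproduces every file byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .design import ArrayDesign
from .gpr import write_gpr
from .truth import KmerAffinityTruth


@dataclass
class SimulationConfig:
    seed: int = 0
    bg_mean: float = 300.0        # intensity counts
    bg_sd: float = 40.0
    signal_scale: float = 8000.0  # exponential-like signal scale (alpha)
    nonspecific: float = 0.05     # nonspecific binding floor, affinity units
    noise_sd: float = 0.15        # log-normal sigma, probe measurement noise
    probe_noise_scale_sd: float = 0.5  # log-sd of fixed per-probe noise scale
    probe_bias_sd: float = 1.20   # log-normal sigma of the fixed per-probe bias
    dna_sd: float = 0.10          # log-normal sigma, per-probe dsDNA amount
    spatial_amplitude: float = 0.10
    position_decay: float = 0.02  # per-nt decay away from the free probe end
    saturation: int = 65536       # 2**16 scanner ceiling
    pmt_gains: tuple = (350, 450, 550)
    pmt_gain_multipliers: tuple = (0.5, 1.0, 2.0)
    cy3_scale: float = 1000.0
    cy3_bg_mean: float = 100.0
    cy3_noise_sd: float = 0.05
    cy3_outlier_frac: float = 0.002
    flag_frac: float = 0.001

    def __post_init__(self) -> None:
        for name in ("bg_sd", "signal_scale", "noise_sd", "dna_sd", "cy3_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(self.pmt_gains) != len(self.pmt_gain_multipliers):
            raise ValueError("pmt_gains and pmt_gain_multipliers must align")


def make_layout(
    alleles: list[tuple[str, str]],
    n_replicates: int = 2,
    stripped: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Sample sheet assigning each allele to one chamber on every slide.

    `alleles` is a list of (allele_id, role) with role 'reference' or
    'variant'; slide r is named S{r} and flagged stripped if listed.
    """
    rows = []
    for r in range(1, n_replicates + 1):
        slide = f"S{r}"
        for chamber, (allele, role) in enumerate(alleles, start=1):
            rows.append(
                {
                    "slide_id": slide,
                    "chamber": chamber,
                    "allele_id": allele,
                    "role": role,
                    "stripped": slide in stripped,
                }
            )
    return pd.DataFrame(rows)


def expected_probe_signal(design: ArrayDesign, truth: KmerAffinityTruth, cfg: SimulationConfig) -> np.ndarray:
    """Noise-free per-probe signal term (affinity x position decay, summed)."""
    decay = np.exp(-cfg.position_decay * design.occ_offset.astype(float))
    base = np.bincount(
        design.occ_probe_ix,
        weights=truth.affinity[design.occ_kmer_ix] * decay,
        minlength=design.n_probes,
    )
    return base + cfg.nonspecific


def _spatial_field(design: ArrayDesign, cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    rows = design.probes["row"].to_numpy(float)
    cols = design.probes["col"].to_numpy(float)
    ph = rng.uniform(0, 2 * np.pi, size=4)
    g = 0.5 * (
        np.sin(2 * np.pi * rows / rows.max() + ph[0]) * np.sin(2 * np.pi * cols / cols.max() + ph[1])
        + np.cos(4 * np.pi * rows / rows.max() + ph[2]) * np.cos(4 * np.pi * cols / cols.max() + ph[3])
    )
    return 1.0 + cfg.spatial_amplitude * g


def _at_fraction(design: ArrayDesign) -> np.ndarray:
    return np.array(
        [(s.count("A") + s.count("T")) / len(s) for s in design.probes["sequence"]]
    )


def simulate_chamber_tables(
    design: ArrayDesign,
    truth: KmerAffinityTruth,
    cfg: SimulationConfig,
    slide_ix: int,
    chamber: int,
) -> list[tuple[pd.DataFrame, dict]]:
    """All PMT scans of one chamber as (probe table, header metadata) pairs."""
    rng = np.random.default_rng([cfg.seed, slide_ix, chamber])
    n = design.n_probes
    base = expected_probe_signal(design, truth, cfg)
    # fixed sequence-dependent measurement bias of the protein channel:
    # identical in every chamber/replicate/allele, so it cancels in
    # contrasts but broadens the across-k-mer score distribution
    bias = np.random.default_rng([cfg.seed, 7777]).lognormal(0.0, cfg.probe_bias_sd, size=n)
    bias = np.clip(bias, 0.25, 4.0)  # extreme fixed biases are unphysical
    # fixed per-probe noise scale: probe measurement noise is heteroscedastic,
    # which is what downstream variance moderation has to cope with
    noise_scale = np.exp(
        np.random.default_rng([cfg.seed, 7778]).normal(0.0, cfg.probe_noise_scale_sd, size=n)
    )
    spatial = _spatial_field(design, cfg, rng)
    dna = rng.lognormal(0.0, cfg.dna_sd, size=n)
    noise = np.exp(rng.normal(0.0, 1.0, size=n) * cfg.noise_sd * noise_scale)
    bg_draw = rng.normal(cfg.bg_mean, cfg.bg_sd, size=n)

    cy3_expected = cfg.cy3_scale * (0.6 + 0.8 * _at_fraction(design))
    cy3_noise = rng.lognormal(0.0, cfg.cy3_noise_sd, size=n)
    outlier = rng.random(n) < cfg.cy3_outlier_frac
    cy3_obs = cfg.cy3_bg_mean + cy3_expected * dna * cy3_noise * np.where(outlier, 4.0, 1.0)
    cy3_obs = np.clip(np.rint(cy3_obs), 0, cfg.saturation).astype(np.int64)

    flags = np.where(rng.random(n) < cfg.flag_frac, -100, 0)

    signal = cfg.signal_scale * base * bias * spatial * dna * noise
    tables = []
    for gain, mult in zip(cfg.pmt_gains, cfg.pmt_gain_multipliers):
        fg = np.clip(np.rint(bg_draw + mult * signal), 0, cfg.saturation).astype(np.int64)
        table = pd.DataFrame(
            {
                "Block": 1,
                "Row": design.probes["row"].to_numpy(),
                "Column": design.probes["col"].to_numpy(),
                "ID": design.probes["probe_id"].to_numpy(),
                "F_protein_Median": fg,
                "B_protein_Median": int(round(cfg.bg_mean)),
                "F_cy3_Median": cy3_obs,
                "B_cy3_Median": int(round(cfg.cy3_bg_mean)),
                "Flags": flags,
            }
        )
        meta = {
            "FileType": "pbmeta-gpr-1",
            "PMTGain": str(gain),
            "Allele": truth.allele_id,
        }
        tables.append((table, meta))
    return tables


def simulate_experiment(
    design: ArrayDesign,
    truths: dict[str, KmerAffinityTruth],
    layout: pd.DataFrame,
    cfg: SimulationConfig,
    outdir,
) -> dict:
    """Write GPR files, a sample sheet, and a truth manifest; return paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    unknown = set(layout["allele_id"]) - set(truths)
    if unknown:
        raise ValueError(f"layout references unknown allele id(s): {sorted(unknown)}")

    slide_order = list(dict.fromkeys(layout["slide_id"]))
    sheet_rows = []
    files: list[str] = []
    for _, row in layout.iterrows():
        slide_ix = slide_order.index(row["slide_id"])
        truth = truths[row["allele_id"]]
        paths = []
        for (table, meta) in simulate_chamber_tables(design, truth, cfg, slide_ix, int(row["chamber"])):
            meta = dict(meta, Slide=row["slide_id"], Chamber=str(row["chamber"]))
            name = f"{row['slide_id']}_c{row['chamber']}_g{meta['PMTGain']}.gpr"
            write_gpr(outdir / name, table, meta)
            paths.append(name)
            files.append(name)
        sheet_rows.append(
            {
                "slide_id": row["slide_id"],
                "chamber": int(row["chamber"]),
                "allele_id": row["allele_id"],
                "role": row["role"],
                "stripped": bool(row["stripped"]),
                "gpr_paths": ";".join(paths),
            }
        )
    sheet = pd.DataFrame(sheet_rows)
    sheet_path = outdir / "sample_sheet.tsv"
    sheet.to_csv(sheet_path, sep="\t", index=False)

    ref_ids = [a for a in truths if truths[a].effect.kind == "none"]
    reference = truths[ref_ids[0]] if ref_ids else next(iter(truths.values()))
    kmers = None
    manifest_rows = []
    for allele, truth in truths.items():
        if kmers is None:
            from ._util import decode_kmer

            kmers = [decode_kmer(int(c), truth.k) for c in truth.kmer_codes]
        manifest_rows.append(
            pd.DataFrame(
                {
                    "kmer": kmers,
                    "allele": allele,
                    "reference_affinity": reference.affinity,
                    "variant_affinity": truth.affinity,
                    "effect_kind": truth.effect.kind,
                }
            )
        )
    manifest = pd.concat(manifest_rows, ignore_index=True)
    manifest_path = outdir / "truth_manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False, float_format="%.6g")
    return {"sample_sheet": sheet_path, "manifest": manifest_path, "files": files, "outdir": outdir}


def standard_experiment(
    design: ArrayDesign,
    effect=None,
    motif_seed: int = 11,
    sim_seed: int = 0,
    n_replicates: int = 4,
    motif_width: int | None = None,
):
    """Reference + one variant under the package's standard study conditions.

    Returns (truths, layout, cfg).  The motif width defaults to k-1 (5 for
    the order-8 design) with three degenerate positions; `effect` may be a
    :class:`VariantEffectSpec` or one of "loss" (uniform 0.5x), "gain"
    (uniform 2x), "subset" (4x gain on a motif-adjacent core).
    """
    from .truth import (
        VariantEffectSpec, baseline_affinities, motif_adjacent_core,
        random_motif, simulate_allele_truth,
    )

    width = motif_width or (design.k - 1)
    motif = random_motif(width, seed=motif_seed, n_degenerate=3)
    if isinstance(effect, str):
        effect = {
            "loss": VariantEffectSpec(kind="uniform_scale", scale=0.5),
            "gain": VariantEffectSpec(kind="uniform_scale", scale=2.0),
            "subset": VariantEffectSpec(
                kind="subset_scale", scale=4.0,
                subset_motif=motif_adjacent_core(motif),
            ),
        }[effect]
    base = baseline_affinities(design.kmer_codes, seed=motif_seed + 500_000)
    truths = {
        "REF": simulate_allele_truth(
            design.kmer_codes, design.k, motif, allele_id="REF", baseline=base
        ),
        "VAR": simulate_allele_truth(
            design.kmer_codes, design.k, motif, effect or VariantEffectSpec(),
            allele_id="VAR", baseline=base,
        ),
    }
    layout = make_layout([("REF", "reference"), ("VAR", "variant")], n_replicates)
    return truths, layout, SimulationConfig(seed=sim_seed)
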