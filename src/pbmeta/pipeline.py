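"""End-to-end orchestration: preprocess -> normalize -> fit -> test -> classify.

`run_pipeline` drives the file-based flow (GPR directory + sample sheet
-> result TSVs, plots, calls); `analyze_experiment` runs the same stages
on in-memory scan sets, which is how the simulation-backed test suites
and the null-comparison machinery avoid file round trips.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as _classify
from . import inference, kmerfit, normalize, preprocess
from .design import ArrayDesign, make_debruijn_design
from .simulate import SimulationConfig, simulate_chamber_tables

logger = logging.getLogger("pbmeta")


@dataclass
class RunConfig:
    """Tunables for a pipeline run; defaults reproduce the stated thresholds."""

    design_order: int = 10
    variable_length: int = 41
    design_seed: int = 0
    gpr_dir: str = "."
    sample_sheet: str = "sample_sheet.tsv"
    output_dir: str = "results"
    spatial_window: int = 15
    cy3_threshold: float = 1.0
    q_strict: float = 1e-6
    fdr: float = 0.05
    affinity_fraction: float = 0.15
    min_spec_kmers: int = 10
    n_bins: int = 20
    spline_knots: int = 5
    min_kmers: int = 1000
    max_null_pairs: int | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    design: ArrayDesign
    sheet: pd.DataFrame
    replicates: list
    factors: normalize.NormalizationFactors
    filter_report: pd.DataFrame
    kmer_fit: kmerfit.KmerFitResult
    results: dict          # variant_id -> per-k-mer results table
    models: dict           # variant_id -> fitted model objects
    calls: list
    panel: _classify.ThresholdPanel
    nulls: _classify.NullComparisonSet | None = None

    @property
    def reference(self) -> str:
        roles = self.sheet.drop_duplicates("allele_id").set_index("allele_id")["role"]
        return roles[roles == "reference"].index[0]

    def calls_frame(self) -> pd.DataFrame:
        return _classify.calls_to_frame(self.calls)


# ---------------------------------------------------------------------------
# chamber loading


def load_scan_sets(sheet: pd.DataFrame, gpr_dir) -> dict:
    """(slide, chamber) -> ScanSet read from the GPR directory."""
    gpr_dir = Path(gpr_dir)
    scan_sets = {}
    for _, row in sheet.iterrows():
        scans = [preprocess.read_gpr(gpr_dir / p) for p in row["gpr_paths"].split(";")]
        scan_sets[(row["slide_id"], int(row["chamber"]))] = preprocess.ScanSet(
            chamber_id=f"{row['slide_id']}_c{row['chamber']}", scans=scans
        )
    return scan_sets


def preprocess_chambers(
    scan_sets: dict, spatial_window: int = 15, cy3_threshold: float = 1.0
) -> dict:
    """Scan choice, subtraction, spatial correction and pooled-Cy3 normalization.

    Returns (slide, chamber) -> log2 signal series over unmasked probes.
    The expected-Cy3 reference is the per-probe median across all chambers
    of the run (requires >=2 chambers; with fewer, Cy3 is skipped).
    """
    for scans in scan_sets.values():
        preprocess.select_optimal_scan(scans)
    # exclude saturated probes as a union per slide so the exclusion is
    # symmetric across the alleles of a replicate
    sat_union: dict = {}
    for (slide, _), scans in scan_sets.items():
        sat = preprocess.saturated_probes(scans.chosen_scan())
        sat_union[slide] = sat.union(sat_union.get(slide, sat[:0]))
    adjusted = {}
    for key, scans in scan_sets.items():
        logger.info("chamber %s: chose scan PMT=%s", key, scans.chosen_scan().pmt_gain)
        tbl = preprocess.mask_saturated(scans.chosen_scan(), probes=sat_union[key[0]])
        tbl = preprocess.background_subtract(tbl)
        adjusted[key] = preprocess.spatially_adjust(tbl, window=spatial_window)
    if len(adjusted) >= 2:
        expected = preprocess.pooled_cy3_reference(list(adjusted.values()))
        adjusted = {
            key: preprocess.cy3_normalize(tbl, expected, threshold=cy3_threshold)
            for key, tbl in adjusted.items()
        }
    return {key: preprocess.log2_signal(tbl) for key, tbl in adjusted.items()}


def build_replicates(sheet: pd.DataFrame, signals: dict) -> list:
    """Group chamber signals into per-slide allelic replicates."""
    reps = []
    for slide, group in sheet.groupby("slide_id", sort=False):
        samples = {
            row["allele_id"]: signals[(slide, int(row["chamber"]))]
            for _, row in group.iterrows()
        }
        anchors = group.loc[group["role"] == "reference", "allele_id"]
        if anchors.empty:
            raise ValueError(f"slide {slide} has no reference-role chamber")
        reps.append(
            normalize.AllelicReplicate(
                replicate_id=str(slide),
                slide_id=str(slide),
                samples=samples,
                anchor_allele=anchors.iloc[0],
                stripped=bool(group["stripped"].iloc[0]),
            )
        )
    return reps


def normalize_replicates(reps: list) -> tuple[list, normalize.NormalizationFactors, pd.DataFrame]:
    """Within-replicate TMM, tail-width filtering, then across-replicate shift/scale."""
    factors = normalize.NormalizationFactors()
    reps = [normalize.normalize_within_replicate(rep, factors)[0] for rep in reps]
    if len(reps) > 1:
        reps, report = normalize.filter_low_quality_replicates(reps)
        reps, factors = normalize.normalize_across_replicates(reps, factors=factors)
    else:
        report = pd.DataFrame()
    return reps, factors, report


# ---------------------------------------------------------------------------
# fitting and testing


def fit_alleles(
    reps: list,
    design: ArrayDesign,
    pairs: list | None = None,
) -> tuple[kmerfit.KmerFitResult, dict]:
    """Probe fits (with prior borrowing for single-replicate alleles) and k-mer fits.

    Alleles observed in a single replicate cannot support variance
    moderation on their own; they borrow the (d0, s0^2) prior fitted on
    the anchor allele's replicates.
    """
    probe_index = pd.Index(design.probes["probe_id"], name="probe_id")
    alleles: dict[str, list] = {}
    for rep in reps:
        for allele, series in rep.samples.items():
            alleles.setdefault(allele, []).append(series)
    anchor = reps[0].anchor_allele
    probe_fits: dict[str, kmerfit.ProbeFit] = {}
    prior = None
    for allele in [anchor] + [a for a in alleles if a != anchor]:
        pf = kmerfit.fit_probes(alleles[allele], probe_index, allele_id=allele, prior=prior)
        if prior is None and np.isfinite(pf.d0):
            prior = (pf.d0, pf.s0_sq)
        kmerfit.correct_position_bias(pf, design)
        probe_fits[allele] = pf
    if pairs is None:
        pairs = [(anchor, a) for a in alleles if a != anchor]
    return kmerfit.fit_kmers(probe_fits, design, pairs=pairs), probe_fits


def run_comparisons(
    kfit: kmerfit.KmerFitResult,
    design: ArrayDesign,
    reference: str,
    variants: list,
    cfg: RunConfig,
) -> tuple[dict, dict]:
    results, models = {}, {}
    kmer_strings = design.kmer_strings()
    for variant in variants:
        table, model = inference.run_kmer_tests(
            kfit, reference, variant, kmer_strings,
            n_bins=cfg.n_bins, min_kmers=min(cfg.min_kmers, design.n_kmers),
        )
        results[variant] = table
        models[variant] = model
    return results, models


# ---------------------------------------------------------------------------
# empirical-null machinery


def null_comparison_runner(reps: list, design: ArrayDesign, allele: str, cfg: RunConfig):
    """Runner for reference-vs-reference pseudo comparisons.

    Probe variances are estimated once from all replicates of the allele;
    each pseudo sample supplies its single replicate's probe means with
    those pooled moderated variances.
    """
    probe_index = pd.Index(design.probes["probe_id"], name="probe_id")
    series_by_rep = {
        rep.replicate_id: rep.samples[allele] for rep in reps if allele in rep.samples
    }
    full = kmerfit.fit_probes(list(series_by_rep.values()), probe_index, allele_id=allele)
    kmerfit.correct_position_bias(full, design)
    kmer_strings = design.kmer_strings()

    def runner(_allele: str, ref_group, var_group) -> pd.DataFrame:
        fits = {}
        for name, group in (("pseudo_ref", ref_group), ("pseudo_var", var_group)):
            group = (group,) if isinstance(group, str) else tuple(group)
            if len(group) >= 2:
                pf = kmerfit.fit_probes(
                    [series_by_rep[r] for r in group], probe_index, allele_id=name
                )
                kmerfit.correct_position_bias(pf, design)
            else:
                # single replicate: means from it, variances from the full fit
                mean = series_by_rep[group[0]].reindex(probe_index).to_numpy(float)
                pf = kmerfit.ProbeFit(
                    allele_id=name,
                    mean=mean,
                    raw_var=np.full(len(probe_index), np.nan),
                    moderated_var=full.moderated_var,
                    df=np.zeros(len(probe_index)),
                    n_reps=(np.isfinite(mean)).astype(int),
                    d0=full.d0,
                    s0_sq=full.s0_sq,
                    position_profile=full.position_profile,
                )
            fits[name] = pf
        kfit = kmerfit.fit_kmers(fits, design, pairs=[("pseudo_ref", "pseudo_var")])
        table, _ = inference.run_kmer_tests(
            kfit, "pseudo_ref", "pseudo_var", kmer_strings,
            n_bins=cfg.n_bins, min_kmers=min(cfg.min_kmers, design.n_kmers),
        )
        return table

    return runner


def calibrate_panel(
    reps: list, design: ArrayDesign, reference: str, cfg: RunConfig
) -> tuple[_classify.ThresholdPanel, _classify.NullComparisonSet | None]:
    """Empirical-null panel from reference replicate relabelings (if possible)."""
    rep_ids = [rep.replicate_id for rep in reps if reference in rep.samples]
    panel = _classify.ThresholdPanel(
        affinity_fraction=cfg.affinity_fraction,
        q_strict=cfg.q_strict,
        min_specificity_kmers=cfg.min_spec_kmers,
    )
    if len(rep_ids) < 2:
        logger.warning("fewer than 2 reference replicates; edit-distance thresholds default to 0")
        return panel, None
    runner = null_comparison_runner(reps, design, reference, cfg)
    nulls = _classify.build_null_comparisons(
        {reference: rep_ids}, runner, max_pairs=cfg.max_null_pairs, seed=cfg.seed
    )
    calibrated = _classify.calibrate_fdr_thresholds(nulls, fdr=cfg.fdr)
    panel.edit_thresholds = calibrated.edit_thresholds
    return panel, nulls


# ---------------------------------------------------------------------------
# entry points


def analyze_experiment(
    design: ArrayDesign,
    sheet: pd.DataFrame,
    scan_sets: dict,
    cfg: RunConfig,
    calibrate: bool = True,
) -> PipelineResult:
    """All pipeline stages on in-memory scan sets."""
    signals = preprocess_chambers(scan_sets, cfg.spatial_window, cfg.cy3_threshold)
    reps = build_replicates(sheet, signals)
    reps, factors, report = normalize_replicates(reps)
    kfit, _ = fit_alleles(reps, design)
    roles = sheet.drop_duplicates("allele_id").set_index("allele_id")["role"]
    reference = roles[roles == "reference"].index[0]
    variants = [a for a in kfit.alleles() if a != reference]
    results, models = run_comparisons(kfit, design, reference, variants, cfg)
    if calibrate:
        panel, nulls = calibrate_panel(reps, design, reference, cfg)
    else:
        panel, nulls = _classify.ThresholdPanel(
            affinity_fraction=cfg.affinity_fraction,
            q_strict=cfg.q_strict,
            min_specificity_kmers=cfg.min_spec_kmers,
        ), None
    calls = [_classify.call_variant(v, results[v], panel) for v in variants]
    return PipelineResult(
        design=design, sheet=sheet, replicates=reps, factors=factors,
        filter_report=report, kmer_fit=kfit, results=results, models=models,
        calls=calls, panel=panel, nulls=nulls,
    )


def simulate_scan_sets(
    design: ArrayDesign, truths: dict, layout: pd.DataFrame, sim_cfg: SimulationConfig
) -> dict:
    """In-memory ScanSets for a simulated experiment (no files written)."""
    slide_order = list(dict.fromkeys(layout["slide_id"]))
    scan_sets = {}
    for _, row in layout.iterrows():
        slide_ix = slide_order.index(row["slide_id"])
        tables = simulate_chamber_tables(
            design, truths[row["allele_id"]], sim_cfg, slide_ix, int(row["chamber"])
        )
        scans = [preprocess.probe_table_from_frame(t, m) for t, m in tables]
        scan_sets[(row["slide_id"], int(row["chamber"]))] = preprocess.ScanSet(
            chamber_id=f"{row['slide_id']}_c{row['chamber']}", scans=scans
        )
    return scan_sets


def simulated_run(
    design: ArrayDesign,
    truths: dict,
    layout: pd.DataFrame,
    sim_cfg: SimulationConfig,
    cfg: RunConfig | None = None,
    calibrate: bool = True,
) -> PipelineResult:
    """Simulate an experiment and analyze it end to end, in memory."""
    cfg = cfg or RunConfig(design_order=design.order, variable_length=design.variable_length)
    sheet = layout.copy()
    if "gpr_paths" not in sheet.columns:
        sheet["gpr_paths"] = ""
    scan_sets = simulate_scan_sets(design, truths, layout, sim_cfg)
    return analyze_experiment(design, sheet, scan_sets, cfg, calibrate=calibrate)


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """File-based end-to-end run; writes TSVs, plots and a summary."""
    import yaml

    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, filename=outdir / "run.log", filemode="w")
    design = make_debruijn_design(cfg.design_order, cfg.variable_length, cfg.design_seed)
    sheet = pd.read_csv(cfg.sample_sheet, sep="\t")
    scan_sets = load_scan_sets(sheet, cfg.gpr_dir)
    result = analyze_experiment(design, sheet, scan_sets, cfg)

    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh)
    result.factors.to_frame().to_csv(outdir / "normalization_factors.tsv", sep="\t", index=False)
    if not result.filter_report.empty:
        result.filter_report.to_csv(outdir / "replicate_filter.tsv", sep="\t", index=False)
    result.kmer_fit.to_frame(design.kmer_strings()).to_csv(
        outdir / "kmer_fits.tsv", sep="\t", index=False, float_format="%.6g"
    )
    for variant, table in result.results.items():
        table.to_csv(outdir / f"{variant}_results.tsv", sep="\t", index=False, float_format="%.6g")
    result.calls_frame().to_csv(outdir / "calls.tsv", sep="\t", index=False)
    with open(outdir / "thresholds.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "affinity_fraction": result.panel.affinity_fraction,
                "q_strict": result.panel.q_strict,
                "min_specificity_kmers": result.panel.min_specificity_kmers,
                "edit_thresholds": {
                    f"d<{d},q<{q}": int(t) for (d, q), t in result.panel.edit_thresholds.items()
                },
            },
            fh,
        )
    try:
        from .plots import contrast_plot, specificity_plot

        plot_dir = outdir / "plots"
        plot_dir.mkdir(exist_ok=True)
        for variant, table in result.results.items():
            contrast_plot(table, plot_dir / f"{variant}_contrast.png", title=variant)
            specificity_plot(
                table, result.models[variant]["trend"],
                plot_dir / f"{variant}_specificity.png", title=variant,
            )
    except Exception as exc:  # plotting must not sink a finished analysis
        logger.warning("plot rendering failed: %s", exc)
    return result
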