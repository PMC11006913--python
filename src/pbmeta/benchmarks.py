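"""Self-contained validation studies on synthetic data.

Each function simulates experiments under the package's standard study
conditions (order-8 design: 6-mer features, 2080 RC-collapsed k-mers,
4096 probes, 4 allelic replicates), runs the full pipeline, and reports
summary numbers: null-comparison false-call rates and z-score
calibration, planted-effect recovery rates, and estimator parameter
recovery.  The acceptance machinery and parts of the test suite are thin
wrappers around these functions.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from ._util import revcomp
from .design import ArrayDesign, cyclic_coverage_counts, de_bruijn_sequence, make_debruijn_design
from .inference import fit_normexp
from .normalize import AllelicReplicate, normalize_across_replicates, tmm_shift
from .pipeline import RunConfig, simulated_run
from .simulate import SimulationConfig, make_layout, standard_experiment
from .truth import (
    VariantEffectSpec, baseline_affinities, motif_adjacent_core, random_motif,
    simulate_allele_truth,
)

STANDARD_ORDER = 8
STANDARD_VARIABLE_LENGTH = 23


def standard_design(order: int = STANDARD_ORDER) -> ArrayDesign:
    length = STANDARD_VARIABLE_LENGTH if order == 8 else order * 2 + 7
    return make_debruijn_design(order, length, seed=0)


def standard_run_config() -> RunConfig:
    return RunConfig(design_order=STANDARD_ORDER, variable_length=STANDARD_VARIABLE_LENGTH)


def debruijn_coverage_summary(order: int = 10, seed: int = 0) -> dict:
    """Combined-strand occurrence counts of RC-collapsed (order-2)-mers."""
    seq = de_bruijn_sequence(order, seed)
    cov = cyclic_coverage_counts(seq, order - 2)
    pal = cov["palindromic"]
    return {
        "nonpalindromic_counts": sorted(set(cov["counts"][~pal].tolist())),
        "palindromic_counts": sorted(set(cov["counts"][pal].tolist())),
        "n_features": int(len(cov["codes"])),
    }


def _seed_ints(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2 ** 31 - 1, size=n)


def null_calibration(
    n_experiments: int = 9,
    variants_per_experiment: int = 12,
    seed: int = 0,
    design: ArrayDesign | None = None,
) -> dict:
    """Reference-vs-reference false-call rate and contrast z calibration.

    Each experiment carries one reference and `variants_per_experiment`
    pseudo-variants with identical truth but independent chambers; the
    classifier (thresholds calibrated from the reference's own replicate
    splits) is applied to every pseudo-variant.
    """
    design = design or standard_design()
    cfg = standard_run_config()
    seeds = _seed_ints(seed, 2 * n_experiments).reshape(2, -1)
    n_altered = 0
    n_total = 0
    ks_pvalues = []
    for e in range(n_experiments):
        motif = random_motif(design.k - 1, seed=int(seeds[0, e]), n_degenerate=3)
        base = baseline_affinities(design.kmer_codes, seed=int(seeds[0, e]) + 500_000)
        truths = {
            "REF": simulate_allele_truth(design.kmer_codes, design.k, motif,
                                         allele_id="REF", baseline=base)
        }
        alleles = [("REF", "reference")]
        for v in range(variants_per_experiment):
            name = f"NULL{v:02d}"
            truths[name] = simulate_allele_truth(
                design.kmer_codes, design.k, motif, allele_id=name, baseline=base
            )
            alleles.append((name, "variant"))
        layout = make_layout(alleles, n_replicates=4)
        sim = SimulationConfig(seed=int(seeds[1, e]))
        result = simulated_run(design, truths, layout, sim, cfg)
        for call in result.calls:
            n_total += 1
            if call.affinity_call != "none" or call.specificity_call != "none":
                n_altered += 1
        z = result.results[f"NULL00"]["contrast_z"].dropna().to_numpy()
        ks_pvalues.append(float(stats.kstest(z, "norm").pvalue))
    return {
        "n_comparisons": n_total,
        "n_altered": n_altered,
        "altered_fraction": n_altered / n_total,
        "binomial_bound": 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_total),
        "ks_pvalues": ks_pvalues,
        "ks_mean_p": float(np.mean(ks_pvalues)),
    }


def _recovery(effect_name: str, n_seeds: int, seed: int, design: ArrayDesign | None):
    design = design or standard_design()
    cfg = standard_run_config()
    seeds = _seed_ints(seed, 2 * n_seeds).reshape(2, -1)
    outcomes = []
    for i in range(n_seeds):
        truths, layout, sim = standard_experiment(
            design, effect_name, motif_seed=int(seeds[0, i]), sim_seed=int(seeds[1, i])
        )
        result = simulated_run(design, truths, layout, sim, cfg)
        outcomes.append((result.calls[0], truths))
    return outcomes


def loss_recovery(n_seeds: int = 20, seed: int = 0, design: ArrayDesign | None = None) -> dict:
    """Planted uniform 0.5x loss: affinity-loss call with no specificity call."""
    outcomes = _recovery("loss", n_seeds, seed, design)
    loss_calls = sum(1 for c, _ in outcomes if c.affinity_call == "loss")
    clean = sum(
        1 for c, _ in outcomes
        if c.affinity_call == "loss" and c.specificity_call == "none"
    )
    return {
        "n_seeds": n_seeds,
        "loss_call_rate": loss_calls / n_seeds,
        "loss_and_no_specificity_rate": clean / n_seeds,
    }


def subset_recovery(n_seeds: int = 10, seed: int = 1, design: ArrayDesign | None = None) -> dict:
    """Planted 4x gain on a motif-adjacent core: specificity call + seed identity."""
    outcomes = _recovery("subset", n_seeds, seed, design)
    altered = 0
    seed_hit = 0
    for call, truths in outcomes:
        core = truths["VAR"].effect.subset_motif
        if call.specificity_call == "altered":
            altered += 1
            sp = call.evidence.get("seed_pos") or ""
            if sp and (core in sp or core in revcomp(sp)):
                seed_hit += 1
    return {
        "n_seeds": n_seeds,
        "specificity_call_rate": altered / n_seeds,
        "seed_contains_core_rate": seed_hit / n_seeds,
    }


def normexp_recovery(seed: int = 0, n: int = 32896, mu: float = 8.0,
                     sigma: float = 0.3, alpha: float = 1.5) -> dict:
    rng = np.random.default_rng(seed)
    x = rng.normal(mu, sigma, n) + rng.exponential(alpha, n)
    params = fit_normexp(x)
    return {
        "mu": params.mu, "sigma": params.sigma, "alpha": params.alpha,
        "mu_rel_error": abs(params.mu - mu) / mu,
        "sigma_rel_error": abs(params.sigma - sigma) / sigma,
        "alpha_rel_error": abs(params.alpha - alpha) / alpha,
    }


def normalization_recovery(seed: int = 0, n_probes: int = 2000) -> dict:
    """TMM shift under contamination and QQ-slope scale recovery."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    base = pd.Series(rng.normal(10, 1, n_probes),
                     index=[f"P{i:05d}" for i in range(n_probes)])
    shifted = base + 1.0
    idx = rng.choice(n_probes, size=n_probes // 20, replace=False)
    shifted.iloc[idx] += 5.0
    tmm = tmm_shift(shifted, base)

    med = base.median()
    scaled = (base - med) * 2.0 + med
    reps = [
        AllelicReplicate("R1", "R1", {"REF": base}, "REF"),
        AllelicReplicate("R2", "R2", {"REF": scaled}, "REF"),
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, factors = normalize_across_replicates(reps)
    # the cross-replicate reference is the mean of the two, so the planted
    # x2 scale appears as the ratio of the replicates' slopes
    ratio = factors.across_scale["R2"] / factors.across_scale["R1"]
    return {
        "tmm_shift": float(tmm),
        "tmm_abs_error": abs(tmm - 1.0),
        "qq_scale_ratio": float(ratio),
        "qq_scale_rel_error": abs(ratio - 2.0) / 2.0,
    }
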