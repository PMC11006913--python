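"""Variant-level calls from per-k-mer test results.

A variant is called *affinity-altered* when more than 15% (strict) of the
reference-preferential k-mers (affinityQ < 1e-6) are differential
(contrastQ < 1e-6) in one direction; the direction with the larger
fraction names the call (loss/gain).

A variant is called *specificity-altered* by either of two rules:

- primary: at least 10 k-mers preferential in the reference OR the
  variant (affinityQ < 1e-6) with specificityQ < 1e-6;
- edit-distance: per residual sign, the k-mer with the maximal
  |contrastResidual| seeds a Levenshtein neighbourhood; the variant is
  called when, for every (distance cutoff, specificityQ cutoff)
  combination in the panel, the count of same-sign k-mers within the
  cutoff distance of the seed exceeds a threshold calibrated at 5% FDR
  on empirical null comparisons (reference replicates relabeled as
  pseudo-reference and pseudo-variant).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from ._util import revcomp

Q_STRICT = 1e-6
AFFINITY_FRACTION = 0.15
MIN_SPECIFICITY_KMERS = 10
DEFAULT_PANEL = ((2, 0.05), (2, 0.01), (3, 0.05), (3, 0.01))


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance between two DNA words."""
    for s in (a, b):
        if not s or any(c not in "ACGT" for c in s):
            raise ValueError(f"non-DNA or empty k-mer: {s!r}")
    return int(edlib.align(a, b, task="distance", mode="NW")["editDistance"])


def levenshtein_rc(a: str, b: str) -> int:
    """Edit distance of RC-collapsed features: min over orientation of b."""
    return min(levenshtein(a, b), levenshtein(a, revcomp(b)))


# ---------------------------------------------------------------------------
# thresholds and null comparisons


@dataclass
class ThresholdPanel:
    """Decision thresholds for the affinity and specificity criteria."""

    affinity_fraction: float = AFFINITY_FRACTION
    q_strict: float = Q_STRICT
    min_specificity_kmers: int = MIN_SPECIFICITY_KMERS
    # (distance_cut, specificityQ_cut) -> minimal count that must be exceeded
    edit_thresholds: dict = field(
        default_factory=lambda: {combo: 0 for combo in DEFAULT_PANEL}
    )


def edit_cluster_counts(
    results: pd.DataFrame,
    panel_combos=DEFAULT_PANEL,
) -> dict:
    """Per-sign seed k-mers and neighbourhood counts for every panel combination.

    Returns {"+": {"seed": str|None, "counts": {(d, q): int}}, "-": ...}.
    Counts are restricted to k-mers whose contrastResidual has the seed's
    sign; distances are RC-collapsed Levenshtein to the seed.  The seed
    itself is not counted: the cluster criterion measures how many OTHER
    k-mers share sequence similarity with the anchor, so a lone
    significant k-mer cannot be its own cluster.
    """
    out = {}
    residual = results["contrastResidual"].to_numpy()
    for sign, sel in (("+", residual > 0), ("-", residual < 0)):
        if not sel.any():
            out[sign] = {"seed": None, "counts": {c: 0 for c in panel_combos}}
            continue
        sub = results.loc[sel]
        seed_ix = sub["contrastResidual"].abs().idxmax()
        seed = sub.loc[seed_ix, "kmer"]
        sub = sub.drop(index=seed_ix)
        dists = np.array([levenshtein_rc(seed, k) for k in sub["kmer"]])
        counts = {}
        for d_cut, q_cut in panel_combos:
            counts[(d_cut, q_cut)] = int(
                ((dists < d_cut) & (sub["specificityQ"].to_numpy() < q_cut)).sum()
            )
        out[sign] = {"seed": seed, "counts": counts}
    return out


def comparison_metrics(results: pd.DataFrame, panel_combos=DEFAULT_PANEL) -> dict:
    """All count metrics for one comparison, as used by the null calibration."""
    pref_ref = results["affinityQ_ref"] < Q_STRICT
    pref_any = pref_ref | (results["affinityQ_var"] < Q_STRICT)
    diff = results["contrastQ"] < Q_STRICT
    neg = results["contrast"] < 0
    n_pref = int(pref_ref.sum())
    metrics = {
        "n_preferential": n_pref,
        "frac_differential_neg": float((pref_ref & diff & neg).sum() / n_pref) if n_pref else 0.0,
        "frac_differential_pos": float((pref_ref & diff & ~neg).sum() / n_pref) if n_pref else 0.0,
        "n_spec_kmers": int((pref_any & (results["specificityQ"] < Q_STRICT)).sum()),
    }
    clusters = edit_cluster_counts(results, panel_combos)
    for sign in ("+", "-"):
        for combo, count in clusters[sign]["counts"].items():
            metrics[("edit", sign, combo)] = count
    metrics["seeds"] = {s: clusters[s]["seed"] for s in ("+", "-")}
    return metrics


@dataclass
class NullComparisonSet:
    """Replicate-relabeled reference-vs-reference comparisons and their metrics."""

    comparisons: list  # (allele_id, rep_a, rep_b)
    metrics: list      # comparison_metrics dict per comparison

    def counts(self, key) -> np.ndarray:
        return np.array([m[key] for m in self.metrics])


def enumerate_null_pairs(
    replicate_ids: dict[str, list],
    max_pairs: int | None = None,
    seed: int = 0,
) -> list[tuple[str, tuple, tuple]]:
    """Balanced pseudo-reference/pseudo-variant replicate splits per allele.

    For n replicates, every choice of floor(n/2) replicates as the
    pseudo-reference (the complement's first floor(n/2) as pseudo-variant)
    gives one comparison: n=2 yields 1, n=4 yields C(4,2)=6.  Splitting
    into groups rather than single replicates keeps the null comparisons
    on the same fitting path (replicate-level variances) as real
    variant-vs-reference comparisons.  An optional cap subsamples
    deterministically from `seed`.
    """
    pairs = []
    for allele, reps in replicate_ids.items():
        if len(reps) < 2:
            continue
        half = len(reps) // 2
        seen = set()
        for ref_group in itertools.combinations(reps, half):
            var_group = tuple(r for r in reps if r not in ref_group)[:half]
            key = frozenset([ref_group, var_group])
            if len(reps) == 2 and key in seen:
                continue  # a single pair is one comparison, not two
            seen.add(key)
            pairs.append((allele, ref_group, var_group))
    if not pairs:
        raise ValueError("need >=2 replicates for >=1 reference allele")
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in sorted(keep)]
    return pairs


def build_null_comparisons(
    replicate_ids: dict[str, list],
    runner,
    panel_combos=DEFAULT_PANEL,
    max_pairs: int | None = None,
    seed: int = 0,
) -> NullComparisonSet:
    """Run the full test stack on every pseudo reference/variant replicate pair.

    `runner(allele, ref_group, var_group)` must return the per-k-mer
    results table for the comparison treating ref_group's replicates as
    the pseudo-reference.
    """
    pairs = enumerate_null_pairs(replicate_ids, max_pairs=max_pairs, seed=seed)
    metrics = [comparison_metrics(runner(allele, a, b), panel_combos) for allele, a, b in pairs]
    return NullComparisonSet(comparisons=pairs, metrics=metrics)


def _fdr_count_threshold(null_counts: np.ndarray, fdr: float) -> int:
    """Smallest integer c with P_null(count > c) <= fdr."""
    c = 0
    n = len(null_counts)
    while np.sum(null_counts > c) / n > fdr:
        c += 1
    return int(c)


def calibrate_fdr_thresholds(
    nulls: NullComparisonSet,
    fdr: float = 0.05,
    panel_combos=DEFAULT_PANEL,
) -> ThresholdPanel:
    """Edit-distance count thresholds at the given empirical FDR.

    Null counts for + and - residual signs are pooled per combination
    (the null has no preferred sign).
    """
    if not nulls.metrics:
        raise ValueError("empty null comparison set")
    if len(nulls.metrics) < 10:
        warnings.warn(f"only {len(nulls.metrics)} null comparisons; thresholds will be coarse")
    panel = ThresholdPanel()
    for combo in panel_combos:
        pooled = np.concatenate([nulls.counts(("edit", s, combo)) for s in ("+", "-")])
        panel.edit_thresholds[combo] = _fdr_count_threshold(pooled, fdr)
    return panel


# ---------------------------------------------------------------------------
# variant calls


@dataclass
class VariantCall:
    variant_id: str
    affinity_call: str      # loss | gain | none
    specificity_call: str   # altered | none
    evidence: dict


def call_affinity_change(results: pd.DataFrame, panel: ThresholdPanel) -> tuple[str, dict]:
    """Affinity loss/gain call from the fraction of differential preferential k-mers."""
    pref = results["affinityQ_ref"] < panel.q_strict
    n_pref = int(pref.sum())
    if n_pref == 0:
        warnings.warn("empty reference preferential set; affinity call is 'none'")
        return "none", {"n_preferential": 0, "frac_loss": 0.0, "frac_gain": 0.0}
    diff = results["contrastQ"] < panel.q_strict
    neg = results["contrast"] < 0
    frac_loss = float((pref & diff & neg).sum() / n_pref)
    frac_gain = float((pref & diff & ~neg).sum() / n_pref)
    evidence = {"n_preferential": n_pref, "frac_loss": frac_loss, "frac_gain": frac_gain}
    best = max(frac_loss, frac_gain)
    if best > panel.affinity_fraction:  # strict inequality
        return ("loss" if frac_loss >= frac_gain else "gain"), evidence
    return "none", evidence


def call_specificity_change(results: pd.DataFrame, panel: ThresholdPanel) -> tuple[str, dict]:
    """Specificity call from the primary count rule OR the edit-distance rule."""
    pref_any = (results["affinityQ_ref"] < panel.q_strict) | (
        results["affinityQ_var"] < panel.q_strict
    )
    n_spec = int((pref_any & (results["specificityQ"] < panel.q_strict)).sum())
    primary = n_spec >= panel.min_specificity_kmers

    clusters = edit_cluster_counts(results, tuple(panel.edit_thresholds))
    edit_call = False
    sign_pass = {}
    for sign in ("+", "-"):
        counts = clusters[sign]["counts"]
        passed = clusters[sign]["seed"] is not None and all(
            counts[combo] > thr for combo, thr in panel.edit_thresholds.items()
        )
        sign_pass[sign] = passed
        edit_call = edit_call or passed
    evidence = {
        "n_spec_kmers": n_spec,
        "primary_rule": primary,
        "edit_rule": edit_call,
        "seed_pos": clusters["+"]["seed"],
        "seed_neg": clusters["-"]["seed"],
        "edit_counts_pos": clusters["+"]["counts"],
        "edit_counts_neg": clusters["-"]["counts"],
        "edit_sign_pass": sign_pass,
    }
    return ("altered" if (primary or edit_call) else "none"), evidence


def call_variant(variant_id: str, results: pd.DataFrame, panel: ThresholdPanel) -> VariantCall:
    affinity_call, aff_ev = call_affinity_change(results, panel)
    specificity_call, spec_ev = call_specificity_change(results, panel)
    return VariantCall(
        variant_id=variant_id,
        affinity_call=affinity_call,
        specificity_call=specificity_call,
        evidence={**aff_ev, **spec_ev},
    )


def calls_to_frame(calls: list[VariantCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        ev = c.evidence
        row = {
            "variant": c.variant_id,
            "affinity_call": c.affinity_call,
            "specificity_call": c.specificity_call,
            "n_preferential": ev.get("n_preferential"),
            "frac_loss": ev.get("frac_loss"),
            "frac_gain": ev.get("frac_gain"),
            "n_spec_kmers": ev.get("n_spec_kmers"),
            "seed_neg": ev.get("seed_neg"),
            "seed_pos": ev.get("seed_pos"),
        }
        for sign, key in (("+", "edit_counts_pos"), ("-", "edit_counts_neg")):
            for (d_cut, q_cut), count in (ev.get(key) or {}).items():
                row[f"edit{sign}_d{d_cut}_q{q_cut}"] = count
        rows.append(row)
    return pd.DataFrame(rows)
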