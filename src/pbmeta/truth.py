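"""Ground-truth k-mer affinities and planted variant effects.

Reference affinities come from a position-specific energy matrix: the
relative affinity of a k-mer is exp(-E) for the best-scoring placement of
the matrix on either strand, rescaled so the best k-mer has affinity 1.
Variant effects are applied on top of the reference truth:

- ``uniform_scale`` multiplies every affinity (affinity loss/gain),
- ``subset_scale``  multiplies only k-mers matching an IUPAC core on
  either strand (specificity loss/gain),
- ``motif_swap``    regenerates affinities from a second matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import decode_kmer, iupac_matches, validate_iupac


@dataclass
class EnergyMatrix:
    """Binding energy penalties, shape (width, 4); consensus rows are 0."""

    penalties: np.ndarray

    @property
    def width(self) -> int:
        return self.penalties.shape[0]


def random_motif(
    width: int,
    seed: int,
    n_degenerate: int = 2,
    penalty_low: float = 3.5,
    penalty_high: float = 5.0,
    degenerate_low: float = 0.2,
    degenerate_high: float = 0.9,
) -> EnergyMatrix:
    """Random energy matrix with specific and degenerate positions.

    Specific positions penalize every non-consensus base steeply
    (mismatches drop affinity 30-150x), while degenerate positions
    tolerate one alternative base at a mild penalty - mirroring real
    TF motifs, where a conserved core is flanked by looser positions
    and tens of k-mers are bound within an order of magnitude of the
    optimum.
    """
    rng = np.random.default_rng(seed)
    pen = rng.uniform(penalty_low, penalty_high, size=(width, 4))
    consensus = rng.integers(0, 4, size=width)
    pen[np.arange(width), consensus] = 0.0
    degen = rng.choice(width, size=min(n_degenerate, width), replace=False)
    for pos in degen:
        alt = (consensus[pos] + rng.integers(1, 4)) % 4
        pen[pos, alt] = rng.uniform(degenerate_low, degenerate_high)
    return EnergyMatrix(pen)


@dataclass
class VariantEffectSpec:
    kind: str = "none"  # none | uniform_scale | subset_scale | motif_swap
    scale: float = 1.0
    subset_motif: str | None = None
    swap_motif: EnergyMatrix | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"none", "uniform_scale", "subset_scale", "motif_swap"}:
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.kind == "subset_scale":
            if not self.subset_motif:
                raise ValueError("subset_scale requires subset_motif")
            validate_iupac(self.subset_motif)
        if self.kind == "motif_swap" and self.swap_motif is None:
            raise ValueError("motif_swap requires swap_motif")


@dataclass
class KmerAffinityTruth:
    """Per canonical k-mer relative affinity plus the generating motif."""

    allele_id: str
    k: int
    kmer_codes: np.ndarray
    affinity: np.ndarray
    motif: EnergyMatrix
    effect: VariantEffectSpec = field(default_factory=VariantEffectSpec)


def _motif_affinities(kmer_codes: np.ndarray, k: int, motif: EnergyMatrix) -> np.ndarray:
    """max over placements/strands of exp(-energy), rescaled to max 1."""
    if motif.width > k:
        raise ValueError("motif width must be <= k")
    n = len(kmer_codes)
    digits = np.empty((n, k), dtype=np.int64)
    tmp = np.asarray(kmer_codes, dtype=np.int64).copy()
    for i in range(k - 1, -1, -1):
        digits[:, i] = tmp & 3
        tmp >>= 2
    rc_digits = 3 - digits[:, ::-1]
    w = motif.width
    best = np.full(n, np.inf)
    for strand_digits in (digits, rc_digits):
        for off in range(k - w + 1):
            e = np.zeros(n)
            for j in range(w):
                e += motif.penalties[j, strand_digits[:, off + j]]
            best = np.minimum(best, e)
    aff = np.exp(-best)
    return aff / aff.max()


def baseline_affinities(
    kmer_codes: np.ndarray,
    seed: int,
    median: float = 0.0003,
    log_sd: float = 1.5,
    cap: float = 0.3,
) -> np.ndarray:
    """Heavy-tailed per-k-mer baseline (nonspecific) binding affinities.

    Real TFs bind most k-mers weakly but non-uniformly; this sequence-
    independent baseline spreads the bulk of the across-k-mer score
    distribution the way real PBM data are spread.  It is a property of
    the protein-DNA pair, so variant effects scale it along with the
    motif-driven affinity.
    """
    rng = np.random.default_rng(seed)
    return np.minimum(rng.lognormal(np.log(median), log_sd, size=len(kmer_codes)), cap)


def simulate_allele_truth(
    kmer_codes: np.ndarray,
    k: int,
    motif: EnergyMatrix,
    effect: VariantEffectSpec | None = None,
    allele_id: str = "allele",
    seed: int = 0,
    baseline: np.ndarray | None = None,
) -> KmerAffinityTruth:
    """Reference affinities from `motif` plus baseline, with the effect applied.

    The motif-driven part is normalized to max 1; `baseline` (shared
    between the alleles of a series) adds weak non-motif binding.  Scaled
    variants keep the reference normalization so planted fold changes are
    exact.
    """
    effect = effect or VariantEffectSpec()
    aff = _motif_affinities(kmer_codes, k, motif)
    if baseline is not None:
        aff = aff + baseline
    if effect.kind == "uniform_scale":
        aff = aff * effect.scale
    elif effect.kind == "subset_scale":
        pattern = effect.subset_motif
        match = np.array(
            [iupac_matches(decode_kmer(int(c), k), pattern) for c in kmer_codes]
        )
        aff = np.where(match, aff * effect.scale, aff)
    elif effect.kind == "motif_swap":
        aff = _motif_affinities(kmer_codes, k, effect.swap_motif)
        if baseline is not None:
            aff = aff + baseline
    return KmerAffinityTruth(
        allele_id=allele_id, k=k, kmer_codes=np.asarray(kmer_codes), affinity=aff,
        motif=motif, effect=effect,
    )


def motif_adjacent_core(motif: EnergyMatrix, length: int = 4, mut_pos: int | None = None) -> str:
    """IUPAC core for a planted specificity change, adjacent to the motif.

    Takes the motif consensus, substitutes one position with a base the
    reference does not tolerate, and returns a window of the requested
    length around it.  Specificity-altering variants gain or lose binding
    to sequences related to the canonical site, so planting effects on a
    motif-adjacent core (rather than an arbitrary word) mirrors the
    biology and guarantees the affected k-mers overlap the bound
    repertoire.
    """
    from ._util import BASES

    consensus = list(np.argmin(motif.penalties, axis=1))
    if mut_pos is None:
        mut_pos = motif.width // 2
    # pick the worst-tolerated alternative base: a genuine specificity change
    alt = int(np.argmax(motif.penalties[mut_pos]))
    consensus[mut_pos] = alt
    start = min(max(mut_pos - length // 2, 0), motif.width - length)
    return "".join(BASES[b] for b in consensus[start:start + length])
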