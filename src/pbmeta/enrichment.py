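"""Region-level k-mer enrichment (ChIP-seq foreground vs matched background).

Regions are fixed-width sequence windows (150 nt by default, e.g. centered
on peak summits).  A region counts as containing a k-mer if the k-mer or
its reverse complement occurs at least once (presence/absence, N never
matches); enrichment of foreground over background containment is tested
with a one-tailed Fisher's exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO
from scipy.stats import fisher_exact

from ._util import revcomp

DEFAULT_WIDTH = 150


@dataclass
class RegionSet:
    names: list
    sequences: list
    width: int | None = DEFAULT_WIDTH

    def __post_init__(self) -> None:
        self.sequences = [s.upper() for s in self.sequences]
        bad = [n for n, s in zip(self.names, self.sequences) if set(s) - set("ACGTN")]
        if bad:
            raise ValueError(f"non-ACGTN characters in region(s): {bad[:3]}")
        if self.width is not None:
            off = [n for n, s in zip(self.names, self.sequences) if len(s) != self.width]
            if off:
                raise ValueError(
                    f"{len(off)} region(s) deviate from width {self.width}; "
                    "pass width=None to disable the check"
                )

    def __len__(self) -> int:
        return len(self.sequences)


def read_fasta_regions(path, width: int | None = DEFAULT_WIDTH) -> RegionSet:
    records = list(SeqIO.parse(str(path), "fasta"))
    return RegionSet([r.id for r in records], [str(r.seq) for r in records], width=width)


def extract_bed_windows(bed_path, genome_fasta, width: int = DEFAULT_WIDTH) -> RegionSet:
    """Fixed windows around BED interval midpoints (0-based half-open BED).

    The summit is taken as the interval midpoint; windows running off a
    contig end are dropped with a warning.
    """
    from pyfaidx import Fasta

    genome = Fasta(str(genome_fasta))
    names, seqs, dropped = [], [], 0
    with open(bed_path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            mid = (start + end) // 2
            lo, hi = mid - width // 2, mid - width // 2 + width
            if chrom not in genome or lo < 0 or hi > len(genome[chrom]):
                dropped += 1
                continue
            name = fields[3] if len(fields) > 3 and fields[3] else f"region{i}"
            names.append(name)
            seqs.append(str(genome[chrom][lo:hi]))
    if dropped:
        warnings.warn(f"dropped {dropped} window(s) extending beyond contig bounds")
    return RegionSet(names, seqs, width=width)


def count_kmer_regions(rs: RegionSet, kmer: str) -> int:
    """Number of regions containing `kmer` or its reverse complement."""
    kmer = kmer.upper()
    if set(kmer) - set("ACGT"):
        raise ValueError("query k-mer must be over ACGT")
    rc = revcomp(kmer)
    probes = (kmer,) if rc == kmer else (kmer, rc)
    return sum(1 for s in rs.sequences if any(p in s for p in probes))


def test_kmer_enrichment(fg: RegionSet, bg: RegionSet, kmer: str) -> dict:
    """One-tailed Fisher's exact test for k-mer enrichment in the foreground.

    Returns the p-value and the 2x2 table
    [[fg_with, fg_without], [bg_with, bg_without]].
    """
    if len(fg) == 0 or len(bg) == 0:
        raise ValueError("both region sets must be non-empty")
    fg_with = count_kmer_regions(fg, kmer)
    bg_with = count_kmer_regions(bg, kmer)
    table = [[fg_with, len(fg) - fg_with], [bg_with, len(bg) - bg_with]]
    _, p = fisher_exact(table, alternative="greater")
    return {"p": float(p), "table": table, "kmer": kmer.upper()}


def sample_gc_matched_background(
    fg: RegionSet, pool: RegionSet, seed: int = 0, n_quantiles: int = 5
) -> RegionSet:
    """Naive GC-quantile-matched sampler for synthetic tests.

    Draws one pool region per foreground region from the same GC-content
    quantile bin (with replacement within a bin).  A stand-in for
    properly matched genomic backgrounds, which are consumed as input.
    """
    import numpy as np

    def gc(seqs):
        return np.array([(s.count("G") + s.count("C")) / max(len(s), 1) for s in seqs])

    rng = np.random.default_rng(seed)
    gc_pool = gc(pool.sequences)
    edges = np.quantile(gc_pool, np.linspace(0, 1, n_quantiles + 1))
    pool_bin = np.clip(np.searchsorted(edges, gc_pool, side="right") - 1, 0, n_quantiles - 1)
    names, seqs = [], []
    for i, g in enumerate(gc(fg.sequences)):
        b = int(np.clip(np.searchsorted(edges, g, side="right") - 1, 0, n_quantiles - 1))
        candidates = np.flatnonzero(pool_bin == b)
        if len(candidates) == 0:
            candidates = np.arange(len(pool))
        j = int(rng.choice(candidates))
        names.append(f"bg_{i}_{pool.names[j]}")
        seqs.append(pool.sequences[j])
    return RegionSet(names, seqs, width=fg.width)


def enrichment_report(fg: RegionSet, bg: RegionSet, kmers: list) -> pd.DataFrame:
    rows = []
    for kmer in kmers:
        res = test_kmer_enrichment(fg, bg, kmer)
        (a, b), (c, d) = res["table"]
        rows.append({"kmer": res["kmer"], "fg_with": a, "fg_total": a + b,
                     "bg_with": c, "bg_total": c + d, "p": res["p"]})
    return pd.DataFrame(rows)
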