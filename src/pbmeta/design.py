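"""Universal array designs from de Bruijn sequences.

A universal PBM design tiles a cyclic de Bruijn sequence of a given order
across probes so that every order-mer occurs in exactly one probe variable
region.  With order o and probe step s = variable_length - o + 1, each
(o-2)-mer occurs 4**2 = 16 times per orientation in the cyclic sequence,
i.e. 32 combined-strand occurrences for non-palindromic RC-collapsed
features and 16 for palindromic ones (for o=10 these features are 8-mers).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._util import (
    BASES,
    all_canonical_kmers,
    canonical_codes,
    decode_kmer,
    encode_seq,
    rc_code_table,
    rolling_codes,
)

DEFAULT_ORDER = 10
DEFAULT_VARIABLE_LENGTH = 41


def de_bruijn_sequence(order: int, seed: int = 0) -> str:
    """Cyclic de Bruijn sequence of the given order over ACGT.

    seed=0 yields the lexicographically least sequence (concatenation of
    Lyndon words in order, Duval/FKM construction); other seeds apply a
    seeded alphabet relabeling and rotation, preserving the de Bruijn
    property.  No RNG enters the construction itself.
    """
    if not 1 <= order <= 12:
        raise ValueError("order out of supported range [1, 12]")
    n = order
    a = [0] * (4 * n)
    seq: list[int] = []

    # iterative FKM: avoids deep recursion for order 10 (4^10-length output)
    def db(t0: int, p0: int) -> None:
        stack = [(t0, p0, 0, False)]
        while stack:
            t, p, j, expanded = stack.pop()
            if not expanded:
                if t > n:
                    if n % p == 0:
                        seq.extend(a[1: p + 1])
                    continue
                a[t] = a[t - p]
                # after the recursive call on (t+1, p), loop j from a[t-p]+1
                stack.append((t, p, a[t - p] + 1, True))
                stack.append((t + 1, p, 0, False))
            else:
                if j < 4:
                    a[t] = j
                    stack.append((t, p, j + 1, True))
                    stack.append((t + 1, t, 0, False))

    db(1, 1)
    digits = np.array(seq, dtype=np.int8)
    if seed:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(4).astype(np.int8)
        digits = perm[digits]
        digits = np.roll(digits, int(rng.integers(0, len(digits))))
    return "".join(BASES[d] for d in digits)


@dataclass
class ArrayDesign:
    """Probe layout plus an index from RC-collapsed k-mers to occurrences.

    k = order - 2.  ``kmer_codes`` holds the sorted canonical codes of all
    RC-collapsed k-mers; the occurrence table (``occ_*`` arrays, one row
    per (probe, canonical k-mer) pair) records for each probe the
    occurrence nearest the free end (offset 0 = free end of the probe).
    """

    order: int
    variable_length: int
    seed: int
    probes: "object"  # pandas DataFrame: probe_id, row, col, sequence
    kmer_codes: np.ndarray
    occ_kmer_ix: np.ndarray
    occ_probe_ix: np.ndarray
    occ_offset: np.ndarray
    occ_strand: np.ndarray
    wrapped: bool = False
    _kmer_strings: list | None = field(default=None, repr=False)

    @property
    def k(self) -> int:
        return self.order - 2

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def n_kmers(self) -> int:
        return len(self.kmer_codes)

    def kmer_strings(self) -> list:
        if self._kmer_strings is None:
            self._kmer_strings = [decode_kmer(int(c), self.k) for c in self.kmer_codes]
        return self._kmer_strings

    def probe_sequences(self) -> list:
        return list(self.probes["sequence"])


def _grid_shape(n: int) -> tuple[int, int]:
    rows = int(math.floor(math.sqrt(n)))
    cols = int(math.ceil(n / rows))
    return rows, cols


def make_debruijn_design(
    order: int = DEFAULT_ORDER,
    variable_length: int = DEFAULT_VARIABLE_LENGTH,
    seed: int = 0,
) -> ArrayDesign:
    """Cut a cyclic de Bruijn sequence into overlapping probes and index k-mers.

    Probes overlap by order-1 nt so each order-mer occurs in exactly one
    probe.  If the step (variable_length - order + 1) does not divide
    4**order the last probe wraps cyclically and a warning is recorded.
    """
    import pandas as pd

    if not 4 <= order <= 10:
        raise ValueError("order must be in [4, 10]")
    if variable_length < order:
        raise ValueError("variable_length must be >= order")
    seq = de_bruijn_sequence(order, seed)
    n_total = len(seq)  # 4 ** order
    step = variable_length - order + 1
    wrapped = n_total % step != 0
    if wrapped:
        warnings.warn(
            f"step {step} does not divide 4^{order}; last probe wraps cyclically",
            stacklevel=2,
        )
    n_probes = math.ceil(n_total / step)
    ext = seq + seq[: variable_length]  # cyclic access
    sequences = [ext[i * step: i * step + variable_length] for i in range(n_probes)]
    rows, cols = _grid_shape(n_probes)
    probe_ids = [f"P{i:06d}" for i in range(n_probes)]
    probes = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "row": [i // cols + 1 for i in range(n_probes)],
            "col": [i % cols + 1 for i in range(n_probes)],
            "sequence": sequences,
        }
    )

    k = order - 2
    rc = rc_code_table(k)
    # per-probe rolling k-mer codes
    mat = np.vstack([encode_seq(s) for s in sequences]).astype(np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    n_pos = variable_length - k + 1
    win = np.lib.stride_tricks.sliding_window_view(mat, k, axis=1)  # (P, n_pos, k)
    codes = win @ powers  # (P, n_pos), forward-strand codes
    canon = np.minimum(codes, rc[codes])
    strand = (codes != canon).astype(np.int8)  # 1 = canonical form on bottom strand

    probe_ix = np.repeat(np.arange(n_probes), n_pos)
    offsets = np.tile(np.arange(n_pos), n_probes)
    canon_f = canon.ravel()
    strand_f = strand.ravel()

    # dedup: one contribution per (probe, canonical k-mer), nearest free end
    order_ix = np.lexsort((offsets, canon_f, probe_ix))
    pi, cf, off, st = probe_ix[order_ix], canon_f[order_ix], offsets[order_ix], strand_f[order_ix]
    keep = np.ones(len(pi), dtype=bool)
    keep[1:] = (pi[1:] != pi[:-1]) | (cf[1:] != cf[:-1])
    pi, cf, off, st = pi[keep], cf[keep], off[keep], st[keep]

    kmer_codes = all_canonical_kmers(k)
    kmer_ix = np.searchsorted(kmer_codes, cf)

    return ArrayDesign(
        order=order,
        variable_length=variable_length,
        seed=seed,
        probes=probes,
        kmer_codes=kmer_codes,
        occ_kmer_ix=kmer_ix.astype(np.int32),
        occ_probe_ix=pi.astype(np.int32),
        occ_offset=off.astype(np.int16),
        occ_strand=st,
        wrapped=wrapped,
    )


def cyclic_coverage_counts(sequence: str, k: int) -> dict:
    """Combined-strand occurrence counts of RC-collapsed k-mers in a cyclic sequence.

    Returns ``{"codes": canonical codes, "counts": counts, "palindromic": bool mask}``.
    A palindromic k-mer is counted once per position (both strands read the
    same word); a non-palindromic feature accumulates occurrences of both
    orientations.
    """
    digits = encode_seq(sequence + sequence[: k - 1])
    codes = rolling_codes(digits, k)
    rc = rc_code_table(k)
    canon = canonical_codes(codes, k, rc)
    counts_full = np.bincount(canon, minlength=4 ** k)
    kmer_codes = all_canonical_kmers(k)
    return {
        "codes": kmer_codes,
        "counts": counts_full[kmer_codes],
        "palindromic": rc[kmer_codes] == kmer_codes,
    }
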