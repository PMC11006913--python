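"""Shared k-mer encoding helpers.

Bases are encoded A=0, C=1, G=2, T=3 so a k-mer maps to an integer in
[0, 4**k).  Reverse-complement collapsing uses the lexicographically
smaller of a k-mer and its reverse complement as the canonical
representative (double-stranded probes cannot distinguish orientation).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_BASE_TO_INT = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_seq(seq: str) -> np.ndarray:
    """DNA string -> int8 array of base codes."""
    try:
        return np.array([_BASE_TO_INT[b] for b in seq], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"non-ACGT base in sequence: {exc}") from exc


def decode_kmer(code: int, k: int) -> str:
    out = []
    for i in range(k):
        out.append(BASES[(code >> (2 * (k - 1 - i))) & 3])
    return "".join(out)


def encode_kmer(kmer: str) -> int:
    code = 0
    for b in kmer:
        code = (code << 2) | _BASE_TO_INT[b]
    return code


def rc_code_table(k: int) -> np.ndarray:
    """Vector mapping each k-mer code to its reverse-complement code."""
    codes = np.arange(4 ** k, dtype=np.int64)
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        rc = (rc << 2) | (3 - (tmp & 3))
        tmp >>= 2
    return rc


def canonical_codes(codes: np.ndarray, k: int, rc_table: np.ndarray | None = None) -> np.ndarray:
    """Map k-mer codes to RC-collapsed canonical codes (elementwise min)."""
    if rc_table is None:
        rc_table = rc_code_table(k)
    return np.minimum(codes, rc_table[codes])


def all_canonical_kmers(k: int) -> np.ndarray:
    """Sorted array of all RC-collapsed canonical k-mer codes.

    There are (4**k - 4**ceil(k/2)) / 2 + 4**ceil(k/2) of them for even k
    (32,896 for k=8).
    """
    rc = rc_code_table(k)
    codes = np.arange(4 ** k, dtype=np.int64)
    return codes[codes <= rc]


def rolling_codes(digits: np.ndarray, k: int) -> np.ndarray:
    """Codes of every length-k window of a base-code array."""
    if len(digits) < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(digits.astype(np.int64), k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return win @ powers


def iupac_matches(kmer: str, pattern: str) -> bool:
    """True if `pattern` (IUPAC) occurs in `kmer` on either strand."""
    for probe in (kmer, revcomp(kmer)):
        for i in range(len(probe) - len(pattern) + 1):
            if all(probe[i + j] in IUPAC[p] for j, p in enumerate(pattern)):
                return True
    return False


def validate_iupac(pattern: str) -> None:
    bad = [c for c in pattern if c not in IUPAC]
    if bad:
        raise ValueError(f"invalid IUPAC characters: {bad!r}")
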