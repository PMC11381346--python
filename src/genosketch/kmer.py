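"""Canonical k-mer multiset extraction.

Genomes are reduced to weighted sets of k-mers: the multiset of all
length-k windows, with nucleotide windows replaced by the lexicographic
minimum of the window and its reverse complement so sketches are
strand-invariant.  Windows never span sequence (contig) boundaries and
any window touching an excluded residue (ambiguity codes, X) is skipped.

Tokens are packed integers: 2 bits per base (k <= 32) or 5 bits per
amino acid (k <= 12), so every k-mer fits a uint64.  Packing is an
internal detail; equality of tokens is equality of k-mers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .genome_io import Alphabet, GenomeRecord

NT_ORDER = "ACGT"
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

_NT_CODE = np.full(128, -1, dtype=np.int8)
for _i, _c in enumerate(NT_ORDER):
    _NT_CODE[ord(_c)] = _i
_AA_CODE = np.full(128, -1, dtype=np.int8)
for _i, _c in enumerate(AA_ORDER):
    _AA_CODE[ord(_c)] = _i

MAX_K = {Alphabet.NUCLEOTIDE: 32, Alphabet.AMINOACID: 12}
_BITS = {Alphabet.NUCLEOTIDE: 2, Alphabet.AMINOACID: 5}


@dataclass
class KmerMultiset:
    """Canonical k-mer -> count map for one genome.

    ``tokens`` is sorted ascending and parallel to ``counts``; every
    count is >= 1 and ``total_count`` is their sum.
    """

    k: int
    alphabet: Alphabet
    tokens: np.ndarray   # uint64, sorted, unique
    counts: np.ndarray   # int64, parallel to tokens

    @property
    def total_count(self) -> int:
        return int(self.counts.sum())

    @property
    def n_distinct(self) -> int:
        return len(self.tokens)

    def __bool__(self) -> bool:
        return len(self.tokens) > 0

    def to_dict(self) -> dict[str, int]:
        return {token_to_kmer(int(t), self.k, self.alphabet): int(c)
                for t, c in zip(self.tokens, self.counts)}


def kmer_to_token(kmer: str, alphabet: Alphabet | str = Alphabet.NUCLEOTIDE) -> int:
    alphabet = Alphabet(alphabet)
    order = NT_ORDER if alphabet is Alphabet.NUCLEOTIDE else AA_ORDER
    bits = _BITS[alphabet]
    t = 0
    for c in kmer:
        t = (t << bits) | order.index(c)
    return t


def token_to_kmer(token: int, k: int, alphabet: Alphabet | str = Alphabet.NUCLEOTIDE) -> str:
    alphabet = Alphabet(alphabet)
    order = NT_ORDER if alphabet is Alphabet.NUCLEOTIDE else AA_ORDER
    bits = _BITS[alphabet]
    mask = (1 << bits) - 1
    out = []
    for i in range(k):
        out.append(order[(token >> (bits * (k - 1 - i))) & mask])
    return "".join(out)


def canonical_token(kmer: str) -> int:
    """Lexicographic min of a nucleotide k-mer and its reverse complement."""
    rc = kmer[::-1].translate(str.maketrans("ACGT", "TGCA"))
    return kmer_to_token(min(kmer, rc))


def _sequence_tokens(seq: str, k: int, alphabet: Alphabet) -> np.ndarray:
    table = _NT_CODE if alphabet is Alphabet.NUCLEOTIDE else _AA_CODE
    codes = table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8) & 0x7F]
    if len(codes) < k:
        return np.empty(0, dtype=np.uint64)
    win = sliding_window_view(codes, k)
    ok = (win >= 0).all(axis=1)
    if not ok.any():
        return np.empty(0, dtype=np.uint64)
    bits = _BITS[alphabet]
    powers = (np.uint64(1) << (np.uint64(bits) * np.arange(k - 1, -1, -1, dtype=np.uint64)))
    fwd = win[ok].astype(np.uint64)
    with np.errstate(over="ignore"):
        toks = (fwd * powers).sum(axis=1, dtype=np.uint64)
        if alphabet is Alphabet.NUCLEOTIDE:
            rc = (np.uint64(3) - fwd)[:, ::-1]
            rtoks = (rc * powers).sum(axis=1, dtype=np.uint64)
            toks = np.minimum(toks, rtoks)
    return toks


def extract_kmers(record: GenomeRecord, k: int) -> KmerMultiset:
    """Slide a width-k window over each sequence and count canonical k-mers.

    Raises ``ValueError`` if k exceeds the packing limit for the record's
    alphabet.  Sequences shorter than k simply contribute nothing; the
    result may be empty and callers must check truthiness.
    """
    if not 1 <= k <= MAX_K[record.alphabet]:
        raise ValueError(
            f"k={k} out of range 1..{MAX_K[record.alphabet]} for {record.alphabet.value}")
    parts = [_sequence_tokens(s, k, record.alphabet) for s in record.sequences]
    allt = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint64)
    tokens, counts = np.unique(allt, return_counts=True)
    return KmerMultiset(k=k, alphabet=record.alphabet,
                        tokens=tokens.astype(np.uint64),
                        counts=counts.astype(np.int64))


def normalize_weights(ms: KmerMultiset) -> dict[int, float]:
    """Relative k-mer frequencies w(x) = count(x)/total; they sum to 1."""
    if not ms:
        raise ValueError("cannot normalize an empty k-mer multiset")
    total = ms.total_count
    return {int(t): c / total for t, c in zip(ms.tokens, ms.counts)}


def weight_arrays(ms: KmerMultiset) -> tuple[np.ndarray, np.ndarray]:
    """(tokens, normalized weights) as aligned arrays for numeric code."""
    if not ms:
        raise ValueError("cannot normalize an empty k-mer multiset")
    return ms.tokens, ms.counts / ms.counts.sum()
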