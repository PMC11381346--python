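"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from genosketch.genome_io import Alphabet
from genosketch.kmer import KmerMultiset


def multiset_from_tokens(tokens, counts=None, k: int = 16,
                         alphabet: Alphabet = Alphabet.NUCLEOTIDE) -> KmerMultiset:
    """Build a KmerMultiset directly from integer tokens (synthetic sets)."""
    tokens = np.asarray(list(tokens), dtype=np.uint64)
    if counts is None:
        counts = np.ones(len(tokens), dtype=np.int64)
    else:
        counts = np.asarray(list(counts), dtype=np.int64)
    order = np.argsort(tokens)
    return KmerMultiset(k=k, alphabet=alphabet,
                        tokens=tokens[order], counts=counts[order])


def overlapping_sets(size: int, shared: int, counts_mod: int = 0
                     ) -> tuple[KmerMultiset, KmerMultiset]:
    """Two equal-size token sets with a given overlap; J = shared/(2*size−shared).

    With counts_mod > 0, counts are a token-determined pattern shared by
    both sets (a genuinely weighted pair whose J_p stays close to J).
    """
    a = np.arange(size, dtype=np.uint64)
    b = np.arange(size - shared, 2 * size - shared, dtype=np.uint64)
    if counts_mod > 0:
        ca = 1 + (a % counts_mod)
        cb = 1 + (b % counts_mod)
        return (multiset_from_tokens(a, ca), multiset_from_tokens(b, cb))
    return multiset_from_tokens(a), multiset_from_tokens(b)


@pytest.fixture(scope="session")
def small_mutant_db():
    """20 groups x 10 mutants of related ancestors (session-shared)."""
    from genosketch.synthetic import mutant_database
    records, truth = mutant_database(
        n_groups=20, group_size=10, genome_length=5000,
        rates=(0.0, 0.01, 0.02, 0.03, 0.05), seed=7)
    return records, truth
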