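"""Exact similarity oracles and distance <-> identity transforms.

``j_exact`` and ``jp_exact`` are the brute-force ground truths that the
sketch estimators are validated against.  The Mash equation

    ANI = 1 + (1/k) * ln( 2J / (1+J) )

maps k-mer Jaccard similarity to an average nucleotide (or amino-acid)
identity proxy; its inverse maps identity thresholds back to the sketch
distance scale used by the search pipeline.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad

from .kmer import KmerMultiset


def j_exact(ma: KmerMultiset, mb: KmerMultiset) -> float:
    """Plain Jaccard |A∩B|/|A∪B| over the k-mer supports."""
    _check_pair(ma, mb)
    inter = np.intersect1d(ma.tokens, mb.tokens, assume_unique=True).size
    union = ma.n_distinct + mb.n_distinct - inter
    return inter / union


def jp_exact(ma: KmerMultiset, mb: KmerMultiset) -> float:
    """Probability (normalized weighted) Jaccard index J_p.

    J_p = sum over shared x of 1 / sum_y max(wA(y)/wA(x), wB(y)/wB(x))
    with w the count-normalized weights.  This is the quantity whose
    per-register collision probability weighted MinHash realizes; it
    accounts for k-mer multiplicity and genome size.
    """
    _check_pair(ma, mb)
    union = np.union1d(ma.tokens, mb.tokens)
    wa = np.zeros(union.size)
    wb = np.zeros(union.size)
    wa[np.searchsorted(union, ma.tokens)] = ma.counts / ma.counts.sum()
    wb[np.searchsorted(union, mb.tokens)] = mb.counts / mb.counts.sum()
    shared = (wa > 0) & (wb > 0)
    if not shared.any():
        return 0.0
    # denom for shared x: sum_y max(wA(y)/wA(x), wB(y)/wB(x)); chunk over x
    total = 0.0
    idx = np.flatnonzero(shared)
    for lo in range(0, idx.size, 512):
        sel = idx[lo:lo + 512]
        ra = wa[None, :] / wa[sel, None]
        rb = wb[None, :] / wb[sel, None]
        denom = np.maximum(ra, rb).sum(axis=1)
        total += float((1.0 / denom).sum())
    return total


def _check_pair(ma: KmerMultiset, mb: KmerMultiset) -> None:
    if not ma or not mb:
        raise ValueError("similarity of an empty k-mer multiset is undefined")
    if ma.k != mb.k or ma.alphabet != mb.alphabet:
        raise ValueError("multisets with different k or alphabet are not comparable")


def mash_transform(j: float, k: int) -> float:
    """ANI/AAI proxy from Jaccard-like similarity: 1 + ln(2j/(1+j))/k."""
    if not 0.0 < j <= 1.0:
        raise ValueError("no detectable similarity: j must lie in (0, 1]")
    if k < 1:
        raise ValueError("k must be >= 1")
    return 1.0 + math.log(2.0 * j / (1.0 + j)) / k


def mash_inverse(ani: float, k: int) -> float:
    """Jaccard-like similarity solving the Mash equation at the given identity."""
    if ani > 1.0:
        raise ValueError("identity cannot exceed 1")
    c = math.exp(k * (ani - 1.0))
    return c / (2.0 - c)


def setsketch_entropy_per_register(b: float) -> float:
    """Shannon entropy (bits) of one geometric-base-b sketch register.

    Evaluates (1/(ln2·ln b)) * ((1 − 1/b) + I) with
    I = ∫₀¹ z^{1/(b−1)} (1−z) ln(1−z) / (z ln z) dz by adaptive
    quadrature; the integrand extends continuously to 0 at z=0 and has an
    integrable log singularity at z=1.
    """
    if b <= 1.0:
        raise ValueError("b must exceed 1")

    def integrand(z: float) -> float:
        if z <= 0.0 or z >= 1.0:
            return 0.0
        return z ** (1.0 / (b - 1.0)) * (1.0 - z) * math.log1p(-z) / (z * math.log(z))

    val, _ = quad(integrand, 0.0, 1.0, epsabs=1e-6, limit=400,
                  points=[1.0 - 1e-9])
    return (1.0 / (math.log(2.0) * math.log(b))) * ((1.0 - 1.0 / b) + val)


def setsketch_space_reduction(b: float, register_bits: int = 16) -> float:
    """Fractional space headroom of entropy coding vs fixed-width registers (%)."""
    h = setsketch_entropy_per_register(b)
    return (1.0 - h / register_bits) * 100.0
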