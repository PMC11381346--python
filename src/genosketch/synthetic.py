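"""Synthetic genomes, proteomes and sketches with known ground truth.

The generators emulate the experimental conditions the search method is
meant for, in a fully controlled way:

* random genomes of configurable length and GC content;
* mutated copies at a per-site substitution rate r (substitutions only,
  so the expected ANI is analytically 1 − r and the expected k-mer
  Jaccard follows the Mash equation);
* incomplete copies where random contiguous blocks are removed until a
  target completeness fraction remains (a MAG-quality proxy);
* proteome-like amino-acid records where related pairs share a copied
  fraction of sequence, controlling amino-acid-level Jaccard directly;
* planted-structure sketch vectors for index benchmarks, where a group
  member copies its group center's registers and rewrites a fraction p
  of them, so the expected register-match distance is p within a group.

Also provides the exhaustive brute-force K-NN oracle and the average
recall scoring used to validate the approximate index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._hashing import mix64
from .genome_io import Alphabet, GenomeRecord
from .kmer import AA_ORDER, NT_ORDER, KmerMultiset, extract_kmers
from .sketching import (SketchParams, SketchVector, estimate_distance)
from .similarity import j_exact, jp_exact
from .hnsw import NeighborHit


@dataclass
class MutationSpec:
    """Controls for the mutant generator; expected ANI ≈ 1 − substitution_rate."""

    substitution_rate: float = 0.0
    seed: int = 0
    completeness: float = 1.0
    n_replicates: int = 1

    def __post_init__(self):
        if not 0.0 <= self.substitution_rate < 1.0:
            raise ValueError("substitution_rate must lie in [0, 1)")
        if not 0.0 < self.completeness <= 1.0:
            raise ValueError("completeness must lie in (0, 1]")


@dataclass
class RecallResult:
    K: int
    per_query_recall: list[float]
    average_recall: float
    n_filtered_hits: int


def generate_genome(length: int, gc: float, seed: int,
                    genome_id: str = "synthetic") -> GenomeRecord:
    """I.i.d. random nucleotide sequence with P(G) + P(C) = gc."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    seq = "".join(np.array(list(NT_ORDER))[rng.choice(4, size=length, p=p)])
    return GenomeRecord(genome_id=genome_id, sequences=[seq],
                        alphabet=Alphabet.NUCLEOTIDE)


def mutate_genome(g: GenomeRecord, spec: MutationSpec,
                  mutant_id: str | None = None) -> GenomeRecord:
    """Independent per-site substitutions plus contiguous-block removal.

    Each site mutates with probability ``substitution_rate`` to a
    uniformly chosen *different* base; with completeness < 1, random
    contiguous blocks totaling (1 − completeness) of each sequence are
    removed and the remaining stretches become separate sequences.
    """
    if g.alphabet is not Alphabet.NUCLEOTIDE:
        raise ValueError("mutation model is defined for nucleotide records")
    rng = np.random.default_rng(spec.seed)
    base_idx = {c: i for i, c in enumerate(NT_ORDER)}
    out_seqs: list[str] = []
    for seq in g.sequences:
        codes = np.array([base_idx.get(c, -1) for c in seq], dtype=np.int64)
        hit = rng.random(len(codes)) < spec.substitution_rate
        hit &= codes >= 0
        # shift by 1..3 mod 4 picks a uniformly random different base
        shifts = rng.integers(1, 4, size=len(codes))
        codes[hit] = (codes[hit] + shifts[hit]) % 4
        arr = np.array(list(seq))
        arr[codes >= 0] = np.array(list(NT_ORDER))[codes[codes >= 0]]
        mutated = "".join(arr)
        if spec.completeness < 1.0:
            out_seqs.extend(_drop_blocks(mutated, spec.completeness, rng))
        else:
            out_seqs.append(mutated)
    out_seqs = [s for s in out_seqs if s]
    mid = mutant_id or f"{g.genome_id}_mut{spec.seed}"
    return GenomeRecord(genome_id=mid, sequences=out_seqs, alphabet=g.alphabet)


def _drop_blocks(seq: str, completeness: float, rng: np.random.Generator,
                 n_blocks: int = 5) -> list[str]:
    remove_total = int(round(len(seq) * (1.0 - completeness)))
    if remove_total <= 0:
        return [seq]
    # random block lengths summing to the removal total, at random
    # non-overlapping positions (sampled by rejection, sorted)
    splits = np.sort(rng.choice(remove_total + 1, size=n_blocks - 1, replace=True))
    lens = np.diff(np.concatenate(([0], splits, [remove_total])))
    lens = lens[lens > 0]
    keep_total = len(seq) - remove_total
    # gap offsets expressed in retained-sequence coordinates; walking them
    # interleaves kept stretches with removed blocks
    starts = np.sort(rng.choice(keep_total + 1, size=len(lens), replace=True))
    pieces: list[str] = []
    src = 0
    kept_before = 0
    for start, ln in zip(starts, lens):
        take = int(start) - kept_before
        pieces.append(seq[src:src + take])
        src += take + int(ln)
        kept_before = int(start)
    pieces.append(seq[src:])
    return [p for p in pieces if p]


def generate_proteome(n_seqs: int, seq_length: int, seed: int,
                      genome_id: str = "synthetic_prot") -> GenomeRecord:
    """I.i.d. amino-acid sequences (uniform over the 20 canonical letters)."""
    rng = np.random.default_rng(seed)
    letters = np.array(list(AA_ORDER))
    seqs = ["".join(letters[rng.integers(0, 20, size=seq_length)])
            for _ in range(n_seqs)]
    return GenomeRecord(genome_id=genome_id, sequences=seqs,
                        alphabet=Alphabet.AMINOACID)


def related_proteome(parent: GenomeRecord, shared_fraction: float, seed: int,
                     genome_id: str | None = None) -> GenomeRecord:
    """Copy a fraction of each parent sequence, draw the rest fresh."""
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    letters = np.array(list(AA_ORDER))
    seqs = []
    for seq in parent.sequences:
        cut = int(round(len(seq) * shared_fraction))
        fresh = "".join(letters[rng.integers(0, 20, size=len(seq) - cut)])
        seqs.append(seq[:cut] + fresh)
    gid = genome_id or f"{parent.genome_id}_rel"
    return GenomeRecord(genome_id=gid, sequences=seqs, alphabet=Alphabet.AMINOACID)


# ---------------------------------------------------------------------------
# planted-structure sketch vectors for index benchmarks


def planted_sketches(n_groups: int, group_size: int, params: SketchParams,
                     seed: int, cluster_spread: float = 0.35,
                     latent_dim: int = 8, bin_width: float = 2.0
                     ) -> list[SketchVector]:
    """Synthetic register vectors with graded, navigable similarity.

    Each genome is a latent point (cluster center + Gaussian spread) and
    register i is the randomly shifted quantization bin of a random
    projection of that point.  The register-match probability then
    decays smoothly with latent Euclidean distance — emulating the
    graded relatedness continuum of a real genome database (close
    relatives share most registers, distant ones progressively fewer)
    rather than an unnavigable all-ties landscape.
    """
    rng = np.random.default_rng(seed)
    m, d = params.m, latent_dim
    proj = rng.standard_normal((d, m))
    shift = rng.random(m) * bin_width
    out: list[SketchVector] = []
    for gidx in range(n_groups):
        center = rng.standard_normal(d)
        for midx in range(group_size):
            x = center + cluster_spread * rng.standard_normal(d)
            bins = np.floor((x @ proj + shift) / bin_width).astype(np.int64)
            # fold (register index, bin) into distinct uint64 tokens
            regs = mix64(bins.view(np.uint64) ^ mix64(np.arange(m, dtype=np.uint64)))
            out.append(SketchVector(params=params, registers=regs,
                                    genome_id=f"g{gidx:03d}_m{midx:02d}"))
    return out


# ---------------------------------------------------------------------------
# oracles and scoring


def brute_force_knn(db_sketches: list[SketchVector], query: SketchVector,
                    K: int) -> list[NeighborHit]:
    """Exhaustive top-K by estimated distance, tie-broken by genome id."""
    if not db_sketches:
        raise ValueError("brute-force search over an empty database")
    scored = sorted((estimate_distance(query, s), s.genome_id)
                    for s in db_sketches)
    return [NeighborHit(genome_id=gid, distance=d, rank=r + 1)
            for r, (d, gid) in enumerate(scored[:K])]


def brute_force_knn_exact(db: list[KmerMultiset], db_ids: list[str],
                          query: KmerMultiset, K: int,
                          weighted: bool = True) -> list[NeighborHit]:
    """Exact-distance oracle over k-mer multisets (1 − J_p or 1 − J)."""
    sim = jp_exact if weighted else j_exact
    scored = sorted((1.0 - sim(query, m), gid) for m, gid in zip(db, db_ids))
    return [NeighborHit(genome_id=gid, distance=d, rank=r + 1)
            for r, (d, gid) in enumerate(scored[:K])]


def score_recall(approx: list[list[NeighborHit]], exact: list[list[NeighborHit]],
                 K: int, distance_cutoff: float = 1.0) -> RecallResult:
    """Average |R' ∩ R| / |R| over queries, after cutoff filtering.

    Hits with distance beyond the cutoff are unreliable at that search
    level and are removed; both lists are then truncated symmetrically to
    the shorter surviving length before comparison.
    """
    if len(approx) != len(exact):
        raise ValueError("approximate and exact hit lists differ in length")
    per_query: list[float] = []
    filtered = 0
    for hits_a, hits_e in zip(approx, exact):
        ka = [h for h in hits_a[:K] if h.distance <= distance_cutoff]
        ke = [h for h in hits_e[:K] if h.distance <= distance_cutoff]
        filtered += (len(hits_a[:K]) - len(ka)) + (len(hits_e[:K]) - len(ke))
        depth = min(len(ka), len(ke))
        if depth == 0:
            per_query.append(1.0 if not ke else 0.0)
            continue
        sa = {h.genome_id for h in ka[:depth]}
        se = {h.genome_id for h in ke[:depth]}
        per_query.append(len(sa & se) / depth)
    return RecallResult(K=K, per_query_recall=per_query,
                        average_recall=float(np.mean(per_query)),
                        n_filtered_hits=filtered)


def mutant_database(n_groups: int, group_size: int, genome_length: int,
                    rates: tuple[float, ...], seed: int, gc: float = 0.5,
                    ancestor_rate: float = 0.08
                    ) -> tuple[list[GenomeRecord], list[tuple[str, str, float]]]:
    """Groups of mutants of related ancestors, plus a (parent, mutant, rate) truth table.

    All group ancestors descend from one root genome at ``ancestor_rate``
    substitutions per site, so between-group k-mer similarity is small
    but graded (as between families of real genomes) while within-group
    similarity is much larger — brute-force nearest neighbors of any
    mutant are its group mates, and the relatedness continuum keeps the
    proximity graph navigable.
    """
    root = generate_genome(genome_length, gc, seed * 99991 + 7,
                           genome_id="root")
    records: list[GenomeRecord] = []
    truth: list[tuple[str, str, float]] = []
    for gidx in range(n_groups):
        parent = mutate_genome(root, MutationSpec(
            substitution_rate=ancestor_rate, seed=seed * 100003 + gidx),
            mutant_id=f"grp{gidx:03d}_anc")
        for midx in range(group_size):
            rate = rates[midx % len(rates)]
            spec = MutationSpec(substitution_rate=rate,
                                seed=seed * 1000003 + gidx * 1009 + midx)
            mut = mutate_genome(parent, spec,
                                mutant_id=f"grp{gidx:03d}_m{midx:02d}")
            records.append(mut)
            truth.append((parent.genome_id, mut.genome_id, rate))
    return records, truth


def completeness_sweep(db_records: list[GenomeRecord], params: SketchParams,
                       completeness_grid: list[float], K: int, seed: int,
                       n_queries: int = 20,
                       distance_cutoff: float = 1.0) -> list[tuple[float, float]]:
    """Average top-K recall of fragmented mutant queries vs full-genome truth.

    For each completeness level, a subset of database genomes is
    re-fragmented (no extra mutations) and searched by brute force
    against the database sketches; recall is scored against the
    brute-force ranking of the *unfragmented* query.
    """
    if not completeness_grid:
        raise ValueError("completeness grid is empty")
    db_ms = [extract_kmers(r, params.k) for r in db_records]
    db_sk = [_sketch(ms_, params) for ms_ in db_ms]
    for rec, sk in zip(db_records, db_sk):
        sk.genome_id = rec.genome_id
    rng = np.random.default_rng(seed)
    q_idx = rng.choice(len(db_records), size=min(n_queries, len(db_records)),
                       replace=False)
    table: list[tuple[float, float]] = []
    for comp in completeness_grid:
        approx, exact = [], []
        for qi in q_idx:
            rec = db_records[qi]
            full_ms = db_ms[qi]
            exact.append(brute_force_knn(db_sk, _sketch(full_ms, params), K))
            if comp >= 1.0:
                frag = rec
            else:
                frag = mutate_genome(rec, MutationSpec(
                    substitution_rate=0.0, completeness=comp,
                    seed=int(rng.integers(2 ** 31))))
            frag_ms = extract_kmers(frag, params.k)
            approx.append(brute_force_knn(db_sk, _sketch(frag_ms, params), K))
        res = score_recall(approx, exact, K, distance_cutoff)
        table.append((comp, res.average_recall))
    return table


def _sketch(ms: KmerMultiset, params: SketchParams) -> SketchVector:
    from .sketching import sketch as _s
    return _s(ms, params)
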