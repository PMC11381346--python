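"""Synthetic generators, oracles and recall scoring."""

import math
import warnings

import numpy as np
import pytest

from genosketch.hnsw import NeighborHit
from genosketch.kmer import extract_kmers
from genosketch.similarity import j_exact, mash_inverse
from genosketch.sketching import SketchParams, sketch
from genosketch.synthetic import (MutationSpec, brute_force_knn,
                                  brute_force_knn_exact, completeness_sweep,
                                  generate_genome, generate_proteome,
                                  mutate_genome, planted_sketches,
                                  related_proteome, score_recall)


class TestGenerateGenome:
    def test_deterministic_per_seed(self):
        a = generate_genome(1000, 0.5, seed=1)
        b = generate_genome(1000, 0.5, seed=1)
        assert a.sequences == b.sequences
        assert a.sequences != generate_genome(1000, 0.5, seed=2).sequences

    def test_gc_content_within_binomial_band(self):
        n = 100_000
        g = generate_genome(n, 0.6, seed=3)
        gc = sum(g.sequences[0].count(c) for c in "GC") / n
        assert abs(gc - 0.6) < 3 * math.sqrt(0.6 * 0.4 / n)

    @pytest.mark.parametrize("gc", [0.0, 1.0])
    def test_degenerate_gc_rejected(self, gc):
        with pytest.raises(ValueError):
            generate_genome(100, gc, seed=0)


class TestMutateGenome:
    def test_rate_zero_full_completeness_is_identity(self):
        g = generate_genome(2000, 0.5, seed=4)
        m = mutate_genome(g, MutationSpec(substitution_rate=0.0))
        assert m.sequences == g.sequences

    def test_hamming_distance_matches_rate(self):
        n, rate = 100_000, 0.05
        g = generate_genome(n, 0.5, seed=5)
        m = mutate_genome(g, MutationSpec(substitution_rate=rate, seed=6))
        ham = sum(a != b for a, b in zip(g.sequences[0], m.sequences[0]))
        assert abs(ham - rate * n) < 3 * math.sqrt(rate * (1 - rate) * n)

    def test_completeness_removes_expected_fraction_in_blocks(self):
        g = generate_genome(50_000, 0.5, seed=7)
        m = mutate_genome(g, MutationSpec(substitution_rate=0.0,
                                          completeness=0.6, seed=8))
        assert len(m.sequences) > 1
        assert m.total_length == pytest.approx(30_000, rel=0.01)

    def test_observed_jaccard_matches_mash_prediction(self):
        # per-site rate r -> expected J = c/(2-c) with c = exp(-k*r)
        rate, k = 0.03, 16
        g = generate_genome(20_000, 0.5, seed=9)
        obs = []
        for s in range(20):
            m = mutate_genome(g, MutationSpec(substitution_rate=rate, seed=s))
            obs.append(j_exact(extract_kmers(g, k), extract_kmers(m, k)))
        predicted = mash_inverse(1.0 - rate, k)
        sd = np.std(obs, ddof=1)
        assert abs(np.mean(obs) - predicted) < 3 * sd


class TestProteomes:
    def test_related_proteome_controls_shared_fraction(self):
        p = generate_proteome(10, 300, seed=10)
        near = related_proteome(p, 0.9, seed=11)
        far = related_proteome(p, 0.2, seed=12)
        k = 7
        j_near = j_exact(extract_kmers(p, k), extract_kmers(near, k))
        j_far = j_exact(extract_kmers(p, k), extract_kmers(far, k))
        assert j_near > 0.6
        assert j_far < 0.2

    def test_shared_fraction_bounds(self):
        p = generate_proteome(2, 100, seed=13)
        with pytest.raises(ValueError):
            related_proteome(p, 1.5, seed=0)


@pytest.fixture(scope="module")
def cloud():
    params = SketchParams(algo="probminhash3a", m=96, k=16, seed=1)
    return planted_sketches(10, 10, params, seed=20)


class TestBruteForce:
    def test_full_ranking_is_permutation(self, cloud):
        hits = brute_force_knn(cloud, cloud[0], K=len(cloud))
        assert sorted(h.genome_id for h in hits) == \
            sorted(s.genome_id for s in cloud)
        assert [h.rank for h in hits] == list(range(1, len(cloud) + 1))

    def test_query_in_database_ranks_first(self, cloud):
        hits = brute_force_knn(cloud, cloud[42], K=3)
        assert hits[0].genome_id == cloud[42].genome_id
        assert hits[0].distance == 0.0

    def test_exact_mode_agrees_with_sketch_mode_on_top1(self):
        from genosketch.synthetic import mutant_database
        records, _ = mutant_database(5, 5, 3000, (0.01, 0.03), seed=21)
        params = SketchParams(algo="probminhash3a", m=2048, k=16, seed=1)
        mss = [extract_kmers(r, 16) for r in records]
        sks = [sketch(ms, params, genome_id=r.genome_id)
               for ms, r in zip(mss, records)]
        ids = [r.genome_id for r in records]
        agree = 0
        for i in range(0, len(records), 5):
            top_sketch = brute_force_knn(sks[:i] + sks[i + 1:], sks[i], 1)
            top_exact = brute_force_knn_exact(mss[:i] + mss[i + 1:],
                                              ids[:i] + ids[i + 1:], mss[i], 1)
            agree += top_sketch[0].genome_id == top_exact[0].genome_id
        assert agree >= 4


class TestScoreRecall:
    def _hits(self, ids, d=0.1):
        return [NeighborHit(genome_id=g, distance=d, rank=i + 1)
                for i, g in enumerate(ids)]

    def test_identical_lists_score_one(self):
        r = self._hits(list("abcdefghij"))
        res = score_recall([r], [r], K=10)
        assert res.average_recall == 1.0

    def test_disjoint_lists_score_zero(self):
        a = self._hits(list("abcde"))
        b = self._hits(list("vwxyz"))
        assert score_recall([a], [b], K=5).average_recall == 0.0

    def test_partial_overlap_arithmetic(self):
        approx = self._hits(list("abcdefgh") + ["x", "y"])
        exact = self._hits(list("abcdefgh") + ["w", "z"])
        assert score_recall([approx], [exact], K=10).average_recall == 0.8

    def test_cutoff_filters_symmetrically(self):
        # two of ten hits beyond the cutoff on each side: top-8 vs top-8
        approx = self._hits(list("abcdefgh")) + self._hits(["x", "y"], d=0.99)
        exact = self._hits(list("abcdefgh")) + self._hits(["w", "z"], d=0.99)
        res = score_recall([approx], [exact], K=10, distance_cutoff=0.9)
        assert res.average_recall == 1.0
        assert res.n_filtered_hits == 4

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score_recall([], [self._hits(list("ab"))], K=2)


def test_completeness_sweep_monotone_and_anchored():
    from genosketch.synthetic import mutant_database
    records, _ = mutant_database(10, 5, 4000, (0.0, 0.02, 0.04), seed=22)
    params = SketchParams(algo="probminhash3a", m=512, k=16, seed=1)
    table = completeness_sweep(records, params, [1.0, 0.9, 0.7, 0.5, 0.3],
                               K=5, seed=23, n_queries=10)
    comps, recalls = zip(*table)
    assert recalls[0] == 1.0  # unfragmented query reproduces its own ranking
    # recall should not increase as completeness drops (1 SE slack)
    for a, b in zip(recalls, recalls[1:]):
        assert b <= a + 0.15
    if recalls[comps.index(0.5)] < 0.8:
        warnings.warn("top-K recall at 50% completeness fell below 0.8 "
                      f"({recalls[comps.index(0.5)]:.2f}) on this synthetic run")
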