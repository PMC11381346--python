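"""HNSW graph construction, querying and persistence."""

import math

import numpy as np
import pytest

from genosketch.hnsw import (HnswGraph, HnswParams, assign_level, _level_draw)
from genosketch.sketching import (IncomparableSketches, SketchParams,
                                  SketchVector, sketch)
from genosketch.synthetic import brute_force_knn, planted_sketches, score_recall

from conftest import multiset_from_tokens

P96 = SketchParams(algo="probminhash3a", m=96, k=16, seed=1)


def _build(sketches, M=16, ef=100, seed=3):
    g = HnswGraph(sketches[0].params, HnswParams(M=M, ef_construct=ef, seed=seed))
    for s in sketches:
        g.insert(s)
    return g


class TestLevelAssignment:
    def test_draw_near_one_gives_level_zero(self):
        assert assign_level(HnswParams(M=20), 1.0 - 1e-12) == 0

    def test_zero_multiplier_flattens_graph(self):
        p = HnswParams(M=20, mL=0.0)
        assert all(assign_level(p, u) == 0 for u in (0.001, 0.5, 0.999))

    def test_tail_probability_matches_exponential_decay(self):
        # with mL = 1/ln(M), P(level >= 1) = e^{-1/mL} = 1/M
        p = HnswParams(M=20)
        n = 100_000
        frac = np.mean([assign_level(p, _level_draw(0, i)) >= 1
                        for i in range(n)])
        se = math.sqrt(0.05 * 0.95 / n)
        assert abs(frac - 1 / 20) < 3 * se

    def test_invalid_draw_rejected(self):
        with pytest.raises(ValueError):
            assign_level(HnswParams(M=16), 0.0)


class TestInsert:
    def test_first_insert_becomes_entry_point(self):
        sk = planted_sketches(1, 1, P96, seed=0)[0]
        g = _build([sk])
        assert g.entry_point == 0
        assert all(not nbrs for nbrs in g.adjacency[0])

    def test_duplicate_id_rejected(self):
        sk = planted_sketches(1, 1, P96, seed=0)[0]
        g = _build([sk])
        with pytest.raises(ValueError, match="duplicate"):
            g.insert(sk)

    def test_incompatible_sketch_rejected(self):
        sk = planted_sketches(1, 1, P96, seed=0)[0]
        g = _build([sk])
        other = SketchVector(
            params=SketchParams(algo="probminhash3a", m=96, k=21, seed=1),
            registers=sk.registers, genome_id="x")
        with pytest.raises(IncomparableSketches):
            g.insert(other)

    def test_identical_sketch_linked_at_distance_zero(self):
        sks = planted_sketches(5, 4, P96, seed=0)
        g = _build(sks)
        twin = SketchVector(params=P96, registers=sks[7].registers.copy(),
                            genome_id="twin")
        idx = g.insert(twin)
        assert 7 in g.adjacency[idx][0]

    def test_neighbor_caps_respected(self):
        sks = planted_sketches(20, 10, P96, seed=2)
        g = _build(sks, M=8)
        for i, per_level in enumerate(g.adjacency):
            for level, nbrs in enumerate(per_level):
                cap = 16 if level == 0 else 8
                assert len(nbrs) <= cap

    def test_layer0_neighborhoods_close_to_true_neighbors(self):
        sks = planted_sketches(30, 10, P96, seed=2)
        g = _build(sks, M=16, ef=200)
        regs = np.stack([s.registers for s in sks])
        good = 0
        for i in range(len(sks)):
            d = 1.0 - (regs == regs[i]).mean(axis=1)
            d[i] = np.inf
            true_2m = set(np.argsort(d, kind="stable")[:32])
            if set(g.adjacency[i][0]) & true_2m:
                good += 1
        assert good / len(sks) >= 0.95


class TestQuery:
    def test_single_node_graph(self):
        sk = planted_sketches(1, 1, P96, seed=0)[0]
        g = _build([sk])
        hits = g.knn_query(sk, 1)
        assert hits[0].genome_id == sk.genome_id
        assert hits[0].distance == 0.0
        assert hits[0].rank == 1

    def test_database_sketch_found_at_rank_one(self):
        sks = planted_sketches(20, 10, P96, seed=2)
        g = _build(sks)
        for q in sks[::37]:
            hits = g.knn_query(q, 5, ef_search=64)
            assert hits[0].genome_id == q.genome_id
            assert hits[0].distance == 0.0

    def test_query_does_not_mutate_graph(self):
        sks = planted_sketches(20, 10, P96, seed=2)
        g = _build(sks)
        before = g.adjacency_checksum()
        g.knn_query(sks[3], 10, ef_search=128)
        assert g.adjacency_checksum() == before

    def test_recall_non_decreasing_in_ef_search(self):
        sks = planted_sketches(50, 10, P96, seed=2)
        g = _build(sks, M=16, ef=100)
        queries = sks[::25]
        exact = [brute_force_knn(sks, q, 10) for q in queries]
        recalls = []
        for ef in (16, 64, 128, 256):
            approx = [g.knn_query(q, 10, ef_search=ef) for q in queries]
            recalls.append(score_recall(approx, exact, 10).average_recall)
        assert all(b >= a - 1e-9 for a, b in zip(recalls, recalls[1:]))

    def test_empty_graph_and_bad_k_rejected(self):
        g = HnswGraph(P96, HnswParams(M=4, ef_construct=8))
        sk = planted_sketches(1, 1, P96, seed=0)[0]
        with pytest.raises(ValueError):
            g.knn_query(sk, 1)
        g.insert(sk)
        with pytest.raises(ValueError):
            g.knn_query(sk, 0)
        with pytest.raises(ValueError):
            g.knn_query(sk, 2, ef_search=1)


class TestPersistence:
    def test_dump_load_round_trip_preserves_queries(self, tmp_path):
        sks = planted_sketches(20, 10, P96, seed=2)
        g = _build(sks)
        queries = sks[::31]
        before = [g.knn_query(q, 10, ef_search=64) for q in queries]
        g.dump(tmp_path / "db")
        g2 = HnswGraph.load(tmp_path / "db")
        after = [g2.knn_query(q, 10, ef_search=64) for q in queries]
        assert before == after
        assert g2.adjacency_checksum() == g.adjacency_checksum()

    def test_dump_is_deterministic(self, tmp_path):
        sks = planted_sketches(10, 5, P96, seed=2)
        _build(sks).dump(tmp_path / "a")
        _build(sks).dump(tmp_path / "b")
        for name in ("sketches.npy", "levels.npy", "graph.npz", "manifest.json",
                     "ids.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()

    def test_mismatched_query_parameters_hard_error(self, tmp_path):
        sks = planted_sketches(5, 4, P96, seed=2)
        g = _build(sks)
        g.dump(tmp_path / "db")
        g2 = HnswGraph.load(tmp_path / "db")
        wrong_k = SketchVector(
            params=SketchParams(algo="probminhash3a", m=96, k=21, seed=1),
            registers=sks[0].registers, genome_id="q")
        with pytest.raises(IncomparableSketches):
            g2.knn_query(wrong_k, 3)

    def test_truncated_database_detected(self, tmp_path):
        sks = planted_sketches(5, 4, P96, seed=2)
        g = _build(sks)
        g.dump(tmp_path / "db")
        ids = (tmp_path / "db" / "ids.tsv").read_text().splitlines()
        (tmp_path / "db" / "ids.tsv").write_text("\n".join(ids[:-1]) + "\n")
        with pytest.raises(ValueError, match="truncated"):
            HnswGraph.load(tmp_path / "db")

    def test_add_after_load_equals_single_session_build(self, tmp_path):
        sks = planted_sketches(14, 5, P96, seed=2)
        single = _build(sks)
        partial = _build(sks[:60])
        partial.dump(tmp_path / "db")
        resumed = HnswGraph.load(tmp_path / "db")
        for s in sks[60:]:
            resumed.insert(s)
        assert resumed.adjacency_checksum() == single.adjacency_checksum()
        assert resumed.ids == single.ids
        q = sks[33]
        assert resumed.knn_query(q, 10, ef_search=64) == \
            single.knn_query(q, 10, ef_search=64)


def test_layer_occupancy_decays_geometrically():
    sks = planted_sketches(100, 10, P96, seed=5)
    g = HnswGraph(P96, HnswParams(M=16, ef_construct=32, seed=9))
    for s in sks:
        g.insert(s)
    n = len(g)
    occ1 = sum(1 for l in g.levels if l >= 1)
    # P(level >= 1) = 1/M; binomial 3-sigma band
    se = math.sqrt(n * (1 / 16) * (15 / 16))
    assert abs(occ1 - n / 16) < 3 * se


def test_genome_sketch_pipeline_through_graph():
    """Sketches built from k-mer multisets are searchable end to end."""
    p = SketchParams(algo="probminhash3a", m=256, k=8, seed=0)
    sets = [multiset_from_tokens(range(i * 50, i * 50 + 400), k=8)
            for i in range(10)]
    sks = [sketch(ms, p, genome_id=f"s{i}") for i, ms in enumerate(sets)]
    g = _build(sks, M=4, ef=16)
    hits = g.knn_query(sks[4], 3, ef_search=16)
    assert hits[0].genome_id == "s4"
    # neighbors in token space are neighbors in sketch space
    assert {h.genome_id for h in hits} <= {"s3", "s4", "s5"}
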