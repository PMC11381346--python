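"""Hierarchical navigable small world index over sketch vectors.

Nodes are genome sketches; edges connect each node to at most M
neighbors per layer (2M at layer 0) under the estimated sketch distance.
Nodes are assigned to layers by an exponential-decay rule
(level = floor(−ln U · mL)), giving O(N log N) build and O(log N) query:
a query greedily descends the sparse upper layers keeping the single
closest node, then runs a beam search of width ef_search at layer 0.

Insertion additionally performs the reverse-update step: the new node is
appended to each selected neighbor's adjacency list, which is re-pruned
to its cap with the same diversity heuristic.  Queries never mutate the
graph.

All tie-breaking is by (distance, genome_id), making builds and queries
deterministic for a fixed seed and insertion order.
"""

from __future__ import annotations

import json
import math
from bisect import insort
from dataclasses import asdict, dataclass
from heapq import heappop, heappush
from pathlib import Path

import numpy as np

from ._hashing import GOLDEN, mix64, to_unit
from .sketching import (Estimator, IncomparableSketches, SketchAlgo,
                        SketchParams, SketchVector, default_estimator,
                        estimate_distance)

FORMAT_VERSION = 1
_LEVEL_SALT = 0x4C45564C


@dataclass(frozen=True)
class HnswParams:
    """Graph construction parameters.

    M is the per-node neighbor budget above layer 0 (2M at layer 0);
    ef_construct the candidate beam width during insertion (production
    guidance is > 1000, tests use less); mL the level multiplier of the
    exponential layer decay, defaulting to 1/ln(M).
    """

    M: int = 16
    ef_construct: int = 200
    mL: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.M < 2:
            raise ValueError("M must be >= 2")
        if self.ef_construct < self.M:
            raise ValueError("ef_construct must be >= M")
        if self.mL is None:
            object.__setattr__(self, "mL", 1.0 / math.log(self.M))
        if self.mL < 0:
            raise ValueError("mL must be >= 0")


@dataclass
class NeighborHit:
    genome_id: str
    distance: float
    rank: int


def assign_level(params: HnswParams, rng_draw: float) -> int:
    """Exponential-decay layer assignment: floor(−ln(u) · mL)."""
    if not 0.0 < rng_draw <= 1.0:
        raise ValueError("rng_draw must lie in (0, 1]")
    if params.mL == 0.0:
        return 0
    return int(math.floor(-math.log(rng_draw) * params.mL))


def _level_draw(seed: int, ordinal: int) -> float:
    # seeded from (params.seed, node ordinal) so that add-after-load
    # reproduces a single-session build exactly
    with np.errstate(over="ignore"):
        h = mix64(mix64(np.uint64(seed & 0xFFFFFFFFFFFFFFFF) ^ np.uint64(_LEVEL_SALT))
                  + np.uint64(ordinal) * GOLDEN)
    return float(to_unit(h))


class HnswGraph:
    """Layered proximity graph over a register matrix."""

    def __init__(self, sketch_params: SketchParams, hnsw_params: HnswParams,
                 estimator: Estimator | None = None):
        self.sketch_params = sketch_params
        self.params = hnsw_params
        self.estimator = estimator or default_estimator(sketch_params.algo)
        dtype = np.float64 if sketch_params.algo is SketchAlgo.SUPERMINHASH else (
            np.int64 if sketch_params.algo is SketchAlgo.SETSKETCH else np.uint64)
        self._regs = np.empty((0, sketch_params.m), dtype=dtype)
        self.ids: list[str] = []
        self._id_set: set[str] = set()
        self.levels: list[int] = []
        # adjacency[node][level] -> list of neighbor indices
        self.adjacency: list[list[list[int]]] = []
        self.entry_point: int = -1
        self.top_level: int = -1
        self.distance_evals: int = 0

    # -- basic accessors ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def registers(self) -> np.ndarray:
        return self._regs[: len(self.ids)]

    def _grow(self, extra: int = 1) -> None:
        need = len(self.ids) + extra
        if need > self._regs.shape[0]:
            cap = max(need, 2 * self._regs.shape[0], 16)
            new = np.empty((cap, self._regs.shape[1]), dtype=self._regs.dtype)
            new[: len(self.ids)] = self._regs[: len(self.ids)]
            self._regs = new

    def _cap(self, level: int) -> int:
        return 2 * self.params.M if level == 0 else self.params.M

    # -- distances ----------------------------------------------------------

    def _dist_many(self, q_regs: np.ndarray, idxs: list[int] | np.ndarray) -> np.ndarray:
        idxs = np.asarray(idxs, dtype=np.int64)
        self.distance_evals += int(idxs.size)
        if self.estimator is Estimator.REGISTER_MATCH:
            return 1.0 - (self._regs[idxs] == q_regs).mean(axis=1)
        # setsketch estimators need per-pair likelihood fits
        out = np.empty(idxs.size)
        q = SketchVector(params=self.sketch_params, registers=q_regs)
        for i, j in enumerate(idxs):
            s = SketchVector(params=self.sketch_params, registers=self._regs[j])
            out[i] = estimate_distance(q, s, self.estimator)
        return out

    # -- layer search primitives --------------------------------------------

    def _search_layer(self, q_regs: np.ndarray, entries: list[tuple[float, str, int]],
                      ef: int, level: int) -> list[tuple[float, str, int]]:
        """Beam search of width ef within one layer; entries pre-scored."""
        visited = {e[2] for e in entries}
        cand: list[tuple[float, str, int]] = []
        result: list[tuple[float, str, int]] = []
        for e in entries:
            heappush(cand, e)
            insort(result, e)
        del result[ef:]
        while cand:
            c = heappop(cand)
            if len(result) == ef and c[0] > result[-1][0]:
                break
            nbrs = [j for j in self.adjacency[c[2]][level] if j not in visited]
            if not nbrs:
                continue
            visited.update(nbrs)
            dists = self._dist_many(q_regs, nbrs)
            for d, j in zip(dists, nbrs):
                t = (float(d), self.ids[j], j)
                if len(result) < ef or t < result[-1]:
                    heappush(cand, t)
                    insort(result, t)
                    del result[ef:]
        return result

    def _greedy_descent(self, q_regs: np.ndarray, start: tuple[float, str, int],
                        level: int) -> tuple[float, str, int]:
        cur = start
        while True:
            nbrs = self.adjacency[cur[2]][level]
            if not nbrs:
                return cur
            dists = self._dist_many(q_regs, nbrs)
            best = min((float(d), self.ids[j], j) for d, j in zip(dists, nbrs))
            if best < cur:
                cur = best
            else:
                return cur

    def _select_neighbors(self, cands: list[tuple[float, str, int]],
                          cap: int) -> list[int]:
        """Diversity heuristic: keep a candidate only if it is closer to the
        query point than to every already-selected neighbor; fill any
        remaining slots nearest-first from the rejected candidates."""
        selected: list[int] = []
        rejected: list[tuple[float, str, int]] = []
        for d, gid, idx in cands:
            if len(selected) == cap:
                break
            if selected:
                dd = self._dist_many(self._regs[idx], selected)
                if bool((dd <= d).any()):
                    rejected.append((d, gid, idx))
                    continue
            selected.append(idx)
        for d, gid, idx in rejected:
            if len(selected) == cap:
                break
            selected.append(idx)
        return selected

    # -- public operations ---------------------------------------------------

    def insert(self, sketch_vector: SketchVector) -> int:
        """Insert one sketched genome; returns its node index."""
        if not sketch_vector.params.compatible_with(self.sketch_params):
            raise IncomparableSketches("sketch parameters do not match the graph")
        gid = sketch_vector.genome_id
        if not gid:
            raise ValueError("sketch vector has no genome_id")
        if gid in self._id_set:
            raise ValueError(f"duplicate genome_id: {gid}")
        idx = len(self.ids)
        lvl = assign_level(self.params, _level_draw(self.params.seed, idx))
        self._grow()
        self._regs[idx] = sketch_vector.registers
        self.ids.append(gid)
        self._id_set.add(gid)
        self.levels.append(lvl)
        self.adjacency.append([[] for _ in range(lvl + 1)])
        if idx == 0:
            self.entry_point = 0
            self.top_level = lvl
            return idx
        q = self._regs[idx]
        d0 = float(self._dist_many(q, [self.entry_point])[0])
        ep = (d0, self.ids[self.entry_point], self.entry_point)
        for level in range(self.top_level, lvl, -1):
            ep = self._greedy_descent(q, ep, level)
        entries = [ep]
        for level in range(min(self.top_level, lvl), -1, -1):
            cands = self._search_layer(q, entries, self.params.ef_construct, level)
            sel = self._select_neighbors(cands, self._cap(level))
            self.adjacency[idx][level] = list(sel)
            for s in sel:
                lst = self.adjacency[s][level]
                lst.append(idx)
                cap = self._cap(level)
                if len(lst) > cap:
                    ds = self._dist_many(self._regs[s], lst)
                    ranked = sorted((float(d), self.ids[j], j)
                                    for d, j in zip(ds, lst))
                    self.adjacency[s][level] = self._select_neighbors(ranked, cap)
            entries = cands if cands else [ep]
        if lvl > self.top_level:
            self.entry_point = idx
            self.top_level = lvl
        return idx

    def knn_query(self, query: SketchVector, K: int,
                  ef_search: int | None = None) -> list[NeighborHit]:
        """K nearest genomes by estimated sketch distance (graph unchanged)."""
        if len(self.ids) == 0:
            raise ValueError("query against an empty graph")
        if K < 1:
            raise ValueError("K must be >= 1")
        if not query.params.compatible_with(self.sketch_params):
            raise IncomparableSketches("query sketch parameters do not match the graph")
        if ef_search is None:
            ef_search = max(K, 64)
        if ef_search < K:
            raise ValueError("ef_search must be >= K")
        q = np.asarray(query.registers, dtype=self._regs.dtype)
        d0 = float(self._dist_many(q, [self.entry_point])[0])
        ep = (d0, self.ids[self.entry_point], self.entry_point)
        for level in range(self.top_level, 0, -1):
            ep = self._greedy_descent(q, ep, level)
        result = self._search_layer(q, [ep], ef_search, 0)
        hits = [NeighborHit(genome_id=gid, distance=d, rank=r + 1)
                for r, (d, gid, _) in enumerate(result[:K])]
        return hits

    # -- persistence ---------------------------------------------------------

    def dump(self, out_dir: str | Path) -> None:
        """Persist graph + sketches + id table; round trip is bit-exact."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        n = len(self.ids)
        sp = asdict(self.sketch_params)
        sp["algo"] = self.sketch_params.algo.value
        sp["alphabet"] = self.sketch_params.alphabet.value
        manifest = {
            "format_version": FORMAT_VERSION,
            "n_genomes": n,
            "entry_point": self.entry_point,
            "top_level": self.top_level,
            "estimator": self.estimator.value,
            "sketch_params": sp,
            "hnsw_params": asdict(self.params),
            "register_dtype": str(self._regs.dtype),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        with open(out / "ids.tsv", "w") as fh:
            for i, gid in enumerate(self.ids):
                fh.write(f"{i}\t{gid}\n")
        np.save(out / "sketches.npy", self._regs[:n])
        np.save(out / "levels.npy", np.asarray(self.levels, dtype=np.int64))
        flat: dict[str, np.ndarray] = {}
        for level in range(self.top_level + 1):
            indptr = [0]
            indices: list[int] = []
            for i in range(n):
                if self.levels[i] >= level:
                    indices.extend(self.adjacency[i][level])
                indptr.append(len(indices))
            flat[f"indptr_{level}"] = np.asarray(indptr, dtype=np.int64)
            flat[f"indices_{level}"] = np.asarray(indices, dtype=np.int64)
        np.savez(out / "graph.npz", **flat)

    @classmethod
    def load(cls, in_dir: str | Path) -> "HnswGraph":
        src = Path(in_dir)
        try:
            manifest = json.loads((src / "manifest.json").read_text())
        except FileNotFoundError as exc:
            raise FileNotFoundError(f"not a sketch database: {src}") from exc
        if manifest.get("format_version") != FORMAT_VERSION:
            raise ValueError(f"unsupported database format version in {src}")
        sp = dict(manifest["sketch_params"])
        sketch_params = SketchParams(**sp)
        hnsw_params = HnswParams(**manifest["hnsw_params"])
        graph = cls(sketch_params, hnsw_params, Estimator(manifest["estimator"]))
        regs = np.load(src / "sketches.npy")
        levels = np.load(src / "levels.npy")
        n = manifest["n_genomes"]
        if regs.shape[0] != n or levels.shape[0] != n:
            raise ValueError(f"manifest/sketch count disagreement in {src}")
        if regs.shape[1] != sketch_params.m:
            raise ValueError(f"sketch width does not match manifest m in {src}")
        ids = [""] * n
        with open(src / "ids.tsv") as fh:
            for line in fh:
                i, gid = line.rstrip("\n").split("\t")[:2]
                ids[int(i)] = gid
        if any(g == "" for g in ids):
            raise ValueError(f"truncated ids.tsv in {src}")
        graph._regs = regs.copy()
        graph.ids = ids
        graph._id_set = set(ids)
        graph.levels = [int(v) for v in levels]
        graph.entry_point = manifest["entry_point"]
        graph.top_level = manifest["top_level"]
        graph.adjacency = [[[] for _ in range(lvl + 1)] for lvl in graph.levels]
        with np.load(src / "graph.npz") as flat:
            for level in range(graph.top_level + 1):
                indptr = flat[f"indptr_{level}"]
                indices = flat[f"indices_{level}"]
                for i in range(n):
                    lo, hi = indptr[i], indptr[i + 1]
                    if graph.levels[i] >= level:
                        graph.adjacency[i][level] = [int(v) for v in indices[lo:hi]]
        return graph

    def adjacency_checksum(self) -> int:
        """Stable checksum of the adjacency structure (used to assert that
        queries do not mutate the graph)."""
        acc = 0
        for i, per_level in enumerate(self.adjacency):
            for lvl, nbrs in enumerate(per_level):
                for j in nbrs:
                    acc = (acc * 1000003 + i * 131 + lvl * 31 + j) % (1 << 61)
        return acc
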