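"""Three-step best-match search: nucleotide -> proteome -> universal genes.

Queries are first searched against the whole-genome nucleotide database;
if even the best hit is beyond the reliable nucleotide distance range
(1 − J_p > 0.9850, i.e. below ~78% ANI at k = 16), the query is
escalated to the whole-proteome amino-acid database, and beyond the
proteome range (distance > 0.9720) to the universal-gene database.
Hits are annotated with ANI/AAI proxies through the Mash transform at
the level's own k, and a classification *suggestion* (never an
authoritative taxonomy) is derived:

* same species        — best hit ANI proxy >= 0.95;
* same genus, new sp. — >= 5 of the top 10 hits with AAI proxy >= 0.65
                        (sharing a genus label when labels are given);
* same family         — top 5 hits all with AAI proxy >= 0.52;
* otherwise unclassified at family rank.

Databases may be randomly split into pieces built independently;
pooling each piece's top-k (k >= K) and re-sorting by distance is
exactly equivalent to searching the unsplit database.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from ._hashing import mix64
from .genome_io import FastaError, GenomeRecord, read_fasta
from .hnsw import HnswGraph, HnswParams, NeighborHit
from .kmer import extract_kmers
from .sketching import SketchParams, sketch
from .similarity import mash_inverse, mash_transform

logger = logging.getLogger("genosketch")

FASTA_SUFFIXES = (".fa", ".fasta", ".fna", ".faa", ".fsa",
                  ".fa.gz", ".fasta.gz", ".fna.gz", ".faa.gz", ".fsa.gz")


class SearchLevel(str, Enum):
    NUCLEOTIDE = "nucleotide"
    PROTEOME = "proteome"
    UNIVERSAL = "universal"


class Suggestion(str, Enum):
    SAME_SPECIES = "same_species"
    SAME_GENUS_NEW_SPECIES = "same_genus_new_species"
    SAME_FAMILY_NEW_GENUS = "same_family_new_genus"
    UNCLASSIFIED_AT_FAMILY = "unclassified_at_family"


@dataclass(frozen=True)
class PipelineThresholds:
    """Switching and classification thresholds.

    The nucleotide cutoff is tied to the Mash equation: at k = 16,
    78% ANI corresponds to a 1 − J distance of 0.9850; consistency is
    asserted at construction so a misconfigured pipeline refuses to run.
    """

    nt_distance_cutoff: float = 0.9850
    aa_distance_cutoff: float = 0.9720
    viral_nt_cutoff: float = 0.9800
    species_ani: float = 0.95
    genus_aai: float = 0.65
    genus_votes: int = 5
    vote_pool: int = 10
    family_aai: float = 0.52
    nt_k: int = 16

    def __post_init__(self):
        for v in (self.nt_distance_cutoff, self.aa_distance_cutoff,
                  self.viral_nt_cutoff, self.species_ani, self.genus_aai,
                  self.family_aai):
            if not 0.0 <= v <= 1.0:
                raise ValueError("thresholds must lie in [0, 1]")
        implied = 1.0 - mash_inverse(0.78, self.nt_k)
        if abs(round(implied, 4) - round(self.nt_distance_cutoff, 4)) > 5e-5:
            raise ValueError(
                f"inconsistent configuration: nt cutoff {self.nt_distance_cutoff} "
                f"does not match 78% ANI at k={self.nt_k} (implied {implied:.4f})")


@dataclass
class AnnotatedHit:
    genome_id: str
    distance: float
    rank: int
    identity_proxy: float | None   # ANI (nucleotide level) or AAI (aa levels)
    beyond_reliable_range: bool


@dataclass
class SearchReport:
    query_id: str
    level_used: SearchLevel
    hits: list[AnnotatedHit]
    suggestion: Suggestion
    evidence: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# database building


def list_fasta(genome_dir: str | Path) -> list[Path]:
    paths = [p for p in sorted(Path(genome_dir).iterdir())
             if p.name.lower().endswith(FASTA_SUFFIXES)]
    return paths


def build_graph(records: list[GenomeRecord], sketch_params: SketchParams,
                hnsw_params: HnswParams) -> tuple[HnswGraph, list[str]]:
    """Sketch and insert records in order; returns (graph, skipped ids)."""
    graph = HnswGraph(sketch_params, hnsw_params)
    skipped: list[str] = []
    for rec in records:
        ms = extract_kmers(rec, sketch_params.k)
        if not ms:
            logger.warning("genome %s yields no k-mers at k=%d; skipped",
                           rec.genome_id, sketch_params.k)
            skipped.append(rec.genome_id)
            continue
        graph.insert(sketch(ms, sketch_params, genome_id=rec.genome_id))
    return graph, skipped


def tohnsw(genome_dir: str | Path, out_dir: str | Path,
           sketch_params: SketchParams, hnsw_params: HnswParams,
           strict: bool = True) -> HnswGraph:
    """Build a sketch database from a directory of FASTA files.

    Files are processed in sorted-path order so rebuilds are
    deterministic; genomes producing an empty k-mer multiset are skipped
    with a warning and recorded in the build manifest.
    """
    paths = list_fasta(genome_dir)
    if not paths:
        raise FastaError(f"no FASTA files found in {genome_dir}")
    records = [read_fasta(p, sketch_params.alphabet, strict=strict) for p in paths]
    ids = [r.genome_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids derived from file names")
    graph, skipped = build_graph(records, sketch_params, hnsw_params)
    if len(graph) == 0:
        raise ValueError("no genome produced a non-empty k-mer multiset")
    graph.dump(out_dir)
    occupancy = [sum(1 for l in graph.levels if l >= lev)
                 for lev in range(graph.top_level + 1)]
    logger.info("built database of %d genomes; layer occupancy %s",
                len(graph), occupancy)
    (Path(out_dir) / "build_info.json").write_text(json.dumps({
        "skipped_genomes": skipped,
        "layer_occupancy": occupancy,
    }, indent=1))
    return graph


def add(db_dir: str | Path, genome_dir: str | Path, strict: bool = True) -> HnswGraph:
    """Add new genomes to an existing database with its original parameters."""
    graph = HnswGraph.load(db_dir)
    paths = list_fasta(genome_dir)
    skipped: list[str] = []
    for p in paths:
        rec = read_fasta(p, graph.sketch_params.alphabet, strict=strict)
        ms = extract_kmers(rec, graph.sketch_params.k)
        if not ms:
            logger.warning("genome %s yields no k-mers; skipped", rec.genome_id)
            skipped.append(rec.genome_id)
            continue
        graph.insert(sketch(ms, graph.sketch_params, genome_id=rec.genome_id))
    graph.dump(db_dir)
    info_path = Path(db_dir) / "build_info.json"
    info = json.loads(info_path.read_text()) if info_path.exists() else {}
    info.setdefault("skipped_genomes", []).extend(skipped)
    info["layer_occupancy"] = [sum(1 for l in graph.levels if l >= lev)
                               for lev in range(graph.top_level + 1)]
    info_path.write_text(json.dumps(info, indent=1))
    return graph


# ---------------------------------------------------------------------------
# querying


def _query_level(graph: HnswGraph, record: GenomeRecord, K: int,
                 ef_search: int | None, warnings: list[str]) -> list[NeighborHit] | None:
    if record.alphabet != graph.sketch_params.alphabet:
        raise ValueError(f"query {record.genome_id}: alphabet does not match database")
    ms = extract_kmers(record, graph.sketch_params.k)
    if not ms:
        warnings.append(f"query produces no k-mers at k={graph.sketch_params.k}")
        return None
    if K > len(graph):
        warnings.append(f"K={K} clamped to database size {len(graph)}")
        K = len(graph)
    sv = sketch(ms, graph.sketch_params, genome_id=record.genome_id)
    return graph.knn_query(sv, K, ef_search)


def _annotate(hits: list[NeighborHit], k: int, cutoff: float) -> list[AnnotatedHit]:
    out = []
    for h in hits:
        j = 1.0 - h.distance
        proxy = mash_transform(j, k) if j > 0.0 else None
        out.append(AnnotatedHit(genome_id=h.genome_id, distance=h.distance,
                                rank=h.rank, identity_proxy=proxy,
                                beyond_reliable_range=h.distance > cutoff))
    return out


def _genus_vote(hits: list[AnnotatedHit], thresholds: PipelineThresholds,
                labels: dict[str, dict[str, str]] | None) -> tuple[bool, dict]:
    pool = hits[: thresholds.vote_pool]
    qualifying = [h for h in pool
                  if h.identity_proxy is not None
                  and h.identity_proxy >= thresholds.genus_aai]
    if labels:
        by_genus: dict[str, int] = {}
        for h in qualifying:
            genus = labels.get(h.genome_id, {}).get("genus")
            if genus:
                by_genus[genus] = by_genus.get(genus, 0) + 1
        if by_genus:
            genus, votes = max(by_genus.items(), key=lambda kv: (kv[1], kv[0]))
            return votes >= thresholds.genus_votes, {
                "genus": genus, "votes": votes, "labeled": True}
    return len(qualifying) >= thresholds.genus_votes, {
        "votes": len(qualifying), "labeled": False}


def _family_check(hits: list[AnnotatedHit], thresholds: PipelineThresholds) -> bool:
    top5 = hits[: thresholds.genus_votes]
    return bool(top5) and all(h.identity_proxy is not None
                              and h.identity_proxy >= thresholds.family_aai
                              for h in top5)


def classify(level: SearchLevel, hits: list[AnnotatedHit],
             aa_hits: list[AnnotatedHit] | None,
             thresholds: PipelineThresholds,
             labels: dict[str, dict[str, str]] | None) -> tuple[Suggestion, dict]:
    """Apply the species/genus/family suggestion rules.

    At the nucleotide level the species rule uses the ANI proxy of the
    best hit; genus/family votes need AAI proxies, supplied either by
    the reported level itself (aa levels) or by an auxiliary proteome
    search (``aa_hits``) when the report is at the nucleotide level.
    """
    evidence: dict = {}
    if level is SearchLevel.NUCLEOTIDE:
        best = hits[0] if hits else None
        if best and best.identity_proxy is not None:
            evidence["top1_ani"] = best.identity_proxy
            if best.identity_proxy >= thresholds.species_ani:
                return Suggestion.SAME_SPECIES, evidence
        vote_hits = aa_hits
        evidence["aai_source"] = "auxiliary_proteome_search" if aa_hits else None
    else:
        vote_hits = hits
        evidence["aai_source"] = level.value
    if vote_hits:
        ok, detail = _genus_vote(vote_hits, thresholds, labels)
        evidence["genus_vote"] = detail
        if ok:
            return Suggestion.SAME_GENUS_NEW_SPECIES, evidence
        if _family_check(vote_hits, thresholds):
            return Suggestion.SAME_FAMILY_NEW_GENUS, evidence
    return Suggestion.UNCLASSIFIED_AT_FAMILY, evidence


def request(dbs: dict[SearchLevel, HnswGraph],
            queries: list[dict],
            K: int = 10,
            thresholds: PipelineThresholds | None = None,
            labels: dict[str, dict[str, str]] | None = None,
            viral: bool = False,
            ef_search: int | None = None) -> list[SearchReport]:
    """Run the three-step search for each query.

    ``queries`` holds one dict per query mapping SearchLevel to the
    corresponding GenomeRecord (missing levels stop escalation with a
    warning).  In viral mode the nucleotide step is skipped entirely and
    searches start at the proteome level.
    """
    thresholds = thresholds or PipelineThresholds()
    reports: list[SearchReport] = []
    order = ([SearchLevel.PROTEOME, SearchLevel.UNIVERSAL] if viral
             else [SearchLevel.NUCLEOTIDE, SearchLevel.PROTEOME, SearchLevel.UNIVERSAL])
    cutoffs = {
        SearchLevel.NUCLEOTIDE: thresholds.nt_distance_cutoff,
        SearchLevel.PROTEOME: thresholds.aa_distance_cutoff,
        SearchLevel.UNIVERSAL: 1.0,
    }
    for query in queries:
        qid = next(r.genome_id for r in query.values())
        warnings: list[str] = []
        chosen: tuple[SearchLevel, list[AnnotatedHit]] | None = None
        for level in order:
            graph = dbs.get(level)
            record = query.get(level)
            if graph is None or record is None:
                if chosen is not None:
                    warnings.append(
                        f"stopping at {chosen[0].value}: no "
                        f"{'database' if graph is None else 'query input'} "
                        f"for {level.value}")
                break
            hits = _query_level(graph, record, K, ef_search, warnings)
            if hits is None:
                break
            annotated = _annotate(hits, graph.sketch_params.k, cutoffs[level])
            chosen = (level, annotated)
            if hits and hits[0].distance <= cutoffs[level]:
                break
            if level is order[-1]:
                break
        if chosen is None:
            reports.append(SearchReport(
                query_id=qid, level_used=order[0], hits=[],
                suggestion=Suggestion.UNCLASSIFIED_AT_FAMILY,
                warnings=warnings + ["no searchable level for this query"]))
            continue
        level, annotated = chosen
        aa_hits = None
        if (level is SearchLevel.NUCLEOTIDE
                and annotated and annotated[0].identity_proxy is not None
                and annotated[0].identity_proxy < thresholds.species_ani
                and SearchLevel.PROTEOME in dbs
                and SearchLevel.PROTEOME in query):
            aux = _query_level(dbs[SearchLevel.PROTEOME],
                               query[SearchLevel.PROTEOME], K, ef_search, warnings)
            if aux is not None:
                aa_hits = _annotate(aux, dbs[SearchLevel.PROTEOME].sketch_params.k,
                                    cutoffs[SearchLevel.PROTEOME])
        suggestion, evidence = classify(level, annotated, aa_hits, thresholds, labels)
        reports.append(SearchReport(query_id=qid, level_used=level, hits=annotated,
                                    suggestion=suggestion, evidence=evidence,
                                    warnings=warnings))
    return reports


# ---------------------------------------------------------------------------
# database splitting


def split_build(genome_dir: str | Path, out_root: str | Path, n_pieces: int,
                sketch_params: SketchParams, hnsw_params: HnswParams,
                strict: bool = True) -> list[Path]:
    """Randomly partition genomes into pieces and build one database each."""
    paths = list_fasta(genome_dir)
    if n_pieces < 1:
        raise ValueError("n_pieces must be >= 1")
    if n_pieces > len(paths):
        raise ValueError("more pieces than genomes")
    with np.errstate(over="ignore"):
        rng = np.random.default_rng(
            int(mix64(np.uint64(sketch_params.seed) ^ np.uint64(0x53504C54))))
    assignment = rng.integers(0, n_pieces, size=len(paths))
    out_root = Path(out_root)
    piece_dirs: list[Path] = []
    partition: dict[str, int] = {}
    for piece in range(n_pieces):
        sub = [p for p, a in zip(paths, assignment) if a == piece]
        piece_dir = out_root / f"piece_{piece:03d}"
        records = [read_fasta(p, sketch_params.alphabet, strict=strict) for p in sub]
        for rec in records:
            partition[rec.genome_id] = piece
        graph, _ = build_graph(records, sketch_params, hnsw_params)
        graph.dump(piece_dir)
        piece_dirs.append(piece_dir)
    (out_root / "split_manifest.json").write_text(json.dumps({
        "n_pieces": n_pieces,
        "seed": sketch_params.seed,
        "partition": partition,
    }, indent=1, sort_keys=True))
    return piece_dirs


def split_request(pieces: list[HnswGraph], query, K: int,
                  per_piece_k: int | None = None,
                  ef_search: int | None = None) -> list[NeighborHit]:
    """Pool per-piece top-k hits and re-rank; exact when per_piece_k >= K."""
    per_piece_k = K if per_piece_k is None else per_piece_k
    if per_piece_k < K:
        raise ValueError("per_piece_k must be >= K")
    p0 = pieces[0].sketch_params
    if not all(g.sketch_params.compatible_with(p0) for g in pieces):
        raise ValueError("split pieces were built with inconsistent sketch parameters")
    pooled: list[tuple[float, str]] = []
    for g in pieces:
        kk = min(per_piece_k, len(g))
        for h in g.knn_query(query, kk, ef_search):
            pooled.append((h.distance, h.genome_id))
    pooled.sort()
    return [NeighborHit(genome_id=gid, distance=d, rank=r + 1)
            for r, (d, gid) in enumerate(pooled[:K])]
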