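"""FASTA input/output for whole-genome records.

One FASTA file corresponds to one genome (an assembly may contain many
contigs, which are kept as separate sequences inside the record so that
k-mer windows never span contig joins).  Files may be gzip-compressed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from Bio import SeqIO


class Alphabet(str, Enum):
    NUCLEOTIDE = "nucleotide"
    AMINOACID = "aminoacid"


# residues tolerated after normalization; anything else is an error (strict)
# or is skipped with a report (lenient).  Ambiguity codes are retained here
# and only excluded later at k-mer extraction.
NT_ALLOWED = set("ACGTUNRYSWKMBDHV")
AA_ALLOWED = set("ACDEFGHIKLMNPQRSTVWYXBZJUO")


@dataclass
class GenomeRecord:
    """All sequences of one genome, in stable file order."""

    genome_id: str
    sequences: list[str]
    alphabet: Alphabet
    source_path: str = ""
    skipped: list[str] = field(default_factory=list)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)


class FastaError(ValueError):
    pass


def _open_maybe_gzip(path: Path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path, alphabet: Alphabet | str, *, strict: bool = True,
               genome_id: str | None = None) -> GenomeRecord:
    """Read one (optionally gzipped) FASTA file as a single genome.

    Residues are uppercased; ``*`` stop codons are stripped from amino-acid
    input.  With ``strict`` a residue outside the alphabet raises
    :class:`FastaError` naming the record and position; otherwise the
    offending residue is removed and noted in ``record.skipped``.
    """
    path = Path(path)
    alphabet = Alphabet(alphabet)
    if not path.exists():
        raise FastaError(f"no such file: {path}")
    if genome_id is None:
        genome_id = path.name
        for suffix in (".gz", ".fasta", ".fa", ".fna", ".faa", ".fsa"):
            if genome_id.lower().endswith(suffix):
                genome_id = genome_id[: -len(suffix)]
    allowed = NT_ALLOWED if alphabet is Alphabet.NUCLEOTIDE else AA_ALLOWED
    sequences: list[str] = []
    skipped: list[str] = []
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            if alphabet is Alphabet.AMINOACID:
                seq = seq.replace("*", "")
            if alphabet is Alphabet.NUCLEOTIDE:
                seq = seq.replace("U", "T")
            bad = set(seq) - allowed
            if bad:
                pos = next(i for i, c in enumerate(seq) if c in bad)
                msg = (f"{path}:{rec.id}: residue {seq[pos]!r} at position {pos} "
                       f"outside {alphabet.value} alphabet")
                if strict:
                    raise FastaError(msg)
                skipped.append(msg)
                seq = "".join(c for c in seq if c in allowed)
            sequences.append(seq)
    if not sequences:
        raise FastaError(f"empty FASTA file: {path}")
    return GenomeRecord(genome_id=genome_id, sequences=sequences,
                        alphabet=alphabet, source_path=str(path), skipped=skipped)


def write_fasta(record: GenomeRecord, path: str | Path, *, width: int = 80) -> None:
    """Write a record back to FASTA (one entry per sequence)."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, seq in enumerate(record.sequences):
            fh.write(f">{record.genome_id}_{i}\n")
            for j in range(0, len(seq), width):
                fh.write(seq[j:j + width] + "\n")
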