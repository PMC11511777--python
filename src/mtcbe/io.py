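"""File I/O: FASTA/FASTQ via Biopython, BED6 for design intervals.

FASTQ paths ending in ``.gz`` are transparently (de)compressed.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .genome_model import EditorPair, SequenceRecord

PathLike = Union[str, Path]


class Read(NamedTuple):
    """A single sequencing read (name, bases, Phred string)."""

    name: str
    seq: str
    qual: str


def _open_text(path: PathLike, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fasta(path: PathLike, ref_offset: Optional[int] = None) -> list[SequenceRecord]:
    """Load all records of a FASTA file as :class:`SequenceRecord`."""
    with _open_text(path, "r") as fh:
        return [SequenceRecord(r.id, str(r.seq), ref_offset) for r in SeqIO.parse(fh, "fasta")]


def write_fasta(records: Iterable[SequenceRecord], path: PathLike) -> None:
    bio = [BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with _open_text(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")


def read_fastq(path: PathLike) -> list[Read]:
    reads = []
    with _open_text(path, "r") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            reads.append(Read(rec.id, str(rec.seq), qual))
    return reads


def write_fastq(reads: Iterable[Read], path: PathLike) -> None:
    with _open_text(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.seq}\n+\n{r.qual}\n")


def write_bed6(pairs: Iterable[tuple[str, EditorPair, str]], path: PathLike) -> None:
    """Write arms and spacers of editor pairs as BED6 features.

    ``pairs`` yields (chrom, pair, name_prefix).  Arms carry +/- strand
    per the strand their TALE binds; the spacer is strandless.  BED is
    0-based half-open, matching internal coordinates.
    """
    with _open_text(path, "w") as fh:
        for chrom, pair, prefix in pairs:
            rows = [
                (pair.left.start, pair.left.end, f"{prefix}_left", "+"),
                (pair.spacer[0], pair.spacer[1], f"{prefix}_spacer", "."),
                (pair.right.start, pair.right.end, f"{prefix}_right", "-"),
            ]
            for start, end, name, strand in rows:
                fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\n")
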