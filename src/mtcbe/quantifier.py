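"""Read-to-table quantification of amplicon base-editing outcomes.

Turns FASTQ reads plus an amplicon reference into the two tables the
downstream statistics consume:

* a **nucleotide count table** — per reference position, counts of
  A/C/G/T/deletion and the resulting percentages; the per-cytosine
  editing activity at a top-strand C is its %T, at a bottom-strand C
  (top-strand G) its %A;
* a **spacer allele table** — reads collapsed to their spacer-
  restricted strings, with per-site conversion flags; the *overall
  on-target editing* of a sample is the percentage of aligned reads
  carrying at least one C•G→T•A conversion anywhere in the spacer.

Reads are globally aligned to the reference (edit-distance alignment
with traceback); reads below a configurable identity are discarded and
counted.  By default quantification covers the entire spacer; a
CRISPResso-style parity window (size 8/10 centered near the spacer 3'
end) is available for users comparing against that tool's outputs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import numpy as np
import pandas as pd

from .errors import BarcodeConfigError, BoundsError
from .genome_model import CytosineSite, EditorPair, SequenceRecord
from .io import Read

_SYMBOLS = ("A", "C", "G", "T", "del")


@dataclass(frozen=True)
class QuantConfig:
    """Quantification settings.

    ``min_identity`` is the fraction of matching columns in the global
    alignment below which a read is discarded (0.80 by default, logged
    in every report).  ``window_size``/``window_center`` switch on the
    CRISPResso-parity quantification window; when ``window_size`` is
    None the full spacer is quantified.  Reads whose spacer segment
    contains a deletion stay in the on-target denominator unless
    ``include_indel_reads_in_denominator`` is False.
    """

    min_identity: float = 0.80
    window_size: Optional[int] = None
    window_center: Optional[int] = None
    barcode_map: Optional[Mapping[str, str]] = None
    include_indel_reads_in_denominator: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.min_identity <= 1.0:
            raise ValueError("min_identity must be in (0, 1]")
        if self.window_size is not None and self.window_size < 1:
            raise ValueError("window_size must be >= 1")


@dataclass
class DemuxResult:
    by_sample: dict[str, list[Read]]
    unassigned: list[Read]

    @property
    def n_unassigned(self) -> int:
        return len(self.unassigned)


def demultiplex(reads: Iterable[Read], barcode_map: Mapping[str, str]) -> DemuxResult:
    """Assign reads to samples by exact barcode prefix and strip it.

    Barcodes must be equal length with pairwise Hamming distance >= 2
    so one sequencing error cannot silently reassign a read; violating
    maps are a configuration error.
    """
    barcodes = list(barcode_map)
    if not barcodes:
        raise BarcodeConfigError("barcode map is empty")
    blen = len(barcodes[0])
    if any(len(b) != blen for b in barcodes):
        raise BarcodeConfigError("barcodes must all have equal length")
    for i, a in enumerate(barcodes):
        for b in barcodes[i + 1 :]:
            if sum(x != y for x, y in zip(a, b)) < 2:
                raise BarcodeConfigError(
                    f"barcodes {a!r} and {b!r} are within Hamming distance 1"
                )
    result = DemuxResult({barcode_map[b]: [] for b in barcodes}, [])
    lut = {b: barcode_map[b] for b in barcodes}
    for r in reads:
        sample = lut.get(r.seq[:blen])
        if sample is None:
            result.unassigned.append(r)
        else:
            result.by_sample[sample].append(Read(r.name, r.seq[blen:], r.qual[blen:]))
    return result


def merge_read_pair(r1: Read, r2: Read, min_overlap: int = 10) -> Read:
    """Merge an overlapping pair into one pseudo-read.

    ``r2`` is reverse-complemented, the offset maximizing overlap
    matches is chosen, and disagreeing columns take the higher-quality
    base (tie -> N, which contributes to coverage but to no base
    count).
    """
    from .genome_model import revcomp

    s2 = revcomp(r2.seq)
    q2 = r2.qual[::-1]
    best_offset, best_score = None, -1
    for offset in range(0, len(r1.seq) - min_overlap + 1):
        ov = min(len(r1.seq) - offset, len(s2))
        matches = sum(r1.seq[offset + i] == s2[i] for i in range(ov))
        if matches > best_score:
            best_score, best_offset = matches, offset
    offset = best_offset if best_offset is not None else len(r1.seq)
    merged_seq, merged_qual = list(r1.seq[:offset]), list(r1.qual[:offset])
    ov = min(len(r1.seq) - offset, len(s2))
    for i in range(ov):
        a, qa = r1.seq[offset + i], r1.qual[offset + i]
        b, qb = s2[i], q2[i]
        if a == b:
            merged_seq.append(a)
            merged_qual.append(max(qa, qb))
        elif qa > qb:
            merged_seq.append(a)
            merged_qual.append(qa)
        elif qb > qa:
            merged_seq.append(b)
            merged_qual.append(qb)
        else:
            merged_seq.append("N")
            merged_qual.append(qa)
    merged_seq += list(s2[ov:])
    merged_qual += list(q2[ov:])
    return Read(r1.name, "".join(merged_seq), "".join(merged_qual))


@dataclass
class AlignedReads:
    """Per-read base calls at each reference position.

    ``calls`` holds one string per surviving read, of reference length:
    A/C/G/T for called bases, '-' for a deletion, 'N' for a no-call.
    Insertions relative to the reference are dropped (they occupy no
    reference position).
    """

    ref: SequenceRecord
    calls: list[str] = field(default_factory=list)
    n_discarded: int = 0

    @property
    def n_aligned(self) -> int:
        return len(self.calls)


def _align_one(seq: str, ref: str) -> tuple[str, float]:
    """Global (NW) alignment of one read; returns (calls, identity)."""
    if seq == ref:
        return seq, 1.0
    aln = edlib.align(seq, ref, mode="NW", task="path")
    cigar = aln["cigar"]
    calls = []
    qi = ri = 0
    matches = columns = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        columns += n
        if ch == "=":
            calls.append(seq[qi : qi + n])
            matches += n
            qi += n
            ri += n
        elif ch == "X":
            calls.append(seq[qi : qi + n])
            qi += n
            ri += n
        elif ch == "D":  # deletion in read relative to reference
            calls.append("-" * n)
            ri += n
        elif ch == "I":  # insertion: consumes read only
            qi += n
        else:  # pragma: no cover - edlib emits only =/X/I/D
            raise ValueError(f"unexpected cigar op {ch!r}")
    return "".join(calls), matches / columns


def align_reads(
    reads: Iterable[Read], rec: SequenceRecord, cfg: QuantConfig = QuantConfig()
) -> AlignedReads:
    """Globally align reads to the amplicon; drop low-identity reads."""
    out = AlignedReads(rec)
    ref = rec.seq
    for r in reads:
        calls, identity = _align_one(r.seq, ref)
        if identity < cfg.min_identity:
            out.n_discarded += 1
        else:
            out.calls.append(calls)
    return out


@dataclass
class NucleotideCountTable:
    """Per-position base counts and percentages over aligned reads.

    ``coverage`` is the base-call coverage A+C+G+T+del; N calls are
    tracked separately and excluded from both counts and percentage
    denominators.
    """

    ref: SequenceRecord
    counts: pd.DataFrame  # columns A, C, G, T, del, N, coverage; index = position

    def pct(self, base: str) -> pd.Series:
        """Percentage of ``base`` calls per position (NaN at coverage 0)."""
        cov = self.counts["coverage"].replace(0, np.nan)
        return 100.0 * self.counts[base] / cov

    def to_frame(self) -> pd.DataFrame:
        df = self.counts.copy()
        df.insert(0, "ref_base", list(self.ref.seq))
        for b in ("A", "C", "G", "T"):
            df[f"pct_{b}"] = self.pct(b).round(6)
        return df


@dataclass
class AlleleTable:
    """Spacer-collapsed allele counts over aligned reads."""

    region: tuple[int, int]
    df: pd.DataFrame  # columns: allele, count, fraction, edited
    n_aligned: int    # denominator used for fractions

    def to_frame(self) -> pd.DataFrame:
        return self.df.copy()


def _count_matrix(calls: Sequence[str], L: int) -> pd.DataFrame:
    counts = {s: np.zeros(L, dtype=np.int64) for s in (*_SYMBOLS, "N")}
    if calls:
        mat = np.frombuffer("".join(calls).encode(), dtype=np.uint8).reshape(len(calls), L)
        for sym, byte in (("A", 65), ("C", 67), ("G", 71), ("T", 84), ("del", 45), ("N", 78)):
            counts[sym] = (mat == byte).sum(axis=0)
    df = pd.DataFrame(counts)
    df["coverage"] = df[list(_SYMBOLS)].sum(axis=1)
    df.index.name = "position"
    return df


def _conversion_flags(allele: str, sites: Sequence[CytosineSite], origin: int) -> tuple[bool, ...]:
    flags = []
    for s in sites:
        off = s.top_pos - origin
        flags.append(0 <= off < len(allele) and allele[off] == s.converted_base)
    return tuple(flags)


def build_tables(
    aligned: AlignedReads,
    pair_or_region,
    cfg: QuantConfig = QuantConfig(),
    sites: Optional[Sequence[CytosineSite]] = None,
) -> tuple[NucleotideCountTable, AlleleTable]:
    """Build the nucleotide and allele tables from aligned reads.

    ``pair_or_region`` is an :class:`EditorPair` (its spacer is the
    quantified region) or an explicit (start, end) interval — the
    latter is how pseudospacers in nuclear homologs are quantified with
    metric-identical code.  ``sites`` defaults to the C/G census of the
    region.
    """
    from .genome_model import region_cytosines

    rec = aligned.ref
    if isinstance(pair_or_region, EditorPair):
        region = pair_or_region.spacer
    else:
        region = tuple(pair_or_region)
    start, end = region
    if not (0 <= start <= end <= len(rec)):
        raise BoundsError(f"region [{start}, {end}) outside amplicon of length {len(rec)}")
    if cfg.window_size is not None:
        region = parity_window(region, cfg.window_size, cfg.window_center, len(rec))
        start, end = region
    if sites is None:
        sites = region_cytosines(rec, region, index_origin=start)

    ntable = NucleotideCountTable(rec, _count_matrix(aligned.calls, len(rec)))

    spacer_strs = [c[start:end] for c in aligned.calls]
    if not cfg.include_indel_reads_in_denominator:
        spacer_strs = [s for s in spacer_strs if "-" not in s]
    counter = Counter(spacer_strs)
    n = sum(counter.values())
    rows = []
    for allele, count in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0])):
        flags = _conversion_flags(allele, sites, start)
        rows.append(
            {
                "allele": allele,
                "count": count,
                "fraction": count / n if n else 0.0,
                "edited": any(flags),
                "n_conversions": sum(flags),
            }
        )
    adf = pd.DataFrame(rows, columns=["allele", "count", "fraction", "edited", "n_conversions"])
    return ntable, AlleleTable(region, adf, n)


def parity_window(
    spacer: tuple[int, int], size: int, center: Optional[int], seq_len: int
) -> tuple[int, int]:
    """CRISPResso-style quantification window on the spacer-as-guide.

    The window of ``size`` bases is anchored ``|center|`` bases from the
    spacer 3' end (center is negative, counting back from the 3' end,
    as in that tool's conventions); clipped to the amplicon.
    """
    start, end = spacer
    anchor = end + (center if center is not None else -size)
    w_start = max(anchor, 0)
    w_end = min(anchor + size, seq_len)
    if w_start >= w_end:
        raise BoundsError("parity window collapsed to an empty interval")
    return (w_start, w_end)


def per_cytosine_rates(
    table: NucleotideCountTable, sites: Sequence[CytosineSite]
) -> dict[int, Optional[float]]:
    """Editing percent per spacer cytosine, keyed by C_k.

    Top-strand C sites report %T, bottom-strand C sites report %A.
    Zero-coverage sites report None (missing), never 0.
    """
    out: dict[int, Optional[float]] = {}
    for s in sites:
        if s.top_pos not in table.counts.index:
            raise BoundsError(f"site position {s.top_pos} outside table")
        cov = table.counts.at[s.top_pos, "coverage"]
        if cov == 0:
            out[s.spacer_index] = None
        else:
            out[s.spacer_index] = float(
                100.0 * table.counts.at[s.top_pos, s.converted_base] / cov
            )
    return out


def overall_on_target(alleles: AlleleTable, sites: Sequence[CytosineSite] = ()) -> float:
    """Percent of aligned reads with >= 1 spacer C•G→T•A conversion.

    Counted at the allele (read) level, so co-occurring conversions on
    one molecule are one edited read — the statistic that separates a
    heteroplasmy-like mixture from independent per-site editing.
    """
    if alleles.n_aligned == 0:
        return 0.0
    edited = alleles.df.loc[alleles.df["edited"], "count"].sum()
    return float(100.0 * edited / alleles.n_aligned)


def quantify(
    reads: Iterable[Read],
    rec: SequenceRecord,
    pair: EditorPair,
    cfg: QuantConfig = QuantConfig(),
):
    """Convenience pipeline: align, build tables, compute headline rates.

    Returns (aligned, nucleotide table, allele table, per-C_k rates,
    overall on-target percent).
    """
    from .genome_model import spacer_cytosines

    aligned = align_reads(reads, rec, cfg)
    sites = spacer_cytosines(pair, rec)
    ntab, atab = build_tables(aligned, pair, cfg, sites=sites)
    rates = per_cytosine_rates(ntab, sites)
    on = overall_on_target(atab, sites)
    return aligned, ntab, atab, rates, on
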