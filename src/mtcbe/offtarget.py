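"""Nuclear-specificity tooling: pseudospacer discovery in NUMT-like
homologs and NUMT-discriminating PCR primer proposal.

Nuclear copies of mitochondrial sequence (NUMTs) confound both PCR and
off-target analysis of mtDNA editing.  Two operations address this:

* :func:`pseudospacer_scan` — an ungapped sliding-window scan of a
  nuclear subject (both strands) for the TALE-pair footprint
  (left arm + spacer + right arm), reporting per-arm mismatch counts
  and the *pseudospacer*: the subject region analogous to the genuine
  mtDNA spacer.  Editing inside a pseudospacer is quantified by the
  exact same quantifier code path as the on-target spacer.
* :func:`discriminating_primers` — primer proposals whose 3' terminus
  sits exactly on a base that differs between the mitochondrial target
  and its nuclear homolog (matching the mito allele), annotated with
  3'-terminal phosphorothioate (PS) bonds.  The 3' mismatch plus PS
  protection biases proofreading polymerases against extending the
  nuclear template, raising PCR specificity for true mtDNA.

Matching is Hamming (ungapped) by design: the canonical nuisance NUMT
differs from its mitochondrial counterpart by isolated substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.SeqUtils import MeltingTemp

from .errors import BoundsError, HomologyError
from .genome_model import EditorPair, SequenceRecord, revcomp
from .quantifier import AlignedReads, QuantConfig, build_tables, overall_on_target, per_cytosine_rates


@dataclass
class PseudoSiteHit:
    """One candidate TALE-dependent off-target site in a subject."""

    subject_id: str
    start: int                     # subject plus-strand coords, 0-based half-open
    end: int
    strand: str                    # '+' or '-'
    left_mismatches: int
    spacer_mismatches: int
    right_mismatches: int
    pseudospacer: tuple[int, int]  # subject plus-strand coords
    mismatch_positions: list[tuple[int, str, str]] = field(default_factory=list)
    # (subject plus-strand position, subject base, query base)

    @property
    def total_mismatches(self) -> int:
        return self.left_mismatches + self.spacer_mismatches + self.right_mismatches


def _scan_strand(subject: str, window: str) -> np.ndarray:
    """Mismatch count of `window` at every offset of `subject` (Hamming)."""
    s = np.frombuffer(subject.encode(), dtype=np.uint8)
    w = np.frombuffer(window.encode(), dtype=np.uint8)
    if len(s) < len(w):
        return np.empty(0, dtype=int)
    views = np.lib.stride_tricks.sliding_window_view(s, len(w))
    return (views != w).sum(axis=1)


def pseudospacer_scan(
    pair: EditorPair,
    query: SequenceRecord,
    subjects: Sequence[SequenceRecord],
    max_mismatches: int = 2,
) -> list[PseudoSiteHit]:
    """Scan subjects (both strands) for the TALE-pair footprint.

    The query window is left arm + spacer + right arm extracted from
    the query record.  Hits with total Hamming mismatches up to
    ``max_mismatches`` are returned sorted by mismatch count, subject,
    then coordinate.  Subjects shorter than the window are skipped.
    """
    w_start, w_end = pair.left.start, pair.right.end
    if w_start < 0 or w_end > len(query):
        raise BoundsError("pair footprint outside the query record")
    window = query.seq[w_start:w_end]
    wlen = len(window)
    # offsets of the three segments within the window
    a_left = pair.left.end - w_start
    a_sp_end = pair.right.start - w_start

    def segment(off_in_window: int) -> str:
        if off_in_window < a_left:
            return "left"
        if off_in_window < a_sp_end:
            return "spacer"
        return "right"

    hits: list[PseudoSiteHit] = []
    for subj in subjects:
        L = len(subj)
        if L < wlen:
            continue
        for strand, sseq in (("+", subj.seq), ("-", revcomp(subj.seq))):
            counts = _scan_strand(sseq, window)
            for off in np.flatnonzero(counts <= max_mismatches):
                off = int(off)
                seg_counts = {"left": 0, "spacer": 0, "right": 0}
                mism = []
                for k in range(wlen):
                    if sseq[off + k] != window[k]:
                        seg_counts[segment(k)] += 1
                        if strand == "+":
                            plus_pos = off + k
                            sbase = subj.seq[plus_pos]
                        else:
                            plus_pos = L - (off + k) - 1
                            sbase = subj.seq[plus_pos]
                        mism.append((plus_pos, sbase, window[k]))
                if strand == "+":
                    start, end = off, off + wlen
                    pseudo = (off + a_left, off + a_sp_end)
                else:
                    start, end = L - off - wlen, L - off
                    pseudo = (L - off - a_sp_end, L - off - a_left)
                hits.append(
                    PseudoSiteHit(
                        subject_id=subj.id,
                        start=start,
                        end=end,
                        strand=strand,
                        left_mismatches=seg_counts["left"],
                        spacer_mismatches=seg_counts["spacer"],
                        right_mismatches=seg_counts["right"],
                        pseudospacer=pseudo,
                        mismatch_positions=sorted(mism),
                    )
                )
    hits.sort(key=lambda h: (h.total_mismatches, h.subject_id, h.strand, h.start))
    return hits


def pseudospacer_editing(
    aligned: AlignedReads,
    pseudospacer: tuple[int, int],
    cfg: QuantConfig = QuantConfig(),
) -> tuple[float, dict[int, Optional[float]]]:
    """Overall and per-cytosine editing within a pseudospacer.

    Delegates to the quantifier with the pseudospacer as the region, so
    on- and off-target loci are measured by identical code.
    """
    from .genome_model import region_cytosines

    start, end = pseudospacer
    rec = aligned.ref
    if not (0 <= start < end <= len(rec)):
        raise BoundsError(f"pseudospacer [{start}, {end}) outside amplicon")
    sites = region_cytosines(rec, pseudospacer, index_origin=start)
    ntab, atab = build_tables(aligned, pseudospacer, cfg, sites=sites)
    return overall_on_target(atab, sites), per_cytosine_rates(ntab, sites)


@dataclass
class PrimerProposal:
    """A NUMT-discriminating primer with a 3'-terminal diagnostic base."""

    sequence: str              # 5'->3'
    strand: str                # '+' anneals to bottom strand (forward primer)
    three_prime_pos: int       # mito-record position of the 3' terminal base
    mito_base: str             # mito allele at the discriminating column (top strand)
    homolog_base: str          # homolog allele at that column (top strand)
    ps_bond_count: int
    tm: float
    note: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def order_sheet_sequence(self) -> str:
        """Sequence with '*' marking 3'-terminal phosphorothioate bonds."""
        n = self.ps_bond_count
        if n == 0:
            return self.sequence
        head = self.sequence[: -(n + 1)]
        tail = self.sequence[-(n + 1) :]
        return head + "*".join(tail)


@dataclass(frozen=True)
class PrimerParams:
    length_range: tuple[int, int] = (18, 30)
    tm_range: tuple[float, float] = (55.0, 68.0)
    ps_bond_count: int = 2
    min_identity: float = 0.80


def _global_alignment_columns(a: str, b: str):
    """Aligned (pos_a, pos_b, base_a, base_b) columns and identity."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5
    aln = aligner.align(a, b)[0]
    cols = []
    matches = total = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for i in range(a1 - a0):
            pa, pb = a0 + i, b0 + i
            cols.append((pa, pb, a[pa], b[pb]))
            total += 1
            if a[pa] == b[pb]:
                matches += 1
    # count gap columns into the identity denominator
    gap_cols = (len(a) - total) + (len(b) - total)
    identity = matches / (total + gap_cols) if (total + gap_cols) else 0.0
    return cols, identity


def discriminating_primers(
    mito: SequenceRecord,
    homolog: SequenceRecord,
    params: PrimerParams = PrimerParams(),
) -> list[PrimerProposal]:
    """Propose primers discriminating mtDNA from a nuclear homolog.

    The two records are globally aligned; at every substitution column
    candidate primers are laid on both strands of the *mitochondrial*
    record with their 3' terminus exactly on the mito-specific base, so
    the homolog template presents a 3'-terminal mismatch.  Candidates
    are filtered by length and nearest-neighbor melting temperature
    (default standard conditions) and annotated with ``ps_bond_count``
    3'-terminal phosphorothioate linkages.

    Identical templates yield an empty list (reason: no discriminating
    columns); records under ``min_identity`` raise
    :class:`HomologyError`.
    """
    cols, identity = _global_alignment_columns(mito.seq, homolog.seq)
    if identity < params.min_identity:
        raise HomologyError(
            f"records align at {identity:.1%} identity (< {params.min_identity:.0%}); "
            "not homologous enough to pairwise-align reliably"
        )
    subs = [(pa, pb, ba, bb) for pa, pb, ba, bb in cols if ba != bb]
    lo, hi = params.length_range
    tmin, tmax = params.tm_range
    proposals: list[PrimerProposal] = []
    for pa, pb, mito_base, hom_base in subs:
        for L in range(lo, hi + 1):
            # forward primer: 3' end at pa on the top strand
            if pa - L + 1 >= 0:
                seq = mito.seq[pa - L + 1 : pa + 1]
                tm = MeltingTemp.Tm_NN(seq)
                if tmin <= tm <= tmax:
                    proposals.append(
                        PrimerProposal(
                            sequence=seq,
                            strand="+",
                            three_prime_pos=pa,
                            mito_base=mito_base,
                            homolog_base=hom_base,
                            ps_bond_count=params.ps_bond_count,
                            tm=float(tm),
                            note="nested-PCR orchestration (PCR1/PCR2) left to the bench",
                        )
                    )
            # reverse primer: anneals to top strand, 3' end at pa
            if pa + L <= len(mito):
                seq = revcomp(mito.seq[pa : pa + L])
                tm = MeltingTemp.Tm_NN(seq)
                if tmin <= tm <= tmax:
                    proposals.append(
                        PrimerProposal(
                            sequence=seq,
                            strand="-",
                            three_prime_pos=pa,
                            mito_base=mito_base,
                            homolog_base=hom_base,
                            ps_bond_count=params.ps_bond_count,
                            tm=float(tm),
                            note="nested-PCR orchestration (PCR1/PCR2) left to the bench",
                        )
                    )
    proposals.sort(key=lambda p: (p.three_prime_pos, p.strand, p.length))
    return proposals


def primer_footprint(proposal: PrimerProposal, rec: SequenceRecord) -> str:
    """Extract the primer-covered sequence of ``rec``, primer-oriented.

    On the mitochondrial record this reproduces the primer exactly; on
    the homolog it exposes the engineered 3'-terminal mismatch.
    """
    p = proposal.three_prime_pos
    if proposal.strand == "+":
        return rec.seq[p - proposal.length + 1 : p + 1]
    return revcomp(rec.seq[p : p + proposal.length])
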