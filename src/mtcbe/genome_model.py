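"""Coordinate, strand, and naming conventions for TALE-pair editor targets.

A DddA-derived cytosine base editor (DdCBE) works as a pair of TALE
fusion proteins: the *left* arm binds the top strand, the *right* arm
binds the bottom strand downstream of it, and deamination happens in
the *spacer* between the two binding sites.  Everything downstream of
this module — design enumeration, read simulation, quantification,
specificity metrics — speaks in the types defined here.

Conventions
-----------
* Coordinates are 0-based half-open internally.  Reports emit 1-based
  inclusive coordinates and, when a record carries ``ref_offset``,
  "m."-style positions on the parent reference (e.g. rCRS).
* Sequences are linear.  The circular mitochondrial genome is handled
  by supplying a window with generous flanks; wrap-around arithmetic is
  deliberately not implemented.
* Spacer cytosines are indexed C_k, counting from the 3' end of the
  left TALE binding site (k = 1 is the first spacer position).  Bottom-
  strand cytosines (a G on the top strand) share the same top-strand
  k scale as top-strand cytosines.
* A TALE with an engineered N-terminal domain that accepts any 5' base
  is marked ``ntd="alpha"``; the canonical NTD requires a 5' thymine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Literal, Optional

from .errors import AmbiguousSequenceError, BoundaryError, BoundsError

COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Deaminase variants.  DddAtox is the original split toxin; DddA6 and
#: DddA11 are laboratory-evolved variants, DddA11 with a relaxed
#: TC-dinucleotide context preference.
DEAMINASES = ("DddAtox", "DddA6", "DddA11")

Strand = Literal["top", "bottom"]
Ntd = Literal["canonical", "alpha"]


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return seq.translate(COMPLEMENT)[::-1]


def normalize_seq(seq: str) -> str:
    """Uppercase and validate a nucleotide string.

    Ambiguity codes (N, R, Y, ...) are rejected: every downstream
    operation in this package reasons about exact C/G positions, and a
    guessed base would silently corrupt cytosine censuses.
    """
    s = seq.upper()
    if not s:
        raise AmbiguousSequenceError("empty sequence")
    bad = set(s) - set("ACGT")
    if bad:
        raise AmbiguousSequenceError(
            f"sequence contains non-ACGT characters: {sorted(bad)}; "
            "ambiguity codes are rejected rather than guessed"
        )
    return s


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence, optionally anchored on a parent reference.

    Parameters
    ----------
    id : str
        Record name (FASTA header word).
    seq : str
        Nucleotide sequence over {A, C, G, T}; normalized to uppercase.
    ref_offset : int, optional
        1-based coordinate of ``seq[0]`` in a named parent reference,
        used for "m."-style reporting (e.g. rCRS position of an mtDNA
        amplicon window).
    """

    id: str
    seq: str
    ref_offset: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", normalize_seq(self.seq))
        if self.ref_offset is not None and self.ref_offset < 1:
            raise ValueError("ref_offset is 1-based and must be >= 1")

    def __len__(self) -> int:
        return len(self.seq)

    def ref_position(self, pos0: int) -> Optional[int]:
        """Map a 0-based window position to a 1-based parent coordinate."""
        if self.ref_offset is None:
            return None
        return self.ref_offset + pos0

    def reverse_complement(self, id_suffix: str = "_rc") -> "SequenceRecord":
        return SequenceRecord(self.id + id_suffix, revcomp(self.seq))


@dataclass(frozen=True)
class TaleSite:
    """One TALE binding site.

    ``interval`` is always expressed on the top strand regardless of
    which strand the TALE binds.  The repeat count of the TALE protein
    is the binding-site length minus one half (the half repeat).
    """

    start: int
    end: int
    strand: Strand
    ntd: Ntd = "canonical"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("top", "bottom"):
            raise ValueError(f"strand must be 'top' or 'bottom', got {self.strand!r}")
        if self.ntd not in ("canonical", "alpha"):
            raise ValueError(f"ntd must be 'canonical' or 'alpha', got {self.ntd!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def repeat_count(self) -> float:
        """TALE repeats ~ site length - 0.5 (e.g. 15 bp -> 14.5 repeats)."""
        return (self.end - self.start) - 0.5


@dataclass(frozen=True)
class EditorPair:
    """A dimeric cytosine base editor: two TALE sites plus chemistry.

    The left arm binds the top strand, the right arm the bottom strand;
    deamination is confined to the spacer between them.  ``orientation``
    records which deaminase half goes on which arm: "CN" means left
    TALE carries the C-terminal half and right the N-terminal half.
    """

    left: TaleSite
    right: TaleSite
    deaminase: str = "DddAtox"
    orientation: Literal["CN", "NC"] = "CN"
    split_site: str = "G1397"

    def __post_init__(self) -> None:
        if self.left.strand != "top":
            raise ValueError("left arm must bind the top strand")
        if self.right.strand != "bottom":
            raise ValueError("right arm must bind the bottom strand")
        if self.left.end >= self.right.start:
            raise ValueError(
                "arms must be disjoint with the left arm upstream "
                f"(left end {self.left.end} >= right start {self.right.start})"
            )
        if self.deaminase not in DEAMINASES:
            raise ValueError(f"unknown deaminase {self.deaminase!r}; expected one of {DEAMINASES}")
        if self.orientation not in ("CN", "NC"):
            raise ValueError("orientation must be 'CN' or 'NC'")

    @property
    def spacer(self) -> tuple[int, int]:
        """The spacer interval [left.end, right.start), top-strand coords."""
        return (self.left.end, self.right.start)

    @property
    def spacer_len(self) -> int:
        return self.right.start - self.left.end

    def to_dict(self) -> dict:
        return {
            "left": {"start": self.left.start, "end": self.left.end, "ntd": self.left.ntd},
            "right": {"start": self.right.start, "end": self.right.end, "ntd": self.right.ntd},
            "deaminase": self.deaminase,
            "orientation": self.orientation,
            "split_site": self.split_site,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "EditorPair":
        return cls(
            left=TaleSite(d["left"]["start"], d["left"]["end"], "top", d["left"].get("ntd", "canonical")),
            right=TaleSite(d["right"]["start"], d["right"]["end"], "bottom", d["right"].get("ntd", "canonical")),
            deaminase=d.get("deaminase", "DddAtox"),
            orientation=d.get("orientation", "CN"),
            split_site=d.get("split_site", "G1397"),
        )

    @classmethod
    def from_json(cls, s: str) -> "EditorPair":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class CytosineSite:
    """One editable cytosine inside (or near) a spacer.

    ``c_strand == "bottom"`` means the top-strand base at ``top_pos`` is
    a G and the cytosine sits on the bottom strand.  ``context5`` is the
    base immediately 5' of the cytosine *on the strand carrying it*; a
    TC dinucleotide context is the preferred substrate of DddAtox and
    DddA6.  ``spacer_index`` is the C_k index counted from the 3' end of
    the left TALE arm (k >= 1).
    """

    top_pos: int
    c_strand: Strand
    spacer_index: int
    context5: Optional[str] = None

    def __post_init__(self) -> None:
        if self.c_strand not in ("top", "bottom"):
            raise ValueError("c_strand must be 'top' or 'bottom'")
        if self.spacer_index < 1:
            raise ValueError("spacer_index (C_k) must be >= 1")
        if self.context5 is not None and self.context5 not in "ACGT":
            raise ValueError("context5 must be one of A/C/G/T or None")

    @property
    def is_TC(self) -> bool:
        return self.context5 == "T"

    @property
    def converted_base(self) -> str:
        """Top-strand base observed when this cytosine is deaminated.

        Top-strand C -> T; bottom-strand C -> the top-strand G reads A.
        """
        return "T" if self.c_strand == "top" else "A"

    @property
    def reference_base(self) -> str:
        return "C" if self.c_strand == "top" else "G"


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _check_site_in_record(site: TaleSite, rec: SequenceRecord) -> None:
    if site.start < 0 or site.end > len(rec):
        raise BoundsError(
            f"site [{site.start}, {site.end}) outside record {rec.id!r} of length {len(rec)}"
        )


def five_prime_base(site: TaleSite, rec: SequenceRecord) -> str:
    """The base immediately 5' of a TALE binding site, on its own strand.

    For a top-strand site this is the top-strand base just before the
    interval; for a bottom-strand site it is the complement of the
    top-strand base just after the interval (the bottom strand runs
    3'->5' in top-strand coordinates).

    Raises
    ------
    BoundaryError
        If the site is flush with the window edge, so the 5' base is
        outside the supplied sequence.  This is deliberately an error,
        never a silent "non-compliant" call.
    """
    _check_site_in_record(site, rec)
    if site.strand == "top":
        if site.start < 1:
            raise BoundaryError(
                f"top-strand site at window start has no preceding base in {rec.id!r}"
            )
        return rec.seq[site.start - 1]
    if site.end > len(rec) - 1:
        raise BoundaryError(
            f"bottom-strand site at window end has no preceding base in {rec.id!r}"
        )
    return rec.seq[site.end].translate(COMPLEMENT)


def is_five_prime_T(site: TaleSite, rec: SequenceRecord) -> bool:
    """Whether the site satisfies the canonical TALE 5'-T requirement."""
    return five_prime_base(site, rec) == "T"


def region_cytosines(
    rec: SequenceRecord, region: tuple[int, int], index_origin: Optional[int] = None
) -> list[CytosineSite]:
    """Census of editable cytosines (top-strand C and G) in a region.

    ``index_origin`` defaults to ``region[0]``; C_k is computed as
    ``top_pos - index_origin + 1``.  The 5' context of a cytosine at the
    very window edge is unknowable and reported as None.
    """
    start, end = region
    if start < 0 or end > len(rec):
        raise BoundsError(f"region [{start}, {end}) outside record of length {len(rec)}")
    origin = region[0] if index_origin is None else index_origin
    sites: list[CytosineSite] = []
    for pos in range(start, end):
        base = rec.seq[pos]
        if base == "C":
            ctx = rec.seq[pos - 1] if pos >= 1 else None
            sites.append(CytosineSite(pos, "top", pos - origin + 1, ctx))
        elif base == "G":
            ctx = rec.seq[pos + 1].translate(COMPLEMENT) if pos + 1 < len(rec) else None
            sites.append(CytosineSite(pos, "bottom", pos - origin + 1, ctx))
    return sites


def spacer_cytosines(pair: EditorPair, rec: SequenceRecord) -> list[CytosineSite]:
    """All editable cytosines in a pair's spacer, ordered by position.

    Both strands share one C_k numbering counted from the 3' end of the
    left arm; an empty spacer census is an empty list, not an error.
    """
    _check_site_in_record(pair.left, rec)
    _check_site_in_record(pair.right, rec)
    return region_cytosines(rec, pair.spacer, index_origin=pair.left.end)


def label_pair(pair: EditorPair, rec: SequenceRecord) -> str:
    """N1/N2-style pair label from the arms' 5' bases.

    Each arm is named by the base immediately 5' of its binding site and
    its position in the pair (1 = left, 2 = right), with an "α" prefix
    when the arm carries the unconstrained NTD.  Examples: "T1-T2"
    (5'-T-compliant canonical pair), "αC1-αA2", "αA1-T2".
    """
    tokens = []
    for arm, idx in ((pair.left, 1), (pair.right, 2)):
        base = five_prime_base(arm, rec)
        prefix = "α" if arm.ntd == "alpha" else ""
        tokens.append(f"{prefix}{base}{idx}")
    return "-".join(tokens)
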