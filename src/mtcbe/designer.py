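"""Enumeration and annotation of candidate editor-pair designs.

Given a target window, this module enumerates every geometrically valid
TALE pair (site lengths 15–17 bp, spacers 11–18 bp by default), under a
chosen NTD policy:

``canonical``
    both arms use the wild-type NTD and must satisfy the 5'-T rule;
``alpha``
    both arms use the unconstrained NTD — any 5' base is allowed;
``alpha_left`` / ``alpha_right``
    one arm unconstrained, the other canonical (5'-T required);
``both_enumerated``
    every geometry is emitted in all four NTD combinations with per-arm
    compliance flags and no 5'-T filtering, mirroring experiments that
    deliberately include 5'-T-noncompliant canonical pairs.

It also implements TALE shifting (all designs whose spacer covers one
fixed target cytosine), spacer-preserving arm trimming (moving each
arm's 5' end by up to ±2 bp while both 3' ends, hence the spacer, stay
fixed), and a per-position accessibility census that counts canonical
vs unconstrained designs covering each C/G.

The ranking score is an explicit heuristic for ordering candidate
designs, not a validated activity predictor; raw annotations are always
emitted alongside it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import BoundaryError, BoundsError, InvalidTargetError
from .genome_model import (
    CytosineSite,
    EditorPair,
    SequenceRecord,
    TaleSite,
    five_prime_base,
    is_five_prime_T,
    label_pair,
    spacer_cytosines,
)

NTD_POLICIES = ("canonical", "alpha", "alpha_left", "alpha_right", "both_enumerated")


@dataclass(frozen=True)
class DesignConstraints:
    """Geometric and chemical constraints on editor-pair design.

    Defaults follow standard dimeric design practice: binding sites of
    15–17 bp (14.5–16.5 TALE repeats) separated by 11–18 bp spacers,
    with up to 2 bp of 5'-end trimming when generating spacer-preserving
    variants.
    """

    site_len_range: tuple[int, int] = (15, 17)
    spacer_len_range: tuple[int, int] = (11, 18)
    ntd_policy: str = "alpha"
    max_5prime_trim: int = 2
    require_target_in_spacer: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.site_len_range
        if not (8 <= lo <= hi <= 20):
            raise ValueError(f"site_len_range {self.site_len_range} outside sanity bound [8, 20]")
        slo, shi = self.spacer_len_range
        if not (1 <= slo <= shi):
            raise ValueError(f"invalid spacer_len_range {self.spacer_len_range}")
        if self.ntd_policy not in NTD_POLICIES:
            raise ValueError(f"ntd_policy must be one of {NTD_POLICIES}")
        if self.max_5prime_trim < 0:
            raise ValueError("max_5prime_trim must be >= 0")


@dataclass(frozen=True)
class ScoreWeights:
    """Weights of the additive design-ranking heuristic (rank only)."""

    center: float = 1.0      # target near spacer center
    tc_context: float = 1.0  # target in TC context (waived for DddA11)
    bystander: float = 0.25  # penalty per bystander cytosine
    short_spacer: float = 0.5  # bonus for spacers <= 16 bp


@dataclass(frozen=True)
class ArmCompliance:
    base: str
    is_T: bool


@dataclass
class DesignAnnotation:
    """One candidate pair with its design-relevant annotations."""

    pair: EditorPair
    label: str
    spacer_len: int
    sites: list[CytosineSite]
    target_index: Optional[int]
    bystander_count: int
    target_is_TC: Optional[bool]
    compliance: dict[str, ArmCompliance]
    score: float

    def row(self) -> dict:
        return {
            "label": self.label,
            "left_start": self.pair.left.start,
            "left_end": self.pair.left.end,
            "left_ntd": self.pair.left.ntd,
            "right_start": self.pair.right.start,
            "right_end": self.pair.right.end,
            "right_ntd": self.pair.right.ntd,
            "spacer_start": self.pair.spacer[0],
            "spacer_end": self.pair.spacer[1],
            "spacer_len": self.spacer_len,
            "deaminase": self.pair.deaminase,
            "n_spacer_cytosines": len(self.sites),
            "target_index": self.target_index,
            "target_is_TC": self.target_is_TC,
            "bystander_count": self.bystander_count,
            "left_5prime": self.compliance["left"].base,
            "right_5prime": self.compliance["right"].base,
            "canonical_compliant": self.compliance["left"].is_T and self.compliance["right"].is_T,
            "score": self.score,
        }


@dataclass
class DesignResult(Sequence):
    """Designs plus a structured summary of rejected candidates."""

    designs: list[DesignAnnotation] = field(default_factory=list)
    rejections: Counter = field(default_factory=Counter)

    def __len__(self) -> int:
        return len(self.designs)

    def __getitem__(self, i):
        return self.designs[i]

    def __iter__(self) -> Iterator[DesignAnnotation]:
        return iter(self.designs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([d.row() for d in self.designs])


def _geometries(seq_len: int, c: DesignConstraints) -> Iterator[tuple[int, int, int, int]]:
    """All (left_start, left_end, right_start, right_end) candidates.

    Left start >= 1 and right end <= L-1 so both arms have a readable
    5' base; yielded in the deterministic order (left start, left len,
    right start, right len).
    """
    lo, hi = c.site_len_range
    slo, shi = c.spacer_len_range
    for ls in range(1, seq_len):
        for llen in range(lo, hi + 1):
            le = ls + llen
            if le >= seq_len:
                break
            for spacer in range(slo, shi + 1):
                rs = le + spacer
                for rlen in range(lo, hi + 1):
                    re = rs + rlen
                    if re > seq_len - 1:
                        break
                    yield ls, le, rs, re


def _ntd_combos(policy: str) -> list[tuple[str, str]]:
    if policy == "canonical":
        return [("canonical", "canonical")]
    if policy == "alpha":
        return [("alpha", "alpha")]
    if policy == "alpha_left":
        return [("alpha", "canonical")]
    if policy == "alpha_right":
        return [("canonical", "alpha")]
    return [
        ("canonical", "canonical"),
        ("alpha", "alpha"),
        ("alpha", "canonical"),
        ("canonical", "alpha"),
    ]


def _score(
    ann_sites: list[CytosineSite],
    target_index: Optional[int],
    target_is_TC: Optional[bool],
    spacer_len: int,
    bystander_count: int,
    deaminase: str,
    w: ScoreWeights,
) -> float:
    score = -w.bystander * bystander_count
    if spacer_len <= 16:
        score += w.short_spacer
    if target_index is not None:
        mid = (spacer_len + 1) / 2.0
        half = max((spacer_len - 1) / 2.0, 1.0)
        score += w.center * (1.0 - abs(target_index - mid) / half)
        if deaminase == "DddA11" or target_is_TC:
            score += w.tc_context
    return score


def enumerate_pairs(
    rec: SequenceRecord,
    c: DesignConstraints,
    target: Optional[int] = None,
    deaminase: str = "DddAtox",
    weights: ScoreWeights = ScoreWeights(),
) -> DesignResult:
    """Exhaustively enumerate valid editor pairs on a record.

    Every (left site, right site) combination satisfying site-length,
    spacer-length, boundary (readable 5' base on both arms), NTD-policy
    and target-containment constraints is returned, in deterministic
    order (left start, left length, right start, right length, NTD
    combination).  When no design is valid the result is empty and the
    ``rejections`` counter explains what was filtered.
    """
    result = DesignResult()
    seq = rec.seq
    min_len = 2 * c.site_len_range[0] + c.spacer_len_range[0] + 2
    if len(seq) < min_len:
        result.rejections["record_too_short"] += 1
        return result
    for ls, le, rs, re in _geometries(len(seq), c):
        if target is not None and c.require_target_in_spacer and not (le <= target < rs):
            result.rejections["target_not_in_spacer"] += 1
            continue
        left_5p = seq[ls - 1]
        right_5p = seq[re].translate(_COMPL)
        for lntd, rntd in _ntd_combos(c.ntd_policy):
            if lntd == "canonical" and c.ntd_policy != "both_enumerated" and left_5p != "T":
                result.rejections["left_5prime_not_T"] += 1
                continue
            if rntd == "canonical" and c.ntd_policy != "both_enumerated" and right_5p != "T":
                result.rejections["right_5prime_not_T"] += 1
                continue
            pair = EditorPair(
                TaleSite(ls, le, "top", lntd),
                TaleSite(rs, re, "bottom", rntd),
                deaminase=deaminase,
            )
            result.designs.append(_annotate(pair, rec, target, weights))
    return result


_COMPL = str.maketrans("ACGT", "TGCA")


def _annotate(
    pair: EditorPair,
    rec: SequenceRecord,
    target: Optional[int],
    weights: ScoreWeights,
) -> DesignAnnotation:
    sites = spacer_cytosines(pair, rec)
    target_index = None
    target_is_TC = None
    if target is not None:
        for s in sites:
            if s.top_pos == target:
                target_index = s.spacer_index
                target_is_TC = s.is_TC
                break
    bystanders = len(sites) - (1 if target_index is not None else 0)
    compliance = {
        "left": ArmCompliance(five_prime_base(pair.left, rec), is_five_prime_T(pair.left, rec)),
        "right": ArmCompliance(five_prime_base(pair.right, rec), is_five_prime_T(pair.right, rec)),
    }
    score = _score(
        sites, target_index, target_is_TC, pair.spacer_len, bystanders, pair.deaminase, weights
    )
    return DesignAnnotation(
        pair=pair,
        label=label_pair(pair, rec),
        spacer_len=pair.spacer_len,
        sites=sites,
        target_index=target_index,
        bystander_count=bystanders,
        target_is_TC=target_is_TC,
        compliance=compliance,
        score=score,
    )


def tale_shift(
    rec: SequenceRecord,
    target: int,
    c: DesignConstraints,
    deaminase: str = "DddAtox",
    weights: ScoreWeights = ScoreWeights(),
) -> DesignResult:
    """All designs accessing one target cytosine via alternative TALE pairs.

    TALE shifting fixes the target base and varies the flanking TALE
    sites, hence the spacer; each candidate is annotated with its C_k
    target index, bystander count, context, and per-arm compliance, and
    ranked by score (ties broken by the deterministic enumeration key).
    """
    if not (0 <= target < len(rec)):
        raise BoundsError(f"target {target} outside record of length {len(rec)}")
    if rec.seq[target] not in "CG":
        raise InvalidTargetError(
            f"target base {rec.seq[target]!r} at {target} is not an editable cytosine (C or G)"
        )
    c = replace(c, require_target_in_spacer=True)
    result = enumerate_pairs(rec, c, target=target, deaminase=deaminase, weights=weights)
    order = {id(d): i for i, d in enumerate(result.designs)}
    result.designs.sort(key=lambda d: (-d.score, order[id(d)]))
    return result


def spacer_preserving_variants(
    pair: EditorPair, rec: SequenceRecord, c: DesignConstraints
) -> list[EditorPair]:
    """Variant pairs with the same spacer, arms trimmed/extended at 5' ends.

    Each arm's 5' end moves by up to ``max_5prime_trim`` bp in either
    direction while both 3' ends — and therefore the spacer sequence —
    stay fixed.  Variants whose site length leaves the allowed range or
    whose 5' base becomes unreadable are silently filtered.  The input
    pair is always included.
    """
    lo, hi = c.site_len_range
    t = c.max_5prime_trim
    left_starts = [
        s
        for d in range(-t, t + 1)
        if (s := pair.left.start + d) >= 1 and lo <= pair.left.end - s <= hi
    ]
    right_ends = [
        e
        for d in range(-t, t + 1)
        if (e := pair.right.end + d) <= len(rec) - 1 and lo <= e - pair.right.start <= hi
    ]
    variants = []
    for ls in left_starts:
        for re_ in right_ends:
            variants.append(
                EditorPair(
                    TaleSite(ls, pair.left.end, "top", pair.left.ntd),
                    TaleSite(pair.right.start, re_, "bottom", pair.right.ntd),
                    deaminase=pair.deaminase,
                    orientation=pair.orientation,
                    split_site=pair.split_site,
                )
            )
    return variants


def count_canonical_accessible(
    rec: SequenceRecord, c: DesignConstraints
) -> tuple[pd.DataFrame, int]:
    """Per-C/G-position design accessibility census.

    For every C or G position, counts the valid canonical designs and
    the valid unconstrained (alpha) designs whose spacer covers it.
    Returns the table and the number of positions reachable only by
    unconstrained designs (zero canonical, >= 1 alpha) — the positions
    the 5'-T rule locks out.
    """
    n = len(rec)
    canon = np.zeros(n, dtype=int)
    alpha = np.zeros(n, dtype=int)
    seq = rec.seq
    for ls, le, rs, re in _geometries(n, c):
        alpha[le:rs] += 1
        if seq[ls - 1] == "T" and seq[re] == "A":  # bottom-strand 5'-T = top-strand A
            canon[le:rs] += 1
    rows = []
    for pos in range(n):
        if seq[pos] in "CG":
            rows.append(
                {
                    "position": pos,
                    "base": seq[pos],
                    "n_canonical": int(canon[pos]),
                    "n_alpha": int(alpha[pos]),
                }
            )
    df = pd.DataFrame(rows)
    alpha_only = int(((df["n_canonical"] == 0) & (df["n_alpha"] > 0)).sum()) if len(df) else 0
    return df, alpha_only
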