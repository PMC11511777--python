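"""Design enumeration, TALE shifting, trimming, accessibility census."""

import numpy as np
import pytest

from mtcbe.designer import (
    DesignConstraints,
    count_canonical_accessible,
    enumerate_pairs,
    spacer_preserving_variants,
    tale_shift,
)
from mtcbe.errors import InvalidTargetError
from mtcbe.genome_model import EditorPair, SequenceRecord, TaleSite
from mtcbe.simulator import random_amplicon


def naive_enumeration(seq: str, c: DesignConstraints, target=None):
    """Independent quadratic oracle: every geometry checked from scratch.

    Returns the set of (left_start, left_end, right_start, right_end,
    left_ntd, right_ntd) tuples that satisfy the constraints.
    """
    compl = {"A": "T", "C": "G", "G": "C", "T": "A"}
    lo, hi = c.site_len_range
    slo, shi = c.spacer_len_range
    combos = {
        "canonical": [("canonical", "canonical")],
        "alpha": [("alpha", "alpha")],
        "alpha_left": [("alpha", "canonical")],
        "alpha_right": [("canonical", "alpha")],
        "both_enumerated": [
            ("canonical", "canonical"),
            ("alpha", "alpha"),
            ("alpha", "canonical"),
            ("canonical", "alpha"),
        ],
    }[c.ntd_policy]
    out = set()
    n = len(seq)
    for ls in range(n):
        for le in range(ls + 1, n + 1):
            if not lo <= le - ls <= hi or ls < 1:
                continue
            for rs in range(le + 1, n):
                if not slo <= rs - le <= shi:
                    continue
                for re in range(rs + 1, n):
                    if not lo <= re - rs <= hi or re > n - 1:
                        continue
                    if target is not None and not le <= target < rs:
                        continue
                    for lntd, rntd in combos:
                        if c.ntd_policy != "both_enumerated":
                            if lntd == "canonical" and seq[ls - 1] != "T":
                                continue
                            if rntd == "canonical" and compl[seq[re]] != "T":
                                continue
                        out.add((ls, le, rs, re, lntd, rntd))
    return out


def design_keys(result):
    return {
        (
            d.pair.left.start,
            d.pair.left.end,
            d.pair.right.start,
            d.pair.right.end,
            d.pair.left.ntd,
            d.pair.right.ntd,
        )
        for d in result
    }


class TestEnumeration:
    @pytest.mark.parametrize("policy", ["canonical", "alpha", "alpha_left", "both_enumerated"])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_naive_oracle(self, policy, seed):
        rec = random_amplicon(70, seed=seed)
        c = DesignConstraints(ntd_policy=policy, require_target_in_spacer=False)
        result = enumerate_pairs(rec, c)
        keys = design_keys(result)
        assert len(keys) == len(result), "duplicate designs emitted"
        assert keys == naive_enumeration(rec.seq, c)

    def test_all_cg_sequence_has_no_canonical_designs(self):
        rec = SequenceRecord("cg", "CG" * 40)
        canonical = enumerate_pairs(rec, DesignConstraints(ntd_policy="canonical"))
        alpha = enumerate_pairs(rec, DesignConstraints(ntd_policy="alpha"))
        assert len(canonical) == 0
        assert canonical.rejections  # structured reasons, not a bare empty list
        assert len(alpha) > 0

    def test_canonical_is_subset_of_alpha_geometries(self):
        rec = random_amplicon(90, seed=5)
        canon = enumerate_pairs(rec, DesignConstraints(ntd_policy="canonical"))
        alpha = enumerate_pairs(rec, DesignConstraints(ntd_policy="alpha"))
        geom = lambda res: {
            (d.pair.left.start, d.pair.left.end, d.pair.right.start, d.pair.right.end)
            for d in res
        }
        assert geom(canon) <= geom(alpha)

    def test_deterministic_order(self):
        rec = random_amplicon(80, seed=7)
        c = DesignConstraints(ntd_policy="alpha")
        a = [d.pair for d in enumerate_pairs(rec, c)]
        b = [d.pair for d in enumerate_pairs(rec, c)]
        assert a == b

    def test_degenerate_short_record_gives_reasoned_empty(self):
        rec = SequenceRecord("tiny", "ACGTACGTAC")
        result = enumerate_pairs(rec, DesignConstraints())
        assert len(result) == 0
        assert result.rejections["record_too_short"] == 1

    def test_flank_invariance(self):
        """Designs are unchanged by flanking sequence beyond reach."""
        core = random_amplicon(80, seed=9).seq
        c = DesignConstraints(ntd_policy="alpha", require_target_in_spacer=False)
        base = naive_enumeration(core, c)
        rec2 = SequenceRecord("padded", "T" + core + "A")
        shifted = {
            (ls - 1, le - 1, rs - 1, re - 1, a, b)
            for ls, le, rs, re, a, b in design_keys(enumerate_pairs(rec2, c))
            # keep only designs fully inside the original core's valid zone
            if ls - 1 >= 1 and re - 1 <= len(core) - 1
        }
        assert base <= shifted


class TestTaleShift:
    def test_every_spacer_contains_target(self):
        rec = random_amplicon(100, seed=3)
        target = next(i for i in range(45, 60) if rec.seq[i] in "CG")
        result = tale_shift(rec, target, DesignConstraints(ntd_policy="alpha"))
        assert len(result) > 0
        for d in result:
            start, end = d.pair.spacer
            assert start <= target < end
            assert d.target_index == target - start + 1

    def test_rows_sorted_by_score(self):
        rec = random_amplicon(100, seed=3)
        target = next(i for i in range(45, 60) if rec.seq[i] in "CG")
        scores = [d.score for d in tale_shift(rec, target, DesignConstraints(ntd_policy="alpha"))]
        assert scores == sorted(scores, reverse=True)

    def test_non_cytosine_target_rejected(self):
        rec = SequenceRecord("x", "A" * 50 + "T" + "A" * 49)
        with pytest.raises(InvalidTargetError):
            tale_shift(rec, 50, DesignConstraints())

    def test_planted_single_upstream_t_constrains_canonical_designs(self):
        """With exactly one T on the top strand, canonical designs can
        only place their left arm right after it."""
        seq = list("A" * 100)
        seq[20] = "T"
        seq[55] = "C"  # the target
        # right-arm 5'-T needs a top-strand A: everywhere satisfied
        rec = SequenceRecord("planted", "".join(seq))
        res = tale_shift(rec, 55, DesignConstraints(ntd_policy="canonical"))
        assert len(res) > 0
        for d in res:
            assert d.pair.left.start == 21

    def test_narrow_spacer_range_never_worsens_best_bystander_count(self):
        for seed in (1, 2, 3):
            rec = random_amplicon(120, seed=seed)
            target = next(i for i in range(55, 70) if rec.seq[i] in "CG")
            wide = tale_shift(rec, target, DesignConstraints(ntd_policy="alpha"))
            narrow = tale_shift(
                rec, target, DesignConstraints(ntd_policy="alpha", spacer_len_range=(11, 12))
            )
            if len(narrow) and len(wide):
                assert (
                    min(d.bystander_count for d in narrow)
                    >= min(d.bystander_count for d in wide) - 0
                )
                # narrow range is a subset of wide, so its best cannot beat wide's best
                assert min(d.bystander_count for d in wide) <= min(
                    d.bystander_count for d in narrow
                )


class TestSpacerPreservingVariants:
    def _pair(self):
        return EditorPair(TaleSite(20, 36, "top"), TaleSite(50, 66, "bottom"))

    def test_at_most_nine_variants_sharing_one_spacer(self):
        rec = random_amplicon(120, seed=4)
        pair = self._pair()
        variants = spacer_preserving_variants(pair, rec, DesignConstraints())
        assert 1 <= len(variants) <= 9
        assert len(variants) == 9  # 16-nt arms, range 15-17, trim 2
        assert {v.spacer for v in variants} == {pair.spacer}
        assert pair in variants

    def test_trim_zero_is_identity(self):
        rec = random_amplicon(120, seed=4)
        pair = self._pair()
        assert spacer_preserving_variants(
            pair, rec, DesignConstraints(max_5prime_trim=0)
        ) == [pair]

    def test_variants_respect_site_length_range(self):
        rec = random_amplicon(120, seed=4)
        for v in spacer_preserving_variants(self._pair(), rec, DesignConstraints()):
            assert 15 <= len(v.left) <= 17
            assert 15 <= len(v.right) <= 17


class TestAccessibilityCensus:
    def test_poly_g_has_zero_canonical_everywhere(self):
        rec = SequenceRecord("gg", "G" * 100)
        df, alpha_only = count_canonical_accessible(rec, DesignConstraints())
        assert (df["n_canonical"] == 0).all()
        assert (df["n_alpha"] > 0).any()
        assert alpha_only == (df["n_alpha"] > 0).sum()

    def test_alpha_count_dominates_canonical(self):
        rec = random_amplicon(150, seed=6)
        df, _ = count_canonical_accessible(rec, DesignConstraints())
        assert (df["n_alpha"] >= df["n_canonical"]).all()

    def test_counts_match_per_position_enumeration(self):
        rec = random_amplicon(90, seed=8)
        c = DesignConstraints()
        df, _ = count_canonical_accessible(rec, c)
        for _, row in df.iterrows():
            pos = row["position"]
            for policy, col in (("canonical", "n_canonical"), ("alpha", "n_alpha")):
                oracle = naive_enumeration(
                    rec.seq,
                    DesignConstraints(ntd_policy=policy, require_target_in_spacer=True),
                    target=pos,
                )
                assert len(oracle) == row[col], (pos, policy)
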