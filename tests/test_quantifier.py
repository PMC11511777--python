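"""Read alignment, table construction, and on-target statistics."""

import numpy as np
import pandas as pd
import pytest

from mtcbe.errors import BarcodeConfigError, BoundsError
from mtcbe.genome_model import EditorPair, SequenceRecord, TaleSite, spacer_cytosines
from mtcbe.io import Read
from mtcbe.quantifier import (
    AlignedReads,
    QuantConfig,
    align_reads,
    build_tables,
    demultiplex,
    merge_read_pair,
    overall_on_target,
    parity_window,
    per_cytosine_rates,
    quantify,
)
from mtcbe.simulator import SimulationParams, build_truth, random_amplicon, simulate_reads


def mk_reads(seqs):
    return [Read(f"r{i}", s, "I" * len(s)) for i, s in enumerate(seqs)]


class TestDemultiplex:
    def test_exact_prefix_assignment_and_stripping(self):
        bmap = {"AAAA": "s1", "TTTT": "s2"}
        reads = mk_reads(["AAAA" + "CGCG"] * 10 + ["TTTT" + "GCGC"] * 10)
        res = demultiplex(reads, bmap)
        assert len(res.by_sample["s1"]) == 10 and len(res.by_sample["s2"]) == 10
        assert res.n_unassigned == 0
        assert all(r.seq == "CGCG" for r in res.by_sample["s1"])

    def test_unmatched_barcode_is_unassigned(self):
        res = demultiplex(mk_reads(["GGGGACGT"]), {"AAAA": "s1", "TTTT": "s2"})
        assert res.n_unassigned == 1

    def test_colliding_barcodes_rejected(self):
        with pytest.raises(BarcodeConfigError):
            demultiplex([], {"AAAA": "s1", "AAAT": "s2"})

    def test_unequal_lengths_rejected(self):
        with pytest.raises(BarcodeConfigError):
            demultiplex([], {"AAAA": "s1", "TTTTT": "s2"})


class TestAlignment:
    def test_identical_read_full_identity(self, amplicon):
        out = align_reads(mk_reads([amplicon.seq]), amplicon)
        assert out.n_aligned == 1 and out.n_discarded == 0
        assert out.calls[0] == amplicon.seq

    def test_single_substitution_single_mismatch_column(self, amplicon):
        s = list(amplicon.seq)
        pos = amplicon.seq.index("C")
        s[pos] = "T"
        out = align_reads(mk_reads(["".join(s)]), amplicon)
        diffs = [i for i, (a, b) in enumerate(zip(out.calls[0], amplicon.seq)) if a != b]
        assert diffs == [pos]

    def test_low_identity_read_discarded(self, amplicon):
        junk = "A" * len(amplicon)
        out = align_reads(mk_reads([junk]), amplicon)
        # a poly-A read against a mixed-composition amplicon sits far
        # below the 0.80 default identity
        assert out.n_discarded == 1 and out.n_aligned == 0

    def test_deletion_produces_del_calls(self, amplicon):
        s = amplicon.seq[:100] + amplicon.seq[103:]
        out = align_reads(mk_reads([s]), amplicon)
        assert out.n_aligned == 1
        assert out.calls[0].count("-") == 3


class TestMergePairs:
    def test_perfect_overlap_reconstructs_amplicon(self):
        from mtcbe.genome_model import revcomp

        amp = random_amplicon(100, seed=5).seq
        r1 = Read("m/1", amp[:70], "I" * 70)
        r2 = Read("m/2", revcomp(amp[40:]), "I" * 60)
        merged = merge_read_pair(r1, r2)
        assert merged.seq == amp

    def test_disagreement_takes_higher_quality_base(self):
        r1 = Read("a/1", "ACGTACGTACGT", "IIIIIIIIIIII")
        seq2 = "ACGTACGTACGT"
        from mtcbe.genome_model import revcomp

        mutated = "ACGTACTTACGT"  # position 6 G->T
        r2 = Read("a/2", revcomp(mutated), "JJJJJJJJJJJJ")  # higher quality
        merged = merge_read_pair(r1, r2, min_overlap=12)
        assert merged.seq[6] == "T"

    def test_quality_tie_yields_n(self):
        from mtcbe.genome_model import revcomp

        r1 = Read("a/1", "ACGTACGTACGT", "IIIIIIIIIIII")
        r2 = Read("a/2", revcomp("ACGTACTTACGT"), "IIIIIIIIIIII")
        merged = merge_read_pair(r1, r2, min_overlap=12)
        assert merged.seq[6] == "N"


class TestTables:
    def _toy(self):
        # 40-nt reference; spacer [20, 26) contains a C at 21 and a G at 24
        seq = "T" * 20 + "ACATGA" + "T" * 14
        rec = SequenceRecord("toy", seq)
        pair = EditorPair(TaleSite(5, 20, "top"), TaleSite(26, 40 - 1, "bottom"))
        return rec, pair

    def test_allele_fraction_from_counting(self):
        rec, pair = self._toy()
        edited = rec.seq[:21] + "T" + rec.seq[22:]  # C->T at 21
        reads = mk_reads([rec.seq] * 7 + [edited] * 3)
        aligned = align_reads(reads, rec)
        _, atab = build_tables(aligned, pair)
        frac = dict(zip(atab.df["allele"], atab.df["fraction"]))
        assert frac[edited[20:26]] == pytest.approx(0.3)
        assert overall_on_target(atab) == pytest.approx(30.0)

    def test_row_sums_equal_coverage(self, amplicon, pair):
        truth = build_truth(amplicon, pair, SimulationParams(n_reads=300, seed=3))
        sim = simulate_reads(truth)
        aligned, ntab, atab, _, _ = quantify(sim.reads, amplicon, pair)
        sums = ntab.counts[["A", "C", "G", "T", "del"]].sum(axis=1)
        assert (sums == ntab.counts["coverage"]).all()
        assert atab.df["count"].sum() == aligned.n_aligned
        assert atab.df["fraction"].sum() == pytest.approx(1.0)

    def test_spacer_outside_amplicon_is_bounds_error(self, amplicon):
        aligned = align_reads(mk_reads([amplicon.seq]), amplicon)
        with pytest.raises(BoundsError):
            build_tables(aligned, (10, len(amplicon) + 5))

    def test_parity_window_semantics(self):
        # spacer [20, 34), window size 10 centered -10 from the 3' end
        assert parity_window((20, 34), 10, -10, 200) == (24, 34)
        assert parity_window((20, 34), 8, -8, 200) == (26, 34)


class TestRates:
    def test_per_cytosine_percentages(self):
        seq = "T" * 20 + "ACATGA" + "T" * 14
        rec = SequenceRecord("toy", seq)
        pair = EditorPair(TaleSite(5, 20, "top"), TaleSite(26, 39, "bottom"))
        sites = spacer_cytosines(pair, rec)
        edited_c = rec.seq[:21] + "T" + rec.seq[22:]
        edited_g = rec.seq[:24] + "A" + rec.seq[25:]
        reads = mk_reads([rec.seq] * 65 + [edited_c] * 25 + [edited_g] * 10)
        aligned = align_reads(reads, rec)
        ntab, _ = build_tables(aligned, pair, sites=sites)
        rates = per_cytosine_rates(ntab, sites)
        by_strand = {s.c_strand: rates[s.spacer_index] for s in sites}
        assert by_strand["top"] == pytest.approx(25.0)
        assert by_strand["bottom"] == pytest.approx(10.0)

    def test_zero_coverage_reports_missing(self, amplicon, pair):
        aligned = AlignedReads(amplicon)  # no reads
        sites = spacer_cytosines(pair, amplicon)
        ntab, _ = build_tables(aligned, pair, sites=sites)
        rates = per_cytosine_rates(ntab, sites)
        assert all(v is None for v in rates.values())


class TestMixtureSemantics:
    def test_cooccurring_edits_counted_once_per_read(self):
        """f=0.5 with two certain sites: overall on-target ~50%, not 75%."""
        seq = "T" * 20 + "TCTTCA" + "T" * 30 + "A"
        rec = SequenceRecord("two_site", seq)
        pair = EditorPair(TaleSite(5, 20, "top"), TaleSite(26, 42, "bottom"))
        truth = build_truth(
            rec, pair,
            SimulationParams(f=0.5, q0=1.0, m_tc=1.0, m_nontc=1.0, b=0.0, e=0.0,
                             n_reads=4000, seed=9),
        )
        assert len(truth.sites) == 2
        sim = simulate_reads(truth)
        _, _, atab, _, on = quantify(sim.reads, rec, pair)
        se = 100 * np.sqrt(0.25 / 4000)
        assert abs(on - 50.0) <= 3 * se

    def test_pipeline_equals_truth_sidecar_when_error_free(self, amplicon, pair):
        truth = build_truth(
            amplicon, pair,
            SimulationParams(f=0.4, q0=0.6, b=0.01, e=0.0, n_reads=800, seed=5),
        )
        sim = simulate_reads(truth)
        aligned, ntab, atab, _, _ = quantify(sim.reads, amplicon, pair)
        # nucleotide counts: direct count of the truth base matrix
        mat = sim.truth_base_matrix()
        for sym, byte in (("A", 65), ("C", 67), ("G", 71), ("T", 84)):
            np.testing.assert_array_equal(
                ntab.counts[sym].to_numpy(), (mat == byte).sum(axis=0)
            )
        # allele table: direct count of truth spacer substrings
        oracle = sim.truth_spacer_alleles().set_index("allele")["count"]
        got = atab.df.set_index("allele")["count"]
        assert got.sort_index().equals(oracle.sort_index())

    def test_on_target_bounds_per_site_rates_without_indels(self, amplicon, pair):
        truth = build_truth(
            amplicon, pair, SimulationParams(f=0.5, q0=0.5, e=0.0, n_reads=1000, seed=2)
        )
        sim = simulate_reads(truth)
        cfg = QuantConfig(include_indel_reads_in_denominator=False)
        _, ntab, atab, rates, on = quantify(sim.reads, amplicon, pair, cfg)
        for v in rates.values():
            if v is not None:
                assert on >= v - 1e-9

    def test_read_order_invariance(self, amplicon, pair, rng):
        truth = build_truth(amplicon, pair, SimulationParams(n_reads=200, seed=8))
        sim = simulate_reads(truth)
        shuffled = list(sim.reads)
        rng.shuffle(shuffled)
        _, n1, a1, r1, on1 = quantify(sim.reads, amplicon, pair)
        _, n2, a2, r2, on2 = quantify(shuffled, amplicon, pair)
        assert on1 == on2 and r1 == r2
        pd.testing.assert_frame_equal(n1.counts, n2.counts)
        pd.testing.assert_frame_equal(
            a1.df.sort_values("allele").reset_index(drop=True),
            a2.df.sort_values("allele").reset_index(drop=True),
        )
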