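"""Positional SNP classification, densities, enrichment, and CpG loss."""

import pytest
from hypothesis import given, strategies as st

from splicescope.core_io import Gene, GenomeAnnotation, SnpRecord, Transcript, write_fasta
from splicescope.snp_context import (
    CATEGORIES,
    CAT_EXONIC,
    CAT_INTRONIC_DOWN,
    CAT_INTRONIC_UP,
    CAT_OUTSIDE,
    CAT_SS3,
    CAT_SS5,
    classify_snp_position,
    count_cpg_loss,
    enrichment_chi2,
    per_event_snp_counts,
    snp_density_per_kb,
)
from splicescope.splice_quant import SpliceEvent

EXON = (5000, 5100)  # 100-nt exon


def snp_at(pos0, chrom="c", ref="A", alt="G"):
    return SnpRecord(chrom, pos0 + 1, ref, alt)


def classify(pos0, strand="+", chrom="c"):
    return classify_snp_position(snp_at(pos0), EXON, strand, chrom=chrom)


class TestClassifySnpPosition:
    @pytest.mark.parametrize(
        "pos0,expected",
        [
            (5000 - 10, CAT_SS3),          # 10 nt into the upstream intron
            (5000 - 100, CAT_INTRONIC_UP),  # 15 < 100 <= 500
            (5000 - 500, CAT_INTRONIC_UP),
            (5000 - 501, CAT_OUTSIDE),
            (5050, CAT_EXONIC),             # exon interior
            (5005, CAT_SS3),                # exonic side of the acceptor
            (5099 - 5, CAT_SS5),            # exonic side of the donor
            (5099 + 3, CAT_SS5),            # donor +3
            (5099 + 200, CAT_INTRONIC_DOWN),
        ],
    )
    def test_plus_strand_windows(self, pos0, expected):
        assert classify(pos0) == expected

    @pytest.mark.parametrize(
        "pos0,plus_cat,minus_cat",
        [
            (5000 - 10, CAT_SS3, CAT_SS5),
            (5000 - 100, CAT_INTRONIC_UP, CAT_INTRONIC_DOWN),
            (5099 + 3, CAT_SS5, CAT_SS3),
            (5099 + 200, CAT_INTRONIC_DOWN, CAT_INTRONIC_UP),
        ],
    )
    def test_minus_strand_flips_sides(self, pos0, plus_cat, minus_cat):
        assert classify(pos0, "+") == plus_cat
        assert classify(pos0, "-") == minus_cat

    def test_exonic_symmetric_on_strand(self):
        assert classify(5050, "+") == classify(5050, "-") == CAT_EXONIC

    def test_other_chromosome_is_outside(self):
        assert (
            classify_snp_position(snp_at(5050, chrom="other"), EXON, "+", chrom="c")
            == CAT_OUTSIDE
        )

    @given(st.integers(min_value=4000, max_value=6100), st.sampled_from(["+", "-"]))
    def test_partition_every_nearby_position_gets_one_category(self, pos0, strand):
        cat = classify(pos0, strand)
        start, end = EXON
        inside = start <= pos0 < end
        within_500 = (start - 500 <= pos0 < start) or (end <= pos0 < end + 500)
        if inside or within_500:
            assert cat in CATEGORIES
        else:
            assert cat == CAT_OUTSIDE


class TestPerEventCounts:
    def _plant(self, strand, spec):
        """Plant exact per-category SNP counts around EXON and count them."""
        event = SpliceEvent("ev", "g", "c", strand, *EXON, "CE")
        start, end = EXON
        upstream_left = strand == "+"
        snps = []
        pos_pool = {
            CAT_INTRONIC_UP: [
                (start - (20 + i)) if upstream_left else (end - 1 + 20 + i)
                for i in range(30)
            ],
            CAT_SS3: [
                (start - (1 + i)) if upstream_left else (end - 1 + 1 + i)
                for i in range(15)
            ],
            CAT_EXONIC: [start + 20 + i for i in range(30)],
            CAT_SS5: [
                (end - 1 + 1 + i) if upstream_left else (start - (1 + i))
                for i in range(15)
            ],
            CAT_INTRONIC_DOWN: [
                (end - 1 + 20 + i) if upstream_left else (start - (20 + i))
                for i in range(30)
            ],
        }
        for cat, n in spec.items():
            snps.extend(snp_at(p) for p in pos_pool[cat][:n])
        return per_event_snp_counts(snps, event)

    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize(
        "spec,total",
        [
            ({CAT_INTRONIC_UP: 11, CAT_SS3: 2, CAT_EXONIC: 0, CAT_SS5: 1, CAT_INTRONIC_DOWN: 5}, 19),
            ({CAT_INTRONIC_UP: 6, CAT_SS3: 3, CAT_EXONIC: 3, CAT_SS5: 1, CAT_INTRONIC_DOWN: 14}, 27),
        ],
    )
    def test_planted_counts_and_total(self, strand, spec, total):
        counts = self._plant(strand, spec)
        assert counts == (
            spec[CAT_INTRONIC_UP], spec[CAT_SS3], spec[CAT_EXONIC],
            spec[CAT_SS5], spec[CAT_INTRONIC_DOWN], total,
        )

    def test_no_snps_in_range(self):
        event = SpliceEvent("ev", "g", "c", "+", *EXON, "CE")
        assert per_event_snp_counts([snp_at(100)], event) == (0, 0, 0, 0, 0, 0)


class TestDensity:
    @pytest.mark.parametrize("n,length,expected", [(3, 600, 5.0), (0, 600, 0.0), (1, 1000, 1.0)])
    def test_per_kb(self, n, length, expected):
        assert snp_density_per_kb(n, length) == expected

    def test_linear_in_count(self):
        assert snp_density_per_kb(6, 600) == 2 * snp_density_per_kb(3, 600)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            snp_density_per_kb(1, 0)


def chi2_by_hand(a, b, c, d):
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


class TestEnrichmentChi2:
    def test_equal_densities_give_zero(self):
        chi2, p = enrichment_chi2(10, 1000, 100, 10_000)
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "n_near,len_near,n_global,len_global",
        [(200, 10**5, 1000, 10**6), (5, 4000, 80, 300_000), (13, 999, 13, 5000)],
    )
    def test_matches_hand_formula(self, n_near, len_near, n_global, len_global):
        chi2, _ = enrichment_chi2(n_near, len_near, n_global, len_global)
        expected = chi2_by_hand(
            n_near, len_near - n_near, n_global, len_global - n_global
        )
        assert chi2 == pytest.approx(expected, abs=1e-9)

    def test_scaling_counts_raises_chi2_at_fixed_ratio(self):
        chi2_small, _ = enrichment_chi2(20, 10_000, 100, 100_000)
        chi2_big, _ = enrichment_chi2(40, 20_000, 200, 200_000)
        assert chi2_big > chi2_small


class TestCpgLoss:
    def _setup(self, tmp_path, seq):
        write_fasta({"c": seq}, tmp_path / "g.fa")
        exon = (40, 70)
        tx = Transcript("t1", "g", [(10, 30), exon, (90, 110)])
        ann = GenomeAnnotation(
            [Gene("g", "G", "c", "+", [tx])], fasta_path=tmp_path / "g.fa"
        )
        event = SpliceEvent("g.e1", "g", "c", "+", *exon, "CE")
        return ann, [event]

    def test_c_to_t_in_cpg_is_loss(self, tmp_path):
        seq = "A" * 50 + "CG" + "A" * 60  # CpG at positions 50/51
        ann, events = self._setup(tmp_path, seq)
        losses = count_cpg_loss([SnpRecord("c", 51, "C", "T")], ann, events)
        assert losses == {"g": 1}

    def test_g_to_a_in_cpg_is_loss(self, tmp_path):
        seq = "A" * 50 + "CG" + "A" * 60
        ann, events = self._setup(tmp_path, seq)
        losses = count_cpg_loss([SnpRecord("c", 52, "G", "A")], ann, events)
        assert losses == {"g": 1}

    def test_non_cpg_context_is_no_loss(self, tmp_path):
        seq = "A" * 50 + "CA" + "A" * 60
        ann, events = self._setup(tmp_path, seq)
        assert count_cpg_loss([SnpRecord("c", 51, "C", "T")], ann, events) == {}

    def test_snp_outside_windows_ignored(self, tmp_path):
        seq = "A" * 700 + "CG" + "A" * 60
        write_fasta({"c": seq}, tmp_path / "g.fa")
        tx = Transcript("t1", "g", [(10, 30), (40, 70), (90, 110)])
        ann = GenomeAnnotation(
            [Gene("g", "G", "c", "+", [tx])], fasta_path=tmp_path / "g.fa"
        )
        event = SpliceEvent("g.e1", "g", "c", "+", 40, 70, "CE")
        assert count_cpg_loss([SnpRecord("c", 701, "C", "T")], ann, [event]) == {}

    def test_contig_edge_snp_skipped(self, tmp_path):
        seq = "CG" + "A" * 120
        ann, events = self._setup(tmp_path, seq)
        # pos 1 has no left context; no call, no crash
        assert count_cpg_loss([SnpRecord("c", 1, "C", "T")], ann, events) == {}
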