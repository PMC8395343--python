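"""Readers/writers, coordinate conventions, and the genomic data model."""

import pytest

from splicescope.core_io import (
    AnnotationError,
    Gene,
    GenomeAnnotation,
    JunctionTableError,
    SnpRecord,
    Transcript,
    VcfFormatError,
    read_annotation,
    read_junction_counts,
    read_vcf,
    reverse_complement,
    write_annotation,
    write_fasta,
    write_junction_counts,
)

GTF_HEADER = "#!genome-build toy\n"


def _gtf_line(chrom, feature, start, end, strand, gene, tx):
    return (
        f"{chrom}\ttoy\t{feature}\t{start}\t{end}\t.\t{strand}\t.\t"
        f'gene_id "{gene}"; transcript_id "{tx}"; gene_name "{gene}";\n'
    )


class TestReadAnnotation:
    def test_gtf_closed_coordinates_become_half_open(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(GTF_HEADER + _gtf_line("chr1", "exon", 101, 200, "+", "g1", "t1"))
        ann = read_annotation(p)
        assert ann.genes["g1"].transcripts[0].exons == [(100, 200)]
        assert ann.genes["g1"].transcripts[0].spliced_length == 100

    def test_minus_strand_exons_ordered_5p_to_3p(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(
            _gtf_line("chr1", "exon", 101, 200, "-", "g1", "t1")
            + _gtf_line("chr1", "exon", 301, 400, "-", "g1", "t1")
        )
        ann = read_annotation(p)
        assert ann.genes["g1"].transcripts[0].exons == [(300, 400), (100, 200)]

    def test_cds_outside_exons_rejected(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(
            _gtf_line("chr1", "exon", 101, 200, "+", "g1", "t1")
            + _gtf_line("chr1", "CDS", 150, 500, "+", "g1", "t1")
        )
        with pytest.raises(AnnotationError, match="CDS"):
            read_annotation(p)

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text("chr1\ttoy\texon\tnot_enough_fields\n")
        with pytest.raises(AnnotationError, match=":1"):
            read_annotation(p)

    def test_transcript_without_exons_rejected(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(_gtf_line("chr1", "CDS", 120, 180, "+", "g1", "t1"))
        with pytest.raises(AnnotationError, match="t1"):
            read_annotation(p)

    def test_row_without_ids_rejected(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text('chr1\ttoy\texon\t1\t10\t.\t+\t.\tfoo "bar";\n')
        with pytest.raises(AnnotationError, match="gene_id"):
            read_annotation(p)


class TestRoundTripAndSequence:
    def test_write_read_round_trip_is_exact(self, tmp_path):
        genes = [
            Gene("g1", "G1", "chr1", "+", [
                Transcript("t1", "g1", [(100, 200), (300, 400)], 130, 380),
            ]),
            Gene("g2", "G2", "chr1", "-", [
                Transcript("t2", "g2", [(900, 1000), (600, 700)]),
            ]),
        ]
        ann = GenomeAnnotation(genes)
        p = tmp_path / "rt.gtf"
        write_annotation(ann, p)
        ann2 = read_annotation(p)
        for gid in ann.genes:
            for t1, t2 in zip(ann.genes[gid].transcripts, ann2.genes[gid].transcripts):
                assert t1.exons == t2.exons
                assert (t1.cds_start, t1.cds_end) == (t2.cds_start, t2.cds_end)

    def test_spliced_length_matches_sequence(self, tmp_path):
        seq = "".join("ACGT"[(i * 7 + 3) % 4] for i in range(1200))
        write_fasta({"chr1": seq}, tmp_path / "g.fa")
        tx = Transcript("t1", "g1", [(700, 800), (100, 300)])
        ann = GenomeAnnotation(
            [Gene("g1", "G1", "chr1", "-", [tx])], fasta_path=tmp_path / "g.fa"
        )
        spliced = ann.spliced_sequence(tx)
        assert len(spliced) == tx.spliced_length == 300
        # 5' part of the minus-strand transcript is the genomic-right exon
        assert spliced[:100] == reverse_complement(seq[700:800])

    def test_minus_strand_sequence_is_reverse_complement(self, tmp_path):
        write_fasta({"c": "AACCGGTT"}, tmp_path / "g.fa")
        ann = GenomeAnnotation(
            [Gene("g", "G", "c", "+", [Transcript("t", "g", [(0, 8)])])],
            fasta_path=tmp_path / "g.fa",
        )
        assert ann.sequence("c", 0, 4, "+") == "AACC"
        assert ann.sequence("c", 0, 4, "-") == "GGTT"


class TestReadVcf:
    def _write(self, tmp_path, body):
        p = tmp_path / "v.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=chr1,length=10000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n" + body
        )
        return p

    def test_snv_row(self, tmp_path):
        p = self._write(tmp_path, "chr1\t500\t.\tG\tA\t.\tPASS\t.\n")
        assert read_vcf(p) == [SnpRecord("chr1", 500, "G", "A")]

    def test_multiallelic_row_yields_two_records(self, tmp_path):
        p = self._write(tmp_path, "chr1\t500\t.\tG\tA,T\t.\tPASS\t.\n")
        recs = read_vcf(p)
        assert [(r.ref, r.alt) for r in recs] == [("G", "A"), ("G", "T")]

    def test_indel_skipped_and_counted(self, tmp_path):
        p = self._write(
            tmp_path,
            "chr1\t500\t.\tG\tAT\t.\tPASS\t.\nchr1\t600\t.\tC\tT\t.\tPASS\t.\n",
        )
        stats = {}
        recs = read_vcf(p, stats=stats)
        assert len(recs) == 1 and stats["skipped"] == 1

    def test_missing_header_is_format_error(self, tmp_path):
        p = tmp_path / "bad.vcf"
        p.write_text("chr1\t500\t.\tG\tA\t.\tPASS\t.\n")
        with pytest.raises(VcfFormatError):
            read_vcf(p)


class TestSnpRecord:
    def test_ref_equals_alt_rejected(self):
        with pytest.raises(ValueError):
            SnpRecord("chr1", 5, "A", "A")

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            SnpRecord("chr1", 5, "N", "A")


class TestJunctionCounts:
    def test_basic_parse(self, tmp_path):
        p = tmp_path / "j.tsv"
        p.write_text("event_id\ts1\ts2\nev1\t10,2\t8,4\n")
        counts, samples = read_junction_counts(p)
        assert samples == ["s1", "s2"]
        assert counts["ev1"] == [(10, 2), (8, 4)]

    def test_negative_count_rejected(self, tmp_path):
        p = tmp_path / "j.tsv"
        p.write_text("event_id\ts1\nev1\t-1,2\n")
        with pytest.raises(JunctionTableError, match="negative"):
            read_junction_counts(p)

    def test_duplicate_event_rejected(self, tmp_path):
        p = tmp_path / "j.tsv"
        p.write_text("event_id\ts1\nev1\t1,2\nev1\t3,4\n")
        with pytest.raises(JunctionTableError, match="duplicate"):
            read_junction_counts(p)

    def test_missing_cell_becomes_zero_with_warning(self, tmp_path):
        p = tmp_path / "j.tsv"
        p.write_text("event_id\ts1\ts2\nev1\t1,2\t\n")
        with pytest.warns(UserWarning, match="missing"):
            counts, _ = read_junction_counts(p)
        assert counts["ev1"][1] == (0, 0)

    def test_empty_file_gives_empty_collection(self, tmp_path):
        p = tmp_path / "j.tsv"
        p.write_text("event_id\ts1\n")
        counts, samples = read_junction_counts(p)
        assert counts == {} and samples == ["s1"]

    def test_write_read_round_trip(self, tmp_path):
        p = tmp_path / "j.tsv"
        data = {"a": [(1, 2), (3, 4)], "b": [(0, 0), (5, 5)]}
        write_junction_counts(data, ["s1", "s2"], p)
        counts, samples = read_junction_counts(p)
        assert counts == data and samples == ["s1", "s2"]
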