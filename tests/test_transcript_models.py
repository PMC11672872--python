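"""Gene-model parsing, coordinate arithmetic and region-length invariants."""

import numpy as np
import pytest

from lengthome.transcript_models import (
    AnnotationError,
    GenomeStore,
    GenomicInterval,
    ModelConsistencyError,
    TranscriptModel,
    read_annotation,
    region_lengths,
    reverse_complement,
    spliced_sequence,
    write_table,
)

from conftest import make_transcript


def write_gtf_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")


class TestReadAnnotation:
    def test_two_exon_gtf_cds_in_transcript_coordinates(self, tmp_path):
        """Hand-walked toy gene: exons 1-100/201-300, CDS 51-100 + 201-250."""
        gtf = tmp_path / "toy.gtf"
        attrs = 'gene_id "g1"; transcript_id "t1";'
        write_gtf_lines(gtf, [
            f'c1\tsrc\texon\t1\t100\t.\t+\t.\t{attrs}',
            f'c1\tsrc\texon\t201\t300\t.\t+\t.\t{attrs}',
            f'c1\tsrc\tCDS\t51\t100\t.\t+\t0\t{attrs}',
            f'c1\tsrc\tCDS\t201\t250\t.\t+\t1\t{attrs}',
        ])
        (t,) = read_annotation(gtf, dialect="gtf")
        assert t.spliced_length == 200
        assert (t.cds_start, t.cds_end) == (51, 150)
        assert t.gene_symbol == "g1"

    def test_noncoding_single_exon(self, tmp_path):
        gtf = tmp_path / "nc.gtf"
        write_gtf_lines(gtf, [
            'c1\tsrc\texon\t1\t500\t.\t+\t.\tgene_id "g2"; transcript_id "t2";',
        ])
        (t,) = read_annotation(gtf, dialect="gtf")
        assert not t.is_coding
        assert region_lengths(t).len_cds == 0

    def test_minus_strand_exons_in_transcription_order(self, tmp_path):
        gtf = tmp_path / "minus.gtf"
        attrs = 'gene_id "g3"; transcript_id "t3";'
        write_gtf_lines(gtf, [
            f'c1\tsrc\texon\t1\t100\t.\t-\t.\t{attrs}',
            f'c1\tsrc\texon\t201\t300\t.\t-\t.\t{attrs}',
        ])
        (t,) = read_annotation(gtf, dialect="gtf")
        assert [e.start for e in t.exons] == [201, 1]  # genomically descending

    def test_gff3_parent_attributes(self, tmp_path):
        gff = tmp_path / "toy.gff3"
        write_gtf_lines(gff, [
            "##gff-version 3",
            "c1\tsrc\tmRNA\t1\t300\t.\t+\t.\tID=t1;gene=g1",
            "c1\tsrc\texon\t1\t100\t.\t+\t.\tParent=t1",
            "c1\tsrc\texon\t201\t300\t.\t+\t.\tParent=t1",
            "c1\tsrc\tCDS\t51\t100\t.\t+\t0\tParent=t1",
            "c1\tsrc\tCDS\t201\t250\t.\t+\t1\tParent=t1",
        ])
        (t,) = read_annotation(gff, dialect="gff3")
        assert (t.cds_start, t.cds_end) == (51, 150)
        assert t.gene_symbol == "g1"

    def test_cds_outside_exons_is_consistency_error(self, tmp_path):
        gtf = tmp_path / "bad.gtf"
        attrs = 'gene_id "g"; transcript_id "t";'
        write_gtf_lines(gtf, [
            f'c1\tsrc\texon\t1\t100\t.\t+\t.\t{attrs}',
            f'c1\tsrc\tCDS\t150\t200\t.\t+\t0\t{attrs}',
        ])
        with pytest.raises(ModelConsistencyError, match="CDS not contained"):
            read_annotation(gtf, dialect="gtf")

    def test_malformed_table_row_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "transcript_id\tgene_symbol\tchrom\tstrand\texon_starts\texon_ends"
            "\tcds_start_tx\tcds_end_tx\n"
            "t1\tg1\tc1\t+\tone,two\t100,300\t\t\n"
        )
        with pytest.raises(AnnotationError, match=":2"):
            read_annotation(p, dialect="table")


class TestRegionLengths:
    def test_cds_spanning_whole_mrna_has_empty_utrs(self):
        t = make_transcript(exons=((1, 300),), cds=(1, 300))
        r = region_lengths(t)
        assert (r.len_5utr, r.len_3utr) == (0, 0)
        assert r.len_cds == r.len_full == 300

    def test_conservation_and_exon_count(self, toy_transcript):
        r = region_lengths(toy_transcript)
        assert r.len_5utr + r.len_cds + r.len_3utr == r.len_full == 200
        assert (r.len_5utr, r.len_cds, r.len_3utr, r.n_exons) == (50, 100, 50, 2)

    def test_invariant_violation_raises(self):
        with pytest.raises(ModelConsistencyError):
            make_transcript(exons=((1, 100),), cds=(50, 250))  # CDS beyond mRNA


class TestSplicedSequence:
    def test_single_exon_identity_and_symmetry(self):
        genome = {"c1": "ACGTACGTAA"}
        plus = make_transcript(exons=((1, 10),), cds=None, strand="+")
        minus = make_transcript(exons=((1, 10),), cds=None, strand="-")
        assert spliced_sequence(plus, genome) == "ACGTACGTAA"
        assert spliced_sequence(minus, genome) == reverse_complement("ACGTACGTAA")

    def test_three_exon_equals_manual_join(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 400))
        genome = {"c1": seq}
        exons = ((11, 60), (101, 180), (301, 350))
        t = make_transcript(exons=exons, cds=None)
        manual = "".join(seq[s - 1 : e] for s, e in exons)
        assert spliced_sequence(t, genome) == manual

    def test_missing_contig_raises(self, toy_transcript):
        with pytest.raises(KeyError):
            spliced_sequence(toy_transcript, {"other": "ACGT"})


class TestRoundTripAndSymmetry:
    def test_table_round_trip_identical(self, tmp_path, small_sim):
        models = small_sim.models[:50]
        p = tmp_path / "models.tsv"
        write_table(models, p)
        back = read_annotation(p, dialect="table")
        assert len(back) == len(models)
        for a, b in zip(models, back):
            assert a.transcript_id == b.transcript_id
            assert [(e.start, e.end, e.strand) for e in a.exons] == [
                (e.start, e.end, e.strand) for e in b.exons
            ]
            assert (a.cds_start, a.cds_end) == (b.cds_start, b.cds_end)

    def test_strand_symmetry_of_region_lengths(self, small_sim):
        """Mirroring a gene to the opposite strand preserves region lengths
        and the spliced sequence (on the reverse-complemented contig)."""
        gs = GenomeStore(small_sim.genome)
        for t in small_sim.models[:30]:
            L = gs.length(t.chrom)
            flipped_strand = "-" if t.strand == "+" else "+"
            exons = [
                GenomicInterval(t.chrom, L - e.end + 1, L - e.start + 1, flipped_strand)
                for e in t.exons
            ]
            m = TranscriptModel(t.transcript_id, t.gene_symbol, exons,
                                t.cds_start, t.cds_end).validate()
            assert region_lengths(m) == region_lengths(t)
            flipped_genome = {t.chrom: reverse_complement(small_sim.genome[t.chrom])}
            assert spliced_sequence(m, flipped_genome) == spliced_sequence(t, gs)

    def test_sequence_level_oracle_on_random_transcripts(self, small_sim):
        """Region lengths measured on the spliced sequence string agree with
        the coordinate arithmetic: planted start/stop codons sit exactly at
        the boundaries the 5'UTR/CDS lengths imply."""
        gs = GenomeStore(small_sim.genome)
        coding = [t for t in small_sim.models if t.is_coding][:100]
        assert len(coding) == 100
        for t in coding:
            seq = spliced_sequence(t, gs)
            r = region_lengths(t)
            assert len(seq) == r.len_full
            assert r.len_5utr + r.len_cds + r.len_3utr == r.len_full
            assert seq[r.len_5utr : r.len_5utr + 3] == "ATG"
            cds_end = r.len_5utr + r.len_cds
            assert seq[cds_end - 3 : cds_end] == "TAA"
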