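"""Coordinate model, interval arithmetic and GFF3/BED12/FASTA round trips."""

import numpy as np
import pytest

from annoweave.genomic_model import (
    GenomicInterval,
    MaskedGenome,
    interval_length,
    introns_of,
    read_bed12,
    read_gff3,
    write_gff3,
)

from conftest import make_transcript


class TestGenomicInterval:
    def test_invariants(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 5, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 5)

    def test_one_based_inclusive_length_of_candidate_locus(self):
        # chromosome-arm interval printed as 25,901,374-37,085,204 bp
        iv = GenomicInterval("Ra02", 25_901_374, 37_085_204)
        assert interval_length(iv, "one_based_inclusive") == 11_183_831
        assert round(interval_length(iv, "one_based_inclusive") / 1e6, 1) == 11.2

    def test_single_position_interval(self):
        assert interval_length(GenomicInterval("c", 5, 6), "internal") == 1
        # a single base printed as "5..5"
        assert interval_length((5, 5), "one_based_inclusive") == 1

    def test_length_vs_position_enumeration(self, rng):
        for _ in range(1000):
            start = int(rng.integers(0, 10_000))
            end = start + int(rng.integers(1, 500))
            iv = GenomicInterval("c", start, end)
            n_positions = len(range(start, end))
            assert interval_length(iv, "internal") == n_positions
            assert interval_length(iv, "one_based_inclusive") == n_positions + 1


class TestIntrons:
    def test_examples(self):
        t = make_transcript([(0, 100), (200, 300), (400, 500)])
        assert [(iv.start, iv.end) for iv in introns_of(t)] == [
            (100, 200),
            (300, 400),
        ]
        single = make_transcript([(0, 100)])
        assert introns_of(single) == ()

    def test_against_pairwise_gap_oracle(self, rng):
        for _ in range(100):
            k = int(rng.integers(1, 8))
            bounds = np.sort(rng.choice(np.arange(1, 5000), size=2 * k, replace=False))
            exon_coords = [(int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(k)]
            t = make_transcript(exon_coords)
            expected = [
                (exon_coords[i][1], exon_coords[i + 1][0]) for i in range(k - 1)
            ]
            got = [(iv.start, iv.end) for iv in introns_of(t)]
            assert got == expected
            assert len(got) == k - 1
            # introns disjoint from exons
            for s, e in got:
                assert all(e <= es or s >= ee for es, ee in exon_coords)


class TestGff3:
    def test_coordinate_convention(self, tmp_path):
        gff = tmp_path / "x.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t101\t300\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\tmRNA\t101\t300\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr1\tsrc\texon\t101\t200\t.\t+\t.\tID=t1.e1;Parent=t1\n"
            "chr1\tsrc\texon\t201\t300\t.\t+\t.\tID=t1.e2;Parent=t1\n"
        )
        (t,) = read_gff3(gff)
        assert (t.exons[0].start, t.exons[0].end) == (100, 200)
        assert t.exons[0].length == 100

    def test_intron_between_one_based_exons(self, tmp_path):
        gff = tmp_path / "x.gff3"
        gff.write_text(
            "chr1\tsrc\tmRNA\t1\t300\t.\t+\t.\tID=t1\n"
            "chr1\tsrc\texon\t1\t100\t.\t+\t.\tID=t1.e1;Parent=t1\n"
            "chr1\tsrc\texon\t201\t300\t.\t+\t.\tID=t1.e2;Parent=t1\n"
        )
        (t,) = read_gff3(gff)
        (intron,) = introns_of(t)
        assert (intron.start, intron.end) == (100, 200)

    def test_round_trip_lossless(self, tmp_path, annotation_fixture):
        models = annotation_fixture.truth[:20]
        p1, p2 = tmp_path / "a.gff3", tmp_path / "b.gff3"
        write_gff3(models, p1)
        back = read_gff3(p1)
        write_gff3(back, p2)
        again = read_gff3(p2)
        assert back == again
        assert sorted(t.id for t in back) == sorted(t.id for t in models)
        by_id = {t.id: t for t in back}
        for t in models:
            assert by_id[t.id].exons == t.exons
            assert by_id[t.id].cds == t.cds

    def test_duplicate_id_is_hard_error(self, tmp_path):
        gff = tmp_path / "dup.gff3"
        gff.write_text(
            "chr1\tsrc\tmRNA\t1\t100\t.\t+\t.\tID=t1\n"
            "chr1\tsrc\tmRNA\t200\t300\t.\t+\t.\tID=t1\n"
        )
        with pytest.raises(ValueError):
            read_gff3(gff)

    def test_dangling_parent_is_hard_error(self, tmp_path):
        gff = tmp_path / "bad.gff3"
        gff.write_text(
            "chr1\tsrc\tmRNA\t1\t100\t.\t+\t.\tID=t1;Parent=nope\n"
            "chr1\tsrc\texon\t1\t100\t.\t+\t.\tID=t1.e1;Parent=t1\n"
        )
        with pytest.raises(ValueError, match="nope"):
            read_gff3(gff)

    def test_cds_outside_exons_is_hard_error(self, tmp_path):
        gff = tmp_path / "bad.gff3"
        gff.write_text(
            "chr1\tsrc\tmRNA\t1\t100\t.\t+\t.\tID=t1\n"
            "chr1\tsrc\texon\t1\t50\t.\t+\t.\tID=t1.e1;Parent=t1\n"
            "chr1\tsrc\tCDS\t40\t80\t.\t+\t0\tID=t1.c1;Parent=t1\n"
        )
        with pytest.raises(ValueError, match="outside exons"):
            read_gff3(gff)


class TestBed12:
    def test_blocks_become_exons(self, tmp_path):
        bed = tmp_path / "x.bed"
        bed.write_text(
            "chr1\t1000\t2000\ttx1\t0\t+\t1100\t1900\t0\t2\t300,400\t0,600\n"
        )
        (t,) = read_bed12(bed)
        assert [(e.start, e.end) for e in t.exons] == [(1000, 1300), (1600, 2000)]
        assert [(c.start, c.end) for c in t.cds] == [(1100, 1300), (1600, 1900)]
        assert t.strand == "+"

    def test_malformed_line_rejected(self, tmp_path):
        bed = tmp_path / "x.bed"
        bed.write_text("chr1\t0\t100\tt\t0\t+\n")
        with pytest.raises(ValueError):
            read_bed12(bed)


class TestMaskedGenome:
    def test_case_round_trip_and_mask_queries(self, tmp_path):
        g = MaskedGenome({"c": "ACGTacgtNNNN"})
        path = tmp_path / "g.fa"
        g.to_fasta(path)
        back = MaskedGenome.from_fasta(path)
        assert back.sequences == g.sequences
        assert back.masked_bp("c") == 4
        assert back.masked_runs("c") == [(4, 8)]

    def test_transcript_sequence_minus_strand(self):
        g = MaskedGenome({"c": "AAACCCGGGTTT"})
        t = make_transcript([(0, 3), (6, 9)], strand="-", seq_id="c")
        # exons AAA + GGG -> plus-strand cDNA AAAGGG -> revcomp CCCTTT
        assert g.transcript_sequence(t) == "CCCTTT"
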