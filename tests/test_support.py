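"""Support classification against a literal-rule oracle, and its invariants."""

import numpy as np
import pytest

from annoweave.genomic_model import GenomicInterval
from annoweave.hint_integration import Hint, HintSet
from annoweave.support_classifier import (
    category_counts,
    classify,
    classify_all,
    codon_intervals,
    select_training,
)

from conftest import make_isoform, make_transcript


def intron_hint(start, end, source, strand="+", mult=3, seq="chr1"):
    return Hint("intron", GenomicInterval(seq, start, end, strand), source, mult)


def codon_hint(kind, start, source="protein", strand="+", seq="chr1"):
    return Hint(kind, GenomicInterval(seq, start, start + 3, strand), source, 1)


def coding(coords, tid="t1", strand="+"):
    return make_transcript(coords, strand=strand, tid=tid, cds_coords=coords)


class TestIsoSeqRules:
    def test_extra_intron_inside_cds_span_blocks_full(self):
        # prediction with 3 introns, all carried by the isoform, but the
        # isoform has a fourth intron inside the prediction's CDS span
        t = coding([(0, 100), (200, 300), (400, 500), (600, 700)])
        iso = make_isoform(
            [(0, 100), (200, 250), (260, 300), (400, 500), (600, 700)], 300
        )
        rec = classify(t, [iso], HintSet(), HintSet())
        assert rec.isoseq == "partial"

    def test_extra_intron_in_utr_allows_full(self):
        t = coding([(100, 200), (300, 400)])
        # isoform carries the intron plus an extra one upstream of the CDS span
        iso = make_isoform([(0, 40), (60, 200), (300, 450)], 200)
        rec = classify(t, [iso], HintSet(), HintSet())
        assert rec.isoseq == "full"

    def test_single_exon_requires_exact_orf_match(self):
        t = coding([(1000, 1600)], tid="se")
        exact = make_isoform([(900, 1700)], 600, tid="exact")
        exact_orf = exact.lorf.__class__("exact", 100, 700)  # maps to 1000..1600
        exact = exact.__class__(exact.transcript, 1.0, 1.0, exact_orf)
        off = make_isoform([(900, 1700)], 600, tid="off")  # ORF at 900..1500
        assert classify(t, [exact], HintSet(), HintSet()).isoseq == "full"
        rec = classify(t, [off], HintSet(), HintSet())
        assert rec.isoseq == "partial"  # overlapping ORF but no exact match

    def test_cds_overlap_gives_partial(self):
        t = coding([(0, 100), (200, 300)])
        iso = make_isoform([(250, 900)], 300, tid="ov")
        rec = classify(t, [iso], HintSet(), HintSet())
        assert rec.isoseq == "partial"


class TestRnaSeqAndProteinRules:
    def test_all_introns_in_rnaseq_hints_full(self):
        t = coding([(0, 100), (200, 300), (400, 500)])
        hints = HintSet(
            [intron_hint(100, 200, "rnaseq"), intron_hint(300, 400, "rnaseq")]
        )
        rec = classify(t, [], hints, HintSet())
        assert rec.rnaseq == "full"

    def test_some_introns_partial(self):
        t = coding([(0, 100), (200, 300), (400, 500)])
        hints = HintSet([intron_hint(100, 200, "rnaseq")])
        assert classify(t, [], hints, HintSet()).rnaseq == "partial"

    def test_single_exon_never_rnaseq_supported(self):
        t = coding([(0, 600)])
        hints = HintSet([intron_hint(100, 200, "rnaseq")])
        assert classify(t, [], hints, HintSet()).rnaseq == "none"

    def test_single_exon_protein_start_and_stop(self):
        t = coding([(0, 600)])
        start_only = HintSet([codon_hint("start", 0)])
        both = HintSet([codon_hint("start", 0), codon_hint("stop", 597)])
        assert classify(t, [], HintSet(), start_only).protein == "partial"
        assert classify(t, [], HintSet(), both).protein == "full"

    def test_minus_strand_codons(self):
        t = coding([(0, 600)], strand="-")
        start_key, stop_key = codon_intervals(t)
        assert start_key == ("chr1", "start", 597, 600, "-")
        assert stop_key == ("chr1", "stop", 0, 3, "-")
        both = HintSet(
            [
                codon_hint("start", 597, strand="-"),
                codon_hint("stop", 0, strand="-"),
            ]
        )
        assert classify(t, [], HintSet(), both).protein == "full"

    def test_nothing_matches(self):
        t = coding([(0, 100), (200, 300)])
        rec = classify(t, [], HintSet(), HintSet())
        assert (rec.isoseq, rec.rnaseq, rec.protein) == ("none", "none", "none")
        assert not rec.any_support

    def test_transcript_without_cds_is_hard_error(self):
        bare = make_transcript([(0, 300)])
        with pytest.raises(ValueError, match="CDS"):
            classify(bare, [], HintSet(), HintSet())


class TestAgainstLiteralOracle:
    """Random fixtures compared with an independent rule-by-rule oracle."""

    @staticmethod
    def _oracle(t, iso_set, rnaseq, protein):
        t_introns = {
            (t.seq_id, "intron", a.end, b.start, t.strand)
            for a, b in zip(t.exons, t.exons[1:])
        }
        cds_lo, cds_hi = t.cds[0].start, t.cds[-1].end
        rn = {h.key for h in rnaseq if h.kind == "intron"}
        pr = {h.key for h in protein if h.kind == "intron"}
        ss = {h.key for h in protein if h.kind in ("start", "stop")}
        start_key, stop_key = codon_intervals(t)

        def iso_introns(iso):
            e = iso.transcript.exons
            return {
                (t.seq_id, "intron", a.end, b.start, t.strand)
                for a, b in zip(e, e[1:])
            }

        isos = [
            i
            for i in iso_set
            if i.transcript.seq_id == t.seq_id and i.transcript.strand == t.strand
        ]
        multi = len(t.exons) >= 2
        if multi:
            iso_full = any(
                t_introns <= iso_introns(i)
                and all(
                    k[3] <= cds_lo or k[2] >= cds_hi
                    for k in iso_introns(i) - t_introns
                )
                for i in isos
            )
        else:
            iso_full = any(
                i.genome_cds()
                and i.genome_cds()[0].start == cds_lo
                and i.genome_cds()[-1].end == cds_hi
                for i in isos
            )
        iso_partial = any(iso_introns(i) & t_introns for i in isos) or any(
            any(
                c.start < p.end and p.start < c.end
                for c in t.cds
                for p in i.genome_cds()
            )
            for i in isos
        )
        rn_level = (
            "full"
            if multi and t_introns <= rn
            else "partial"
            if multi and t_introns & rn
            else "none"
        )
        hits = len({start_key, stop_key} & ss)
        if multi:
            pr_level = (
                "full"
                if t_introns <= pr
                else "partial"
                if (t_introns & pr) or hits
                else "none"
            )
        else:
            pr_level = "full" if hits == 2 else "partial" if hits == 1 else "none"
        iso_level = "full" if iso_full else "partial" if iso_partial else "none"
        return iso_level, rn_level, pr_level

    def test_fixture_matches_oracle(self, annotation_fixture):
        fx = annotation_fixture
        from annoweave.isoseq_processing import isoforms_from_models

        iso_set = isoforms_from_models(fx.isoforms, fx.genome)
        records = classify_all(fx.predictions, iso_set, fx.rnaseq_hints, fx.protein_hints)
        for t, rec in zip(fx.predictions, records):
            expected = self._oracle(t, iso_set, fx.rnaseq_hints, fx.protein_hints)
            assert (rec.isoseq, rec.rnaseq, rec.protein) == expected, t.id


class TestMonotonicityAndAggregates:
    def test_adding_hints_never_demotes(self, annotation_fixture):
        fx = annotation_fixture
        rank = {"none": 0, "partial": 1, "full": 2}
        some = HintSet(list(fx.rnaseq_hints)[::2])
        base = classify_all(fx.predictions, [], some, HintSet())
        more = classify_all(fx.predictions, [], fx.rnaseq_hints, fx.protein_hints)
        for b, m in zip(base, more):
            assert rank[m.rnaseq] >= rank[b.rnaseq]
            assert rank[m.protein] >= rank[b.protein]

    def test_training_selection(self):
        t1 = coding([(0, 100), (200, 300)], tid="iso_full")
        t2 = coding([(1000, 1100), (1200, 1300)], tid="rna_only")
        iso = make_isoform([(0, 100), (200, 300)], 200)
        rnaseq = HintSet([intron_hint(1100, 1200, "rnaseq")])
        records = classify_all([t1, t2], [iso], rnaseq, HintSet())
        assert select_training(records) == ["iso_full"]
        assert records[1].rnaseq == "full"  # supported, but not for training
        assert select_training([]) == []

    def test_category_partition(self, annotation_fixture):
        fx = annotation_fixture
        from annoweave.isoseq_processing import isoforms_from_models

        iso_set = isoforms_from_models(fx.isoforms, fx.genome)
        records = classify_all(fx.predictions, iso_set, fx.rnaseq_hints, fx.protein_hints)
        counts = category_counts(records)
        assert (
            counts["fully_supported_any"]
            + counts["partial_any"]
            + counts["unsupported"]
            == counts["total"]
        )
        training = set(select_training(records))
        fully = {r.transcript_id for r in records if r.fully_supported_any}
        assert training <= fully

    def test_all_full_single_transcript(self):
        t = coding([(0, 100), (200, 300)])
        iso = make_isoform([(0, 100), (200, 300)], 200)
        rnaseq = HintSet([intron_hint(100, 200, "rnaseq")])
        protein = HintSet([intron_hint(100, 200, "protein")])
        counts = category_counts(classify_all([t], [iso], rnaseq, protein))
        assert counts == {
            "total": 1,
            "full_isoseq": 1,
            "full_rnaseq": 1,
            "full_protein": 1,
            "fully_supported_any": 1,
            "partial_any": 0,
            "unsupported": 0,
        }
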