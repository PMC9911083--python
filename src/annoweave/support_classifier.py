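"""Classify predicted transcripts by external-evidence support.

Each prediction receives a support level (full / partial / none) per evidence
class — Iso-Seq, RNA-Seq, protein:

* multiexon, Iso-Seq full: some Iso-Seq transcript carries all of the
  prediction's introns, and any additional introns of that transcript fall
  entirely outside the prediction's CDS genomic span (i.e. in its UTRs);
* multiexon, RNA-Seq/protein full: every intron matches an intron hint of
  that source;
* single-exon, Iso-Seq full: some Iso-Seq ORF projects to exactly the
  prediction's CDS start and end;
* single-exon, protein full: both the start and the stop codon match protein
  hints;
* partial: not full, but at least one element matched — an intron key, a
  start/stop hint, or (Iso-Seq) at least ``min_overlap`` bp of same-strand
  CDS overlap with an Iso-Seq ORF.

Single-exon transcripts can never gain RNA-Seq support, since RNA-Seq
evidence consists solely of intron hints.  Training genes are predictions
with full Iso-Seq OR full protein support.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genomic_model import GenomicInterval, TranscriptModel, introns_of
from .hint_integration import HintKey, HintSet

FULL, PARTIAL, NONE = "full", "partial", "none"


@dataclass(frozen=True)
class SupportRecord:
    transcript_id: str
    isoseq: str
    rnaseq: str
    protein: str

    @property
    def any_support(self) -> bool:
        return any(v != NONE for v in (self.isoseq, self.rnaseq, self.protein))

    @property
    def fully_supported_any(self) -> bool:
        return FULL in (self.isoseq, self.rnaseq, self.protein)


def codon_intervals(t: TranscriptModel) -> tuple[HintKey, HintKey]:
    """(start, stop) codon hint keys of a CDS-bearing transcript.

    The start codon is the first 3 coding bases in transcription order, the
    stop codon the last 3; both are taken within their terminal CDS piece.
    """
    if not t.cds:
        raise ValueError(f"transcript {t.id} has no CDS")
    if t.strand == "-":
        first, last = t.cds[-1], t.cds[0]
        start_iv = (t.seq_id, "start", first.end - 3, first.end, "-")
        stop_iv = (t.seq_id, "stop", last.start, last.start + 3, "-")
    else:
        first, last = t.cds[0], t.cds[-1]
        start_iv = (t.seq_id, "start", first.start, first.start + 3, "+")
        stop_iv = (t.seq_id, "stop", last.end - 3, last.end, "+")
    return start_iv, stop_iv


def _intron_keys(t: TranscriptModel) -> set[HintKey]:
    return {
        (iv.seq_id, "intron", iv.start, iv.end, iv.strand) for iv in introns_of(t)
    }


def _pieces_overlap_bp(a, b) -> int:
    total = 0
    for x in a:
        for y in b:
            if x.seq_id == y.seq_id and x.strand == y.strand:
                total += max(0, min(x.end, y.end) - max(x.start, y.start))
    return total


def classify(
    t: TranscriptModel,
    iso_set,
    intron_hints: HintSet,
    protein_hints: HintSet,
    min_overlap: int = 1,
) -> SupportRecord:
    """Support record of prediction ``t`` against the three evidence classes.

    ``iso_set`` is the representative AlignedIsoform collection;
    ``intron_hints`` the RNA-Seq intron HintSet; ``protein_hints`` the
    protein intron/start/stop HintSet.  A prediction without CDS is a hard
    error.
    """
    if not t.cds:
        raise ValueError(f"transcript {t.id} has no CDS; cannot classify")
    t_introns = _intron_keys(t)
    cds_span = t.cds_span
    rnaseq_introns = intron_hints.keys_of_kind("intron")
    protein_introns = protein_hints.keys_of_kind("intron")
    start_key, stop_key = codon_intervals(t)
    protein_startstop = protein_hints.keys_of_kind("start") | protein_hints.keys_of_kind(
        "stop"
    )

    same_seq_iso = [
        iso
        for iso in iso_set
        if iso.transcript.seq_id == t.seq_id and iso.transcript.strand == t.strand
    ]

    # --- Iso-Seq ---
    iso_level = NONE
    if t.is_multiexon:
        for iso in same_seq_iso:
            iso_introns = _intron_keys(iso.transcript)
            if not t_introns <= iso_introns:
                continue
            extra = iso_introns - t_introns
            if all(
                key[3] <= cds_span.start or key[2] >= cds_span.end for key in extra
            ):
                iso_level = FULL
                break
    else:
        for iso in same_seq_iso:
            pieces = iso.genome_cds()
            if not pieces:
                continue
            if pieces[0].start == cds_span.start and pieces[-1].end == cds_span.end:
                iso_level = FULL
                break
    if iso_level != FULL:
        iso_intron_union: set[HintKey] = set()
        for iso in same_seq_iso:
            iso_intron_union |= _intron_keys(iso.transcript)
        if t_introns & iso_intron_union:
            iso_level = PARTIAL
        else:
            for iso in same_seq_iso:
                if _pieces_overlap_bp(t.cds, iso.genome_cds()) >= min_overlap:
                    iso_level = PARTIAL
                    break

    # --- RNA-Seq (intron hints only) ---
    rnaseq_level = NONE
    if t.is_multiexon:
        if t_introns <= rnaseq_introns:
            rnaseq_level = FULL
        elif t_introns & rnaseq_introns:
            rnaseq_level = PARTIAL

    # --- protein ---
    protein_level = NONE
    startstop_hits = len({start_key, stop_key} & protein_startstop)
    if t.is_multiexon:
        if t_introns <= protein_introns:
            protein_level = FULL
        elif (t_introns & protein_introns) or startstop_hits:
            protein_level = PARTIAL
    else:
        if startstop_hits == 2:
            protein_level = FULL
        elif startstop_hits == 1:
            protein_level = PARTIAL

    return SupportRecord(t.id, iso_level, rnaseq_level, protein_level)


def classify_all(
    transcripts,
    iso_set,
    intron_hints: HintSet,
    protein_hints: HintSet,
    min_overlap: int = 1,
) -> list[SupportRecord]:
    return [
        classify(t, iso_set, intron_hints, protein_hints, min_overlap)
        for t in transcripts
    ]


def select_training(records) -> list[str]:
    """Transcripts fully supported by Iso-Seq or protein hints (AUGUSTUS training)."""
    return [r.transcript_id for r in records if FULL in (r.isoseq, r.protein)]


def category_counts(records) -> dict[str, int]:
    """Support-category tally.

    ``fully_supported_any`` + ``partial_only`` + ``unsupported`` partitions
    the total.
    """
    recs = list(records)
    counts = {
        "total": len(recs),
        "full_isoseq": sum(r.isoseq == FULL for r in recs),
        "full_rnaseq": sum(r.rnaseq == FULL for r in recs),
        "full_protein": sum(r.protein == FULL for r in recs),
        "fully_supported_any": sum(r.fully_supported_any for r in recs),
        "partial_any": sum(r.any_support and not r.fully_supported_any for r in recs),
        "unsupported": sum(not r.any_support for r in recs),
    }
    return counts


def records_to_frame(records) -> pd.DataFrame:
    rows = [
        {
            "transcript_id": r.transcript_id,
            "isoseq": r.isoseq,
            "rnaseq": r.rnaseq,
            "protein": r.protein,
            "any_support": r.any_support,
            "fully_supported_any": r.fully_supported_any,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "isoseq",
            "rnaseq",
            "protein",
            "any_support",
            "fully_supported_any",
        ],
    )


def supported_orf_intervals(
    iso_set,
    intron_hints: HintSet,
    protein_hints: HintSet,
) -> dict[str, tuple[GenomicInterval, ...]]:
    """Iso-Seq ORFs eligible for mask refinement, keyed by isoform id.

    An isoform's ORF counts as supported by independent evidence when at
    least one of its introns appears in the RNA-Seq or protein intron-hint
    set, or — for isoforms whose ORF sits in a single exon — when both its
    start and stop codons match protein hints.
    """
    rnaseq_introns = intron_hints.keys_of_kind("intron")
    protein_introns = protein_hints.keys_of_kind("intron")
    protein_startstop = protein_hints.keys_of_kind("start") | protein_hints.keys_of_kind(
        "stop"
    )
    out: dict[str, tuple[GenomicInterval, ...]] = {}
    for iso in iso_set:
        pieces = iso.genome_cds()
        if not pieces:
            continue
        introns = _intron_keys(iso.transcript)
        supported = bool(introns & (rnaseq_introns | protein_introns))
        if not supported:
            t = iso.transcript
            seq_id, strand = t.seq_id, t.strand
            if strand == "-":
                start_key = (seq_id, "start", pieces[-1].end - 3, pieces[-1].end, "-")
                stop_key = (seq_id, "stop", pieces[0].start, pieces[0].start + 3, "-")
            else:
                start_key = (seq_id, "start", pieces[0].start, pieces[0].start + 3, "+")
                stop_key = (seq_id, "stop", pieces[-1].end - 3, pieces[-1].end, "+")
            supported = {start_key, stop_key} <= protein_startstop
        if supported:
            out[iso.id] = pieces
    return out
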