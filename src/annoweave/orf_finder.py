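"""Longest-ORF detection in spliced transcripts and projection to the genome.

Iso-Seq full-length reads are orientation-resolved upstream (primer/polyA
classification), so only the three forward frames are scanned.  An ORF runs
from ATG to the first in-frame stop (TAA/TAG/TGA), stop included; ORFs with
no stop inside the transcript are not reported.  Codons containing ambiguity
codes qualify neither as start nor as stop.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genomic_model import GenomicInterval, TranscriptModel

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"


@dataclass(frozen=True)
class Orf:
    """An open reading frame in transcript coordinates (0-based half-open).

    ``length_nt`` includes the stop codon and is a multiple of 3.
    """

    transcript_id: str
    tx_start: int
    tx_end: int

    @property
    def length_nt(self) -> int:
        return self.tx_end - self.tx_start


def longest_orf(cdna: str, transcript_id: str = "") -> Orf | None:
    """Longest ATG→stop ORF among the three forward frames of ``cdna``.

    Ties are broken by the smallest transcript start.  Returns None when no
    complete ORF exists.
    """
    seq = cdna.upper()
    n = len(seq)
    best: Orf | None = None
    for frame in range(3):
        start: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if start is not None:
                    cand = Orf(transcript_id, start, i + 3)
                    if (
                        best is None
                        or cand.length_nt > best.length_nt
                        or (
                            cand.length_nt == best.length_nt
                            and cand.tx_start < best.tx_start
                        )
                    ):
                        best = cand
                    start = None
            elif start is None and codon == START_CODON:
                start = i
    return best


def project_orf(t: TranscriptModel, orf: Orf) -> tuple[GenomicInterval, ...]:
    """Map a transcript-relative interval through the exon chain.

    On the '-' strand transcript position 0 corresponds to the highest
    genomic base of the last exon; returned pieces are in ascending genomic
    order and sum to ``orf.length_nt``.
    """
    total = t.exon_len
    if orf.tx_end > total:
        raise ValueError(
            f"ORF ({orf.tx_start}, {orf.tx_end}) extends past transcript "
            f"{t.id} of spliced length {total}"
        )
    return project_transcript_interval(t, orf.tx_start, orf.tx_end)


def project_transcript_interval(
    t: TranscriptModel, tx_start: int, tx_end: int
) -> tuple[GenomicInterval, ...]:
    """Project transcript coordinates [tx_start, tx_end) to genome pieces."""
    if not (0 <= tx_start < tx_end <= t.exon_len):
        raise ValueError(
            f"interval ({tx_start}, {tx_end}) outside transcript {t.id}"
        )
    # exons in transcription order
    exons = t.exons if t.strand != "-" else tuple(reversed(t.exons))
    pieces = []
    offset = 0
    for e in exons:
        e_lo, e_hi = offset, offset + e.length
        lo = max(tx_start, e_lo)
        hi = min(tx_end, e_hi)
        if lo < hi:
            if t.strand == "-":
                # transcript offset 0 maps to e.end - 1
                g_end = e.end - (lo - e_lo)
                g_start = e.end - (hi - e_lo)
            else:
                g_start = e.start + (lo - e_lo)
                g_end = e.start + (hi - e_lo)
            pieces.append(GenomicInterval(t.seq_id, g_start, g_end, t.strand))
        offset = e_hi
    return tuple(sorted(pieces, key=lambda p: p.start))


def orf_of_transcript(t: TranscriptModel, cdna: str) -> Orf | None:
    """Convenience: longest ORF of ``t`` given its spliced sequence."""
    return longest_orf(cdna, transcript_id=t.id)
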