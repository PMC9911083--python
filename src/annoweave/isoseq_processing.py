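"""Iso-Seq alignment filtering and nonoverlapping representative-isoform selection.

Aligned isoforms are first filtered on alignment quality (identity >= 0.95,
coverage >= 0.90 by default).  Overlapping isoforms — connected components of
same-strand genomic-span overlap — are then reduced to a single representative
per locus, the one with the longest ORF; finally representatives whose ORF is
shorter than 300 nt or that contain an intron longer than 10,000 nt are
removed.  The length/intron filter runs AFTER representative selection, so a
locus can end up with no representative at all.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genomic_model import GenomicInterval, MaskedGenome, TranscriptModel, introns_of
from .orf_finder import Orf, orf_of_transcript, project_orf


@dataclass(frozen=True)
class AlignedIsoform:
    """An Iso-Seq transcript aligned to the genome, with alignment metrics."""

    transcript: TranscriptModel
    identity: float
    coverage: float
    lorf: Orf | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0 and 0.0 <= self.coverage <= 1.0):
            raise ValueError(
                f"{self.transcript.id}: identity/coverage must be fractions in [0, 1]"
            )

    @property
    def id(self) -> str:
        return self.transcript.id

    @property
    def span(self) -> GenomicInterval:
        return self.transcript.span

    def genome_cds(self) -> tuple[GenomicInterval, ...]:
        """Spliced genomic projection of the ORF (empty if no ORF)."""
        if self.lorf is None:
            return ()
        return project_orf(self.transcript, self.lorf)


def _parse_fraction(raw: str, what: str, record_id: str) -> float:
    try:
        val = float(raw)
    except ValueError as exc:
        raise ValueError(f"record {record_id}: bad {what} value {raw!r}") from exc
    # percentages auto-detected
    return val / 100.0 if val > 1.0 else val


def isoforms_from_models(
    models, genome: MaskedGenome | None = None
) -> list[AlignedIsoform]:
    """Wrap transcript models as AlignedIsoforms.

    ``identity`` and ``coverage`` are read from transcript attributes
    (fractions or percentages, auto-detected); a missing attribute is a hard
    error.  When a genome is supplied the longest ORF of each isoform is
    computed from its spliced sequence.
    """
    out = []
    for t in models:
        for key in ("identity", "coverage"):
            if key not in t.attributes:
                raise ValueError(f"record {t.id}: missing attribute {key!r}")
        identity = _parse_fraction(str(t.attributes["identity"]), "identity", t.id)
        coverage = _parse_fraction(str(t.attributes["coverage"]), "coverage", t.id)
        lorf = None
        if genome is not None:
            lorf = orf_of_transcript(t, genome.transcript_sequence(t))
        out.append(AlignedIsoform(t, identity, coverage, lorf))
    return out


def filter_alignments(
    isoforms,
    min_identity: float = 0.95,
    min_coverage: float = 0.90,
) -> list[AlignedIsoform]:
    """Keep isoforms with identity >= min_identity AND coverage >= min_coverage."""
    return [
        iso
        for iso in isoforms
        if iso.identity >= min_identity and iso.coverage >= min_coverage
    ]


def _overlap_components(isoforms) -> list[list[AlignedIsoform]]:
    """Connected components of same-strand genomic-span overlap (>= 1 bp)."""
    groups: dict[tuple[str, str], list[AlignedIsoform]] = {}
    for iso in isoforms:
        groups.setdefault((iso.span.seq_id, iso.span.strand), []).append(iso)
    components = []
    for members in groups.values():
        members.sort(key=lambda i: (i.span.start, i.span.end, i.id))
        current: list[AlignedIsoform] = []
        reach = -1
        for iso in members:
            if current and iso.span.start < reach:
                current.append(iso)
                reach = max(reach, iso.span.end)
            else:
                if current:
                    components.append(current)
                current = [iso]
                reach = iso.span.end
        if current:
            components.append(current)
    return components


def select_representatives(
    isoforms,
    min_lorf_nt: int = 300,
    max_intron_nt: int = 10_000,
) -> list[AlignedIsoform]:
    """Reduce isoforms to one representative per overlap locus, then filter.

    Isoforms lacking an ORF are dropped first.  In each connected component of
    same-strand span overlap the isoform with the longest ORF wins (ties:
    smaller span start, then lexicographic id).  Representatives with an ORF
    shorter than ``min_lorf_nt`` or any intron longer than ``max_intron_nt``
    are then removed — strict comparisons, so 300 nt ORFs and 10,000 nt
    introns survive.
    """
    with_orf = [iso for iso in isoforms if iso.lorf is not None]
    reps = []
    for component in _overlap_components(with_orf):
        rep = min(
            component,
            key=lambda i: (-i.lorf.length_nt, i.span.start, i.id),
        )
        reps.append(rep)
    kept = []
    for rep in reps:
        if rep.lorf.length_nt < min_lorf_nt:
            continue
        intron_lengths = [iv.length for iv in introns_of(rep.transcript)]
        if intron_lengths and max(intron_lengths) > max_intron_nt:
            continue
        kept.append(rep)
    kept.sort(key=lambda i: (i.span.seq_id, i.span.start, i.id))
    return kept
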