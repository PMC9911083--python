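"""Combine predicted genes with Iso-Seq ORFs into one nonoverlapping seed set.

Seeds anchor the downstream protein-evidence search.  Both inputs must be
internally nonoverlapping (same-strand CDS-span overlap).  Where an Iso-Seq
seed overlaps predictions, it replaces them only if its ORF is more than
50 nt longer than the longest-CDS overlapping prediction — a diff of exactly
50 keeps the prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genomic_model import GenomicInterval, TranscriptModel


@dataclass(frozen=True)
class SeedRegion:
    origin: str  # prediction | isoseq
    model: TranscriptModel
    cds_len_nt: int

    def __post_init__(self) -> None:
        if self.cds_len_nt <= 0:
            raise ValueError(f"seed {self.model.id}: empty CDS")
        if self.origin not in ("prediction", "isoseq"):
            raise ValueError(f"unknown seed origin {self.origin!r}")

    @property
    def cds_span(self) -> GenomicInterval:
        return self.model.cds_span


def _seed(model: TranscriptModel, origin: str) -> SeedRegion:
    if not model.cds:
        raise ValueError(f"seed candidate {model.id} has no CDS")
    return SeedRegion(origin, model, model.cds_len)


def _check_nonoverlapping(seeds, label: str) -> None:
    by_key: dict[tuple[str, str], list[SeedRegion]] = {}
    for s in seeds:
        by_key.setdefault((s.cds_span.seq_id, s.cds_span.strand), []).append(s)
    for members in by_key.values():
        members.sort(key=lambda s: s.cds_span.start)
        for a, b in zip(members, members[1:]):
            if b.cds_span.start < a.cds_span.end:
                raise ValueError(
                    f"{label} input contains overlapping members "
                    f"{a.model.id} and {b.model.id}"
                )


def _same_strand_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.strand == b.strand and a.overlaps(b)


def combine_seeds(
    predictions,
    isoseq_orfs,
    margin_nt: int = 50,
) -> list[SeedRegion]:
    """Merge prediction and Iso-Seq seed candidates under the >margin rule.

    Overlap is tested on same-strand CDS genomic spans.  Non-overlapping
    candidates pass through.  For each Iso-Seq seed overlapping one or more
    surviving predictions, the rule is applied against the longest-CDS
    opponent: the Iso-Seq seed wins iff its CDS is more than ``margin_nt``
    longer, in which case every prediction it overlaps is removed; otherwise
    the Iso-Seq seed is dropped.  Overlapping members within either input are
    a contract violation (hard error).
    """
    pred_seeds = [_seed(t, "prediction") for t in predictions]
    iso_seeds = [_seed(t, "isoseq") for t in isoseq_orfs]
    _check_nonoverlapping(pred_seeds, "predictions")
    _check_nonoverlapping(iso_seeds, "isoseq")

    surviving = list(pred_seeds)
    kept_iso = []
    for iso in sorted(iso_seeds, key=lambda s: (s.cds_span.seq_id, s.cds_span.start)):
        opponents = [
            p for p in surviving if _same_strand_overlap(iso.cds_span, p.cds_span)
        ]
        if not opponents:
            kept_iso.append(iso)
            continue
        strongest = max(opponents, key=lambda p: (p.cds_len_nt, -p.cds_span.start))
        if iso.cds_len_nt - strongest.cds_len_nt > margin_nt:
            surviving = [p for p in surviving if p not in opponents]
            kept_iso.append(iso)
        # else: prediction side wins, iso dropped
    out = surviving + kept_iso
    out.sort(key=lambda s: (s.cds_span.seq_id, s.cds_span.start, s.model.id))
    return out
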