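"""Unmask soft-masked genome regions overlapping evidence-supported Iso-Seq ORFs.

Repeat masking frequently swallows real coding exons; where an Iso-Seq ORF
with independent (protein or RNA-Seq) support overlaps a masked run, the
overlapping bases are restored to uppercase.  Only the intersection of masked
runs with ORF intervals is unmasked — never whole repeat runs — which is the
minimal, conservative refinement.  Residue identity is case-invariant
throughout, and the operation is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genomic_model import GenomicInterval, MaskedGenome


@dataclass
class MaskReport:
    """Outcome of a mask-refinement pass."""

    unmasked_bp: int
    n_loci: int
    per_sequence: pd.DataFrame  # columns: seq_id, unmasked_bp, n_loci

    def to_tsv(self, path) -> None:
        self.per_sequence.to_csv(path, sep="\t", index=False)


def refine_mask(
    genome: MaskedGenome,
    supported_orfs: dict[str, tuple[GenomicInterval, ...]],
) -> tuple[MaskedGenome, MaskReport]:
    """Unmask every masked base inside a supported ORF interval.

    ``supported_orfs`` maps locus id -> genomic CDS pieces of the supported
    Iso-Seq ORF at that locus (restricted upstream to ORFs with protein or
    RNA-Seq support).  Returns a new genome plus a report counting distinct
    changed bases and loci whose intervals overlapped at least one initially
    masked base.  Intervals outside the genome are a hard error.
    """
    original = genome.sequences
    buffers = {name: bytearray(seq, "ascii") for name, seq in original.items()}
    loci_changed = 0
    per_seq: dict[str, list[int]] = {}
    # locus attribution is judged against the ORIGINAL mask so that the report
    # does not depend on locus iteration order when ORF intervals overlap
    for locus_id, intervals in supported_orfs.items():
        masked_overlap = 0
        locus_seq = None
        for iv in intervals:
            if iv.seq_id not in buffers:
                raise ValueError(f"locus {locus_id}: unknown sequence {iv.seq_id!r}")
            buf = buffers[iv.seq_id]
            if iv.end > len(buf):
                raise ValueError(
                    f"locus {locus_id}: interval {iv.seq_id}:{iv.start}-{iv.end} "
                    f"outside sequence of length {len(buf)}"
                )
            n = sum(c.islower() for c in original[iv.seq_id][iv.start : iv.end])
            buf[iv.start : iv.end] = buf[iv.start : iv.end].upper()
            if n:
                masked_overlap += n
                if locus_seq is None:
                    locus_seq = iv.seq_id
        if masked_overlap:
            loci_changed += 1
            per_seq.setdefault(locus_seq, [0, 0])[1] += 1
    total_unmasked = 0
    for name, buf in buffers.items():
        changed = sum(
            1 for a, b in zip(original[name], buf.decode("ascii")) if a != b
        )
        if changed:
            per_seq.setdefault(name, [0, 0])[0] = changed
            total_unmasked += changed
    table = pd.DataFrame(
        [
            {"seq_id": name, "unmasked_bp": v[0], "n_loci": v[1]}
            for name, v in sorted(per_seq.items())
        ],
        columns=["seq_id", "unmasked_bp", "n_loci"],
    )
    refined = MaskedGenome(
        {name: buf.decode("ascii") for name, buf in buffers.items()}
    )
    return refined, MaskReport(total_unmasked, loci_changed, table)
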