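"""Annotation summary statistics and the proportion/ratio arithmetic of reports.

Covers the headline numbers an annotation report prints: gene and transcript
totals, the isoform-count histogram, mean gene length, introns per gene,
median intron/exon lengths, and per-category protein-length / intronless
tallies.  All printed percentages and ratios use half-up decimal rounding,
which matches how such values are conventionally reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from statistics import median

import pandas as pd

from .genomic_model import TranscriptModel, introns_of


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def proportion(n: float, d: float, decimals: int = 1) -> float:
    """100*n/d with half-up rounding to ``decimals``; d <= 0 is a hard error."""
    if d <= 0:
        raise ValueError("proportion denominator must be > 0")
    return _round_half_up(100.0 * n / d, decimals)


def ratio(a: float, b: float, decimals: int = 1) -> float:
    """a/b with half-up rounding to ``decimals``; b <= 0 is a hard error."""
    if b <= 0:
        raise ValueError("ratio denominator must be > 0")
    return _round_half_up(a / b, decimals)


@dataclass
class AnnotationSummary:
    n_genes: int = 0
    n_transcripts: int = 0
    isoform_histogram: dict[int, int] = field(default_factory=dict)
    mean_gene_length_bp: float = 0.0
    mean_introns_per_gene: float = 0.0
    median_intron_bp: float = 0.0
    median_exon_bp: float = 0.0
    mean_protein_aa_by_category: dict[str, float] = field(default_factory=dict)
    intronless_count_by_category: dict[str, int] = field(default_factory=dict)

    @property
    def is_empty(self) -> bool:
        return self.n_genes == 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("n_genes", self.n_genes),
            ("n_transcripts", self.n_transcripts),
            ("mean_gene_length_bp", self.mean_gene_length_bp),
            ("mean_introns_per_gene", self.mean_introns_per_gene),
            ("median_intron_bp", self.median_intron_bp),
            ("median_exon_bp", self.median_exon_bp),
        ]
        rows += [
            (f"genes_with_{k}_isoforms", v)
            for k, v in sorted(self.isoform_histogram.items())
        ]
        return pd.DataFrame(rows, columns=["statistic", "value"])


def protein_length_aa(t: TranscriptModel) -> float:
    """Protein length in amino acids: CDS_nt/3 minus the stop codon."""
    return t.cds_len / 3 - 1


def summarize(transcripts, support_records=None) -> AnnotationSummary:
    """Summary statistics over transcripts grouped by ``gene_id``.

    ``support_records`` (optional, from the support classifier) enables the
    per-category protein-length and intronless tables, split into
    ``supported`` (any evidence) and ``unsupported``.  Empty input returns an
    empty-summary sentinel.
    """
    ts = list(transcripts)
    if not ts:
        return AnnotationSummary()
    genes: dict[str, list[TranscriptModel]] = {}
    for t in ts:
        genes.setdefault(t.gene_id, []).append(t)

    hist: dict[int, int] = {}
    gene_lengths = []
    introns_per_gene = []
    intron_lengths: list[int] = []
    exon_lengths: list[int] = []
    for members in genes.values():
        hist[len(members)] = hist.get(len(members), 0) + 1
        start = min(t.span.start for t in members)
        end = max(t.span.end for t in members)
        gene_lengths.append(end - start)
        introns_per_gene.append(
            max(len(introns_of(t)) for t in members)
        )
        for t in members:
            intron_lengths.extend(iv.length for iv in introns_of(t))
            exon_lengths.extend(e.length for e in t.exons)

    summary = AnnotationSummary(
        n_genes=len(genes),
        n_transcripts=len(ts),
        isoform_histogram=dict(sorted(hist.items())),
        mean_gene_length_bp=sum(gene_lengths) / len(genes),
        mean_introns_per_gene=sum(introns_per_gene) / len(genes),
        median_intron_bp=float(median(intron_lengths)) if intron_lengths else 0.0,
        median_exon_bp=float(median(exon_lengths)) if exon_lengths else 0.0,
    )

    if support_records is not None:
        by_id = {r.transcript_id: r for r in support_records}
        cats: dict[str, list[TranscriptModel]] = {"supported": [], "unsupported": []}
        for t in ts:
            rec = by_id.get(t.id)
            cat = "supported" if (rec is not None and rec.any_support) else "unsupported"
            cats[cat].append(t)
        for cat, members in cats.items():
            coding = [t for t in members if t.cds]
            if coding:
                summary.mean_protein_aa_by_category[cat] = sum(
                    protein_length_aa(t) for t in coding
                ) / len(coding)
            summary.intronless_count_by_category[cat] = sum(
                not t.is_multiexon for t in members
            )
    return summary


@dataclass
class CountTable:
    """Labelled numerator/denominator rows with printed-percentage rendering."""

    rows: list[tuple[str, float, float]] = field(default_factory=list)

    def add(self, label: str, numerator: float, denominator: float) -> None:
        if denominator <= 0:
            raise ValueError(f"{label}: denominator must be > 0")
        self.rows.append((label, numerator, denominator))

    def to_frame(self, decimals: int = 1) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "label": lab,
                    "numerator": n,
                    "denominator": d,
                    "percent": proportion(n, d, decimals),
                }
                for lab, n, d in self.rows
            ]
        )
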