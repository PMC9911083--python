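"""Core coordinate model and readers/writers for GFF3, BED12 and soft-masked FASTA.

All coordinates are stored 0-based half-open internally; GFF3 I/O converts
to/from the 1-based inclusive convention of the format.  Transcripts on the
minus strand keep their exons in ascending genomic order — biological
(transcription) order is derived where needed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import gffutils
import pyfaidx

_COMPLEMENT = str.maketrans(
    "ACGTUMRWSYKVHDBNacgtumrwsykvhdbn",
    "TGCAAKYWSRMBDHVNtgcaakywsrmbdhvn",
)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ValueError("seq_id must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


def interval_length(a, convention: str = "internal") -> int:
    """Length in bp of an interval or a raw ``(start, end)`` pair.

    ``internal`` treats (start, end) as 0-based half-open (end - start);
    ``one_based_inclusive`` treats them as 1-based inclusive endpoints
    (end - start + 1), the convention of printed genome coordinates, where a
    single base prints as (p, p).
    """
    start, end = (a.start, a.end) if isinstance(a, GenomicInterval) else a
    if convention == "internal":
        if not start < end:
            raise ValueError("internal interval requires start < end")
        return end - start
    if convention == "one_based_inclusive":
        if not start <= end:
            raise ValueError("one-based inclusive interval requires start <= end")
        return end - start + 1
    raise ValueError(f"unknown convention {convention!r}")


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded chain of exons with optional CDS.

    Used both for predicted gene models (``source='prediction'``) and for
    Iso-Seq transcript alignments projected onto the genome
    (``source='isoseq'``).
    """

    id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    cds: tuple[GenomicInterval, ...] = ()
    source: str = "prediction"
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id}: no exons")
        seq_ids = {e.seq_id for e in self.exons} | {c.seq_id for c in self.cds}
        if len(seq_ids) != 1:
            raise ValueError(f"transcript {self.id}: features on multiple sequences")
        strands = {e.strand for e in self.exons}
        if len(strands) != 1:
            raise ValueError(f"transcript {self.id}: mixed exon strands")
        prev_end = -1
        for e in sorted(self.exons, key=lambda x: x.start):
            if e.start < prev_end:
                raise ValueError(f"transcript {self.id}: overlapping exons")
            prev_end = e.end
        object.__setattr__(
            self, "exons", tuple(sorted(self.exons, key=lambda x: x.start))
        )
        object.__setattr__(
            self, "cds", tuple(sorted(self.cds, key=lambda x: x.start))
        )
        for c in self.cds:
            if not any(e.start <= c.start and c.end <= e.end for e in self.exons):
                raise ValueError(
                    f"transcript {self.id}: CDS {c.start}-{c.end} outside exons"
                )

    @property
    def seq_id(self) -> str:
        return self.exons[0].seq_id

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.seq_id, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def cds_span(self) -> GenomicInterval | None:
        if not self.cds:
            return None
        return GenomicInterval(
            self.seq_id, self.cds[0].start, self.cds[-1].end, self.strand
        )

    @property
    def cds_len(self) -> int:
        return sum(c.length for c in self.cds)

    @property
    def exon_len(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def is_multiexon(self) -> bool:
        return len(self.exons) >= 2

    def with_attributes(self, **kwargs) -> "TranscriptModel":
        attrs = dict(self.attributes)
        attrs.update(kwargs)
        return replace(self, attributes=attrs)


def introns_of(t: TranscriptModel) -> tuple[GenomicInterval, ...]:
    """Introns as the gaps between consecutive exons (ascending order)."""
    out = []
    for a, b in zip(t.exons, t.exons[1:]):
        out.append(GenomicInterval(t.seq_id, a.end, b.start, t.strand))
    return tuple(out)


class MaskedGenome:
    """Named nucleotide sequences with per-base masking encoded as lowercase.

    Residue identity is case-invariant: masking/unmasking only changes case.
    """

    def __init__(self, sequences: dict[str, str]):
        self.sequences = dict(sequences)

    @classmethod
    def from_fasta(cls, path) -> "MaskedGenome":
        fa = pyfaidx.Fasta(str(path), read_ahead=10_000_000)
        seqs = {name: str(fa[name][:]) for name in fa.keys()}
        fa.close()
        return cls(seqs)

    def to_fasta(self, path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.sequences

    def length(self, seq_id: str) -> int:
        return len(self.sequences[seq_id])

    def fetch(self, iv: GenomicInterval, *, stranded: bool = True) -> str:
        """Uppercase residues of ``iv``; reverse-complemented on '-' if stranded."""
        seq = self.sequences[iv.seq_id][iv.start : iv.end].upper()
        if stranded and iv.strand == "-":
            seq = reverse_complement(seq)
        return seq

    def is_masked(self, seq_id: str, pos: int) -> bool:
        return self.sequences[seq_id][pos].islower()

    def masked_bp(self, seq_id: str | None = None) -> int:
        names = [seq_id] if seq_id is not None else list(self.sequences)
        return sum(sum(c.islower() for c in self.sequences[n]) for n in names)

    def masked_runs(self, seq_id: str) -> list[tuple[int, int]]:
        """Maximal runs of masked (lowercase) positions as (start, end) pairs."""
        runs = []
        for m in re.finditer(r"[a-z]+", self.sequences[seq_id]):
            runs.append((m.start(), m.end()))
        return runs

    def transcript_sequence(self, t: TranscriptModel) -> str:
        """Spliced cDNA of ``t`` in transcription (sense) orientation."""
        parts = [self.fetch(e, stranded=False) for e in t.exons]
        seq = "".join(parts)
        if t.strand == "-":
            seq = reverse_complement(seq)
        return seq


# ---------------------------------------------------------------------------
# GFF3 I/O


def _transcript_from_db(db, mrna) -> TranscriptModel:
    exons = []
    cds = []
    for child in db.children(mrna, level=1):
        iv = GenomicInterval(child.seqid, child.start - 1, child.end, child.strand)
        if child.featuretype == "exon":
            exons.append(iv)
        elif child.featuretype == "CDS":
            cds.append(iv)
    attrs = {
        k: v[0] if len(v) == 1 else ",".join(v)
        for k, v in mrna.attributes.items()
        if k not in ("ID", "Parent")
    }
    gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
    source = "isoseq" if mrna.source in ("isoseq", "IsoSeq") else "prediction"
    return TranscriptModel(
        id=mrna.id,
        gene_id=gene_id,
        exons=tuple(exons),
        cds=tuple(cds),
        source=source,
        attributes=attrs,
    )


def read_gff3(path) -> list[TranscriptModel]:
    """Read gene/mRNA/exon/CDS models from a GFF3 file.

    Coordinates are converted from 1-based inclusive to internal 0-based
    half-open.  Duplicate feature IDs and dangling Parent references are hard
    errors; CDS segments outside exons are hard errors.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="error",
        keep_order=True,
    )
    ids = {f.id for f in db.all_features() if f.id}
    for f in db.all_features():
        for parent in f.attributes.get("Parent", []):
            if parent not in ids:
                raise ValueError(
                    f"{path}: feature {f.id or f.featuretype} at "
                    f"{f.seqid}:{f.start}-{f.end} references missing parent "
                    f"{parent!r}"
                )
    models = [_transcript_from_db(db, m) for m in db.features_of_type("mRNA")]
    models.sort(key=lambda t: (t.seq_id, t.span.start, t.id))
    return models


def _fmt_attrs(attrs: dict) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def write_gff3(models, path) -> None:
    """Write transcript models as gene/mRNA/exon/CDS GFF3 (1-based inclusive)."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in models:
        by_gene.setdefault(t.gene_id, []).append(t)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id in sorted(
            by_gene, key=lambda g: (by_gene[g][0].seq_id, by_gene[g][0].span.start)
        ):
            ts = by_gene[gene_id]
            seq_id = ts[0].seq_id
            strand = ts[0].strand
            gstart = min(t.span.start for t in ts)
            gend = max(t.span.end for t in ts)
            src = ts[0].source
            # standalone alignments (gene_id == transcript id) get no gene line
            standalone = any(t.id == gene_id for t in ts)
            if not standalone:
                fh.write(
                    f"{seq_id}\t{src}\tgene\t{gstart + 1}\t{gend}\t.\t{strand}\t.\t"
                    f"ID={gene_id}\n"
                )
            for t in sorted(ts, key=lambda x: x.id):
                attrs = {"ID": t.id}
                if not standalone:
                    attrs["Parent"] = gene_id
                attrs.update(t.attributes)
                fh.write(
                    f"{seq_id}\t{src}\tmRNA\t{t.span.start + 1}\t{t.span.end}\t.\t"
                    f"{strand}\t.\t{_fmt_attrs(attrs)}\n"
                )
                for i, e in enumerate(t.exons, 1):
                    fh.write(
                        f"{seq_id}\t{src}\texon\t{e.start + 1}\t{e.end}\t.\t{strand}"
                        f"\t.\tID={t.id}.exon{i};Parent={t.id}\n"
                    )
                phase = 0
                cds_in_order = t.cds if strand != "-" else tuple(reversed(t.cds))
                phases = {}
                for c in cds_in_order:
                    phases[c] = phase
                    phase = (3 - ((c.length - phase) % 3)) % 3
                for i, c in enumerate(t.cds, 1):
                    fh.write(
                        f"{seq_id}\t{src}\tCDS\t{c.start + 1}\t{c.end}\t.\t{strand}"
                        f"\t{phases[c]}\tID={t.id}.cds{i};Parent={t.id}\n"
                    )


def read_bed12(path, source: str = "isoseq") -> list[TranscriptModel]:
    """Read BED12 alignments (blockStarts/blockSizes become exons).

    thickStart/thickEnd, when distinct, are clipped against the blocks to give
    the CDS chain.  BED scores and names are preserved; coordinates are already
    0-based half-open.
    """
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED columns")
            seq_id, chrom_start, name = f[0], int(f[1]), f[3]
            strand = f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != int(f[9]) or len(starts) != int(f[9]):
                raise ValueError(f"{path}:{lineno}: blockCount mismatch")
            exons = tuple(
                GenomicInterval(
                    seq_id, chrom_start + s, chrom_start + s + sz, strand
                )
                for s, sz in zip(starts, sizes)
            )
            cds = []
            if thick_end > thick_start:
                for e in exons:
                    s = max(e.start, thick_start)
                    en = min(e.end, thick_end)
                    if s < en:
                        cds.append(GenomicInterval(seq_id, s, en, strand))
            models.append(
                TranscriptModel(
                    id=name,
                    gene_id=name,
                    exons=exons,
                    cds=tuple(cds),
                    source=source,
                )
            )
    models.sort(key=lambda t: (t.seq_id, t.span.start, t.id))
    return models
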