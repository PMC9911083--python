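"""Desk-scale synthetic fixtures with exact ground truth.

Emulates the inputs of the annotation-evidence pipeline — a soft-masked toy
genome with planted multi-exon genes (ATG..stop CDS, canonical GT-AG
introns), Iso-Seq transcript alignments with UTRs and configurable emission
probabilities, RNA-Seq intron hints with coverage counts, protein
intron/start/stop hints — plus an F1 tetraploid dosage-genotype matrix with
configurable missingness and segregation distortion.

Planted transcripts are constructed so that the longest ORF of every Iso-Seq
isoform is exactly the planted CDS: 5' UTR sequence is drawn from {C,G,T}
(no upstream ATG possible) and assembled transcripts are checked and
resampled until no competing ORF is longer.  That makes the analytic
expected-category table exact rather than approximate.

A single integer seed drives one explicit NumPy generator threaded through
all sampling; identical (config, seed) yields byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genomic_model import (
    GenomicInterval,
    MaskedGenome,
    TranscriptModel,
    introns_of,
    reverse_complement,
    write_gff3,
)
from .hint_integration import Hint, HintSet, write_hints_gff
from .orf_finder import longest_orf
from .sdm_filter import ABSENT, MISSING, PRESENT, DosageMarker, write_marker_tsv
from .support_classifier import codon_intervals

_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_STOPS = ["TAA", "TAG", "TGA"]


@dataclass
class FixtureConfig:
    """All knobs of the synthetic fixture, with study-scale defaults."""

    seed: int = 0
    # genome / gene structure
    genome_length_bp: int = 200_000
    n_genes: int = 40
    exon_bp: tuple[int, int] = (150, 400)
    intron_bp: tuple[int, int] = (60, 300)
    n_exons: tuple[int, int] = (1, 6)
    intergenic_bp: tuple[int, int] = (600, 1000)
    repeat_fraction: float = 0.3
    repeat_run_bp: tuple[int, int] = (100, 600)
    # Iso-Seq
    p_isoseq: float = 0.7
    utr_bp: tuple[int, int] = (40, 120)
    p_extra_utr_intron: float = 0.2
    utr_intron_bp: tuple[int, int] = (60, 90)
    identity_range: tuple[float, float] = (0.95, 1.0)
    coverage_range: tuple[float, float] = (0.90, 1.0)
    # RNA-Seq
    p_rnaseq_intron: float = 0.8
    rnaseq_coverage: tuple[int, int] = (3, 150)
    # protein
    p_protein_intron: float = 0.7
    p_protein_start: float = 0.6
    p_protein_stop: float = 0.6
    # markers
    n_markers: int = 500
    n_progeny: int = 119
    simplex_fraction: float = 0.6
    missing_rate: float = 0.02
    distortion_fraction: float = 0.1
    distortion_p: float = 0.75
    max_missing: float = 0.05

    def validate(self) -> None:
        probs = [
            self.p_isoseq,
            self.p_extra_utr_intron,
            self.p_rnaseq_intron,
            self.p_protein_intron,
            self.p_protein_start,
            self.p_protein_stop,
            self.simplex_fraction,
            self.missing_rate,
            self.distortion_fraction,
            self.distortion_p,
        ]
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        for lo, hi in (
            self.exon_bp,
            self.intron_bp,
            self.intergenic_bp,
            self.repeat_run_bp,
            self.utr_bp,
            self.utr_intron_bp,
        ):
            if not (0 < lo <= hi):
                raise ValueError("length ranges must be positive and ordered")

    @classmethod
    def from_yaml(cls, path) -> "FixtureConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        tuple_fields = {
            "exon_bp",
            "intron_bp",
            "n_exons",
            "intergenic_bp",
            "repeat_run_bp",
            "utr_bp",
            "utr_intron_bp",
            "identity_range",
            "coverage_range",
            "rnaseq_coverage",
        }
        kwargs = {
            k: tuple(v) if k in tuple_fields else v for k, v in raw.items()
        }
        return cls(**kwargs)


@dataclass
class AnnotationFixture:
    """In-memory result of generate_annotation_fixture."""

    genome: MaskedGenome
    truth: list[TranscriptModel]
    predictions: list[TranscriptModel]
    isoforms: list[TranscriptModel]  # attributes carry identity/coverage
    rnaseq_hints: HintSet
    protein_hints: HintSet
    expected_categories: pd.DataFrame  # category, expected, sd
    per_gene: pd.DataFrame  # gene-level truth/emission bookkeeping


def _random_seq(rng, n: int, alphabet: str = "ACGT") -> str:
    return "".join(np.asarray(list(alphabet))[rng.integers(0, len(alphabet), n)])


def _random_cds(rng, length_nt: int) -> str:
    """ATG + random non-stop codons + stop; length_nt must be 3k, k >= 3."""
    assert length_nt % 3 == 0 and length_nt >= 9
    n_mid = length_nt // 3 - 2
    mid = "".join(
        np.asarray(_NON_STOP_CODONS)[rng.integers(0, len(_NON_STOP_CODONS), n_mid)]
    )
    stop = _STOPS[rng.integers(0, 3)]
    return "ATG" + mid + stop


def _random_intron(rng, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "GT" + _random_seq(rng, max(n - 4, 0)) + "AG"


def _gene_structure(cfg: FixtureConfig, rng):
    """Exon/intron lengths for one gene; CDS total is 3k and >= 306 nt."""
    k = int(rng.integers(cfg.n_exons[0], cfg.n_exons[1] + 1))
    lo, hi = cfg.exon_bp
    if k == 1:
        exon_lens = [int(rng.integers(max(lo, 306), max(hi, 312) + 1))]
    else:
        exon_lens = [int(rng.integers(lo, hi + 1)) for _ in range(k)]
    total = sum(exon_lens)
    exon_lens[-1] += (3 - total % 3) % 3
    while sum(exon_lens) < 306:
        exon_lens[-1] += 3
    intron_lens = [
        int(rng.integers(cfg.intron_bp[0], cfg.intron_bp[1] + 1)) for _ in range(k - 1)
    ]
    return exon_lens, intron_lens


def _build_gene(cfg: FixtureConfig, rng, gene_idx: int, offset: int):
    """Plant one gene; returns (block_seq, truth_model, isoform_model|None, meta)."""
    exon_lens, intron_lens = _gene_structure(cfg, rng)
    cds_len = sum(exon_lens)
    strand = "+" if rng.random() < 0.5 else "-"
    has_iso = rng.random() < cfg.p_isoseq
    utr5_len = int(rng.integers(cfg.utr_bp[0], cfg.utr_bp[1] + 1))
    utr3_len = int(rng.integers(cfg.utr_bp[0], cfg.utr_bp[1] + 1))
    has_utr_intron = has_iso and rng.random() < cfg.p_extra_utr_intron
    utr_intron = (
        _random_intron(rng, *cfg.utr_intron_bp) if has_utr_intron else ""
    )
    introns = [_random_intron(rng, l, l) for l in intron_lens]

    for _attempt in range(60):
        cds = _random_cds(rng, cds_len)
        utr5 = _random_seq(rng, utr5_len, alphabet="CGT")
        utr3 = _random_seq(rng, utr3_len)
        cdna = utr5 + cds + utr3
        orf = longest_orf(cdna)
        if orf is not None and orf.tx_start == utr5_len and orf.length_nt == cds_len:
            break
    else:  # pragma: no cover - would need adversarial config
        raise RuntimeError(f"gene {gene_idx}: could not plant a dominant ORF")

    # sense-order genomic parts: (kind, seq); kind utr_exon|utr_intron|cds_exon|intron
    parts: list[tuple[str, str]] = []
    if has_utr_intron:
        u1 = utr5[: utr5_len // 2]
        u2 = utr5[utr5_len // 2 :]
        parts += [("utr_exon", u1), ("utr_intron", utr_intron), ("utr_exon", u2)]
    else:
        parts.append(("utr_exon", utr5))
    pos = 0
    for i, el in enumerate(exon_lens):
        parts.append(("cds_exon", cds[pos : pos + el]))
        pos += el
        if i < len(intron_lens):
            parts.append(("intron", introns[i]))
    parts.append(("utr_exon", utr3))

    block = "".join(seq for _, seq in parts)
    L = len(block)
    # sense offsets of each part
    sense_spans = []
    cur = 0
    for kind, seq in parts:
        sense_spans.append((kind, cur, cur + len(seq)))
        cur += len(seq)
    if strand == "-":
        block = reverse_complement(block)
        spans = [(kind, offset + L - e, offset + L - s) for kind, s, e in sense_spans]
    else:
        spans = [(kind, offset + s, offset + e) for kind, s, e in sense_spans]

    cds_ivs = sorted(
        (GenomicInterval("chr1", s, e, strand) for kind, s, e in spans if kind == "cds_exon"),
        key=lambda iv: iv.start,
    )
    gene_id = f"g{gene_idx}"
    truth = TranscriptModel(
        id=f"{gene_id}.t1",
        gene_id=gene_id,
        exons=tuple(cds_ivs),
        cds=tuple(cds_ivs),
        source="prediction",
    )

    isoform = None
    if has_iso:
        # merge adjacent non-intron spans into isoform exons (sense order)
        iso_exons: list[tuple[int, int]] = []
        for kind, s, e in sorted(spans, key=lambda x: x[1]):
            if kind in ("intron", "utr_intron"):
                continue
            if iso_exons and iso_exons[-1][1] == s:
                iso_exons[-1] = (iso_exons[-1][0], e)
            else:
                iso_exons.append((s, e))
        identity = float(rng.uniform(*cfg.identity_range))
        coverage = float(rng.uniform(*cfg.coverage_range))
        isoform = TranscriptModel(
            id=f"iso_{gene_id}",
            gene_id=f"iso_{gene_id}",
            exons=tuple(
                GenomicInterval("chr1", s, e, strand) for s, e in iso_exons
            ),
            source="isoseq",
            attributes={
                "identity": f"{identity:.4f}",
                "coverage": f"{coverage:.4f}",
            },
        )

    meta = {
        "gene_id": gene_id,
        "strand": strand,
        "n_exons": len(exon_lens),
        "n_introns": len(intron_lens),
        "cds_len_nt": cds_len,
        "has_isoseq": has_iso,
        "has_utr_intron": has_utr_intron,
    }
    return block, truth, isoform, meta


def _soft_mask(cfg: FixtureConfig, rng, seq: str) -> str:
    """Lowercase random runs until ~repeat_fraction of the genome is masked."""
    buf = bytearray(seq, "ascii")
    n = len(buf)
    target = int(cfg.repeat_fraction * n)
    masked = 0
    for _ in range(20 * max(1, n // max(cfg.repeat_run_bp[0], 1))):
        if masked >= target:
            break
        run = int(rng.integers(cfg.repeat_run_bp[0], cfg.repeat_run_bp[1] + 1))
        start = int(rng.integers(0, max(1, n - run)))
        piece = buf[start : start + run]
        lower = piece.lower()
        masked += sum(1 for a, b in zip(piece, lower) if a != b)
        buf[start : start + run] = lower
    return buf.decode("ascii")


def generate_annotation_fixture(
    cfg: FixtureConfig, out_dir=None
) -> AnnotationFixture:
    """Generate the annotation fixture; optionally write its files to out_dir.

    Files written: genome.fa (soft-masked), truth.gff3, predictions.gff3,
    isoseq.gff3 (identity/coverage attributes), rnaseq_hints.gff,
    protein_hints.gff, expected_categories.tsv, per_gene.tsv.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    blocks: list[str] = []
    truth: list[TranscriptModel] = []
    isoforms: list[TranscriptModel] = []
    metas: list[dict] = []
    offset = 0
    for gi in range(cfg.n_genes):
        gap = int(rng.integers(cfg.intergenic_bp[0], cfg.intergenic_bp[1] + 1))
        blocks.append(_random_seq(rng, gap))
        offset += gap
        block, t, iso, meta = _build_gene(cfg, rng, gi + 1, offset)
        blocks.append(block)
        offset += len(block)
        truth.append(t)
        if iso is not None:
            isoforms.append(iso)
        metas.append(meta)
    tail = int(rng.integers(cfg.intergenic_bp[0], cfg.intergenic_bp[1] + 1))
    blocks.append(_random_seq(rng, tail))
    offset += tail
    if offset > cfg.genome_length_bp:
        raise ValueError(
            f"infeasible config: planted content needs {offset} bp but "
            f"genome_length_bp is {cfg.genome_length_bp}"
        )
    blocks.append(_random_seq(rng, cfg.genome_length_bp - offset))
    genome_seq = _soft_mask(cfg, rng, "".join(blocks))
    genome = MaskedGenome({"chr1": genome_seq})

    # evidence emission
    rnaseq = HintSet()
    protein = HintSet()
    for t, meta in zip(truth, metas):
        for iv in introns_of(t):
            if rng.random() < cfg.p_rnaseq_intron:
                mult = int(
                    rng.integers(cfg.rnaseq_coverage[0], cfg.rnaseq_coverage[1] + 1)
                )
                rnaseq.add(Hint("intron", iv, "rnaseq", mult))
            if rng.random() < cfg.p_protein_intron:
                protein.add(Hint("intron", iv, "protein", 1))
        start_key, stop_key = codon_intervals(t)
        if rng.random() < cfg.p_protein_start:
            protein.add(
                Hint(
                    "start",
                    GenomicInterval(start_key[0], start_key[2], start_key[3], start_key[4]),
                    "protein",
                    1,
                )
            )
        if rng.random() < cfg.p_protein_stop:
            protein.add(
                Hint(
                    "stop",
                    GenomicInterval(stop_key[0], stop_key[2], stop_key[3], stop_key[4]),
                    "protein",
                    1,
                )
            )

    expected = _expected_categories(cfg, metas)
    per_gene = pd.DataFrame(metas)

    fixture = AnnotationFixture(
        genome=genome,
        truth=truth,
        predictions=list(truth),
        isoforms=isoforms,
        rnaseq_hints=rnaseq,
        protein_hints=protein,
        expected_categories=expected,
        per_gene=per_gene,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        genome.to_fasta(out / "genome.fa")
        write_gff3(truth, out / "truth.gff3")
        write_gff3(fixture.predictions, out / "predictions.gff3")
        write_gff3(isoforms, out / "isoseq.gff3")
        write_hints_gff(rnaseq, out / "rnaseq_hints.gff")
        write_hints_gff(protein, out / "protein_hints.gff")
        expected.to_csv(out / "expected_categories.tsv", sep="\t", index=False)
        per_gene.to_csv(out / "per_gene.tsv", sep="\t", index=False)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
    return fixture


def _expected_categories(cfg: FixtureConfig, metas) -> pd.DataFrame:
    """Analytic expected support-category counts given emission probabilities.

    Per gene: P(full Iso-Seq) = p_isoseq (an emitted isoform always carries
    the full intron chain, extras only in UTRs); P(full RNA-Seq) =
    p_rnaseq_intron^n_introns for multiexon genes, 0 for single-exon;
    P(full protein) = p_protein_intron^n_introns (multiexon) or
    p_start*p_stop (single-exon).  SDs are exact Poisson-binomial.
    """
    rows = {
        "full_isoseq": [],
        "full_rnaseq": [],
        "full_protein": [],
        "fully_supported_any": [],
    }
    for meta in metas:
        k = meta["n_introns"]
        p_iso = cfg.p_isoseq
        p_rna = cfg.p_rnaseq_intron**k if k > 0 else 0.0
        if k > 0:
            p_prot = cfg.p_protein_intron**k
        else:
            p_prot = cfg.p_protein_start * cfg.p_protein_stop
        p_any = 1.0 - (1.0 - p_iso) * (1.0 - p_rna) * (1.0 - p_prot)
        rows["full_isoseq"].append(p_iso)
        rows["full_rnaseq"].append(p_rna)
        rows["full_protein"].append(p_prot)
        rows["fully_supported_any"].append(p_any)
    out = []
    for cat, ps in rows.items():
        expected = float(sum(ps))
        var = float(sum(p * (1 - p) for p in ps))
        out.append({"category": cat, "expected": expected, "sd": math.sqrt(var)})
    return pd.DataFrame(out, columns=["category", "expected", "sd"])


# ---------------------------------------------------------------------------
# marker fixture


def _present_prob(maternal: int, paternal: int) -> float:
    """P(progeny shows the allele) under tetrasomic bivalent inheritance."""

    def absent_gamete(d: int) -> float:
        return math.comb(4 - d, 2) / math.comb(4, 2)

    return 1.0 - absent_gamete(maternal) * absent_gamete(paternal)


_OFF_TYPE_DOSAGES = [(2, 0), (0, 1), (1, 1), (0, 2)]


def generate_marker_fixture(
    cfg: FixtureConfig, out_path=None
) -> tuple[list[DosageMarker], pd.DataFrame]:
    """Generate the dosage-genotype matrix plus exact truth labels.

    Simplex x nulliplex markers segregate Binomial(n_progeny, 0.5) unless
    flagged distorted (present probability ``distortion_p``).  The truth
    table records, per marker, whether dosage rule (a) and the realized
    missingness rule (b) hold exactly.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    markers = []
    truth_rows = []
    positions = np.sort(
        rng.choice(np.arange(1, 10_000_000), size=cfg.n_markers, replace=False)
    )
    for i in range(cfg.n_markers):
        simplex = rng.random() < cfg.simplex_fraction
        if simplex:
            maternal, paternal = 1, 0
        else:
            maternal, paternal = _OFF_TYPE_DOSAGES[
                int(rng.integers(0, len(_OFF_TYPE_DOSAGES)))
            ]
        distorted = simplex and rng.random() < cfg.distortion_fraction
        p_present = (
            cfg.distortion_p if distorted else _present_prob(maternal, paternal)
        )
        calls = []
        for _ in range(cfg.n_progeny):
            if rng.random() < cfg.missing_rate:
                calls.append(MISSING)
            elif rng.random() < p_present:
                calls.append(PRESENT)
            else:
                calls.append(ABSENT)
        m = DosageMarker(
            marker_id=f"m{i + 1:05d}",
            seq_id="chr1",
            position=int(positions[i]),
            maternal_dosage=maternal,
            paternal_dosage=paternal,
            progeny_calls=tuple(calls),
        )
        markers.append(m)
        truth_rows.append(
            {
                "marker_id": m.marker_id,
                "simplex": simplex,
                "distorted": distorted,
                "passes_dosage": maternal == 1 and paternal == 0,
                "passes_missing": m.missing_fraction < cfg.max_missing,
            }
        )
    truth = pd.DataFrame(truth_rows)
    if out_path is not None:
        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        write_marker_tsv(markers, out_path)
        truth.to_csv(
            out_path.with_name(out_path.stem + "_truth.tsv"), sep="\t", index=False
        )
    return markers, truth
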