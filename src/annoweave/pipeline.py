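"""End-to-end evidence-integration pipeline.

Stages run in the order the method prescribes: ORF detection on Iso-Seq
alignments -> alignment filtering and representative selection -> repeat-mask
refinement -> hint filtering/merging/intersection -> seed combination ->
support classification -> summary statistics.  Every stage writes a plain
file in a standard format so any stage can be swapped for real external-tool
output, and a JSON manifest records the configuration and per-stage record
counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .annotation_stats import summarize
from .genomic_model import MaskedGenome, read_bed12, read_gff3, write_gff3
from .hint_integration import (
    HintSet,
    filter_hints,
    intersect_hints,
    merge_hints,
    read_hints_gff,
    write_hints_gff,
)
from .isoseq_processing import (
    filter_alignments,
    isoforms_from_models,
    select_representatives,
)
from .mask_refinement import refine_mask
from .seed_selection import combine_seeds
from .support_classifier import (
    category_counts,
    classify_all,
    records_to_frame,
    select_training,
    supported_orf_intervals,
)

from dataclasses import replace as _replace


@dataclass
class PipelineConfig:
    """Paths and thresholds of a pipeline run; defaults are the method's values."""

    genome: str = ""
    predictions: str = ""
    isoseq: str = ""  # GFF3, or BED12 when isoseq_format == "bed12"
    rnaseq_hints: str = ""
    protein_hints: str = ""
    out_dir: str = "run"
    isoseq_format: str = "gff3"
    min_identity: float = 0.95
    min_coverage: float = 0.90
    min_lorf: int = 300
    max_intron: int = 10_000
    min_cov: int = 3
    training_cov: int = 100
    seed_margin: int = 50
    min_overlap: int = 1
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class PipelineResult:
    manifest: dict
    records: list = field(default_factory=list)
    seeds: list = field(default_factory=list)


class StageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
                raise StageError(name, exc) from exc

        return wrap

    genome = stage("load-genome")(lambda: MaskedGenome.from_fasta(cfg.genome))
    predictions = stage("load-predictions")(lambda: read_gff3(cfg.predictions))
    counts["predictions"] = len(predictions)

    def _load_iso():
        if not cfg.isoseq:
            return []
        if cfg.isoseq_format == "bed12":
            return read_bed12(cfg.isoseq)
        return read_gff3(cfg.isoseq)

    iso_models = stage("load-isoseq")(_load_iso)
    counts["isoseq_alignments"] = len(iso_models)

    # ORFs + alignment filters + representative selection
    isoforms = stage("orfs")(lambda: isoforms_from_models(iso_models, genome))
    passing = stage("filter-alignments")(
        lambda: filter_alignments(isoforms, cfg.min_identity, cfg.min_coverage)
    )
    counts["isoseq_passing_alignment_filters"] = len(passing)
    reps = stage("select-isoforms")(
        lambda: select_representatives(passing, cfg.min_lorf, cfg.max_intron)
    )
    counts["isoseq_representatives"] = len(reps)
    write_gff3([i.transcript for i in reps], out / "isoseq_representatives.gff3")

    # hints
    rnaseq_raw = stage("load-rnaseq-hints")(
        lambda: read_hints_gff(cfg.rnaseq_hints) if cfg.rnaseq_hints else HintSet()
    )
    protein = stage("load-protein-hints")(
        lambda: read_hints_gff(cfg.protein_hints) if cfg.protein_hints else HintSet()
    )
    rnaseq = stage("filter-hints")(lambda: filter_hints(rnaseq_raw, cfg.min_cov))
    training_hints = stage("training-hints")(
        lambda: filter_hints(rnaseq_raw, cfg.training_cov)
    )
    high_conf = stage("intersect-hints")(lambda: intersect_hints(rnaseq, protein))
    merged = stage("merge-hints")(lambda: merge_hints(protein, rnaseq))
    counts["rnaseq_hints"] = len(rnaseq)
    counts["rnaseq_training_hints"] = len(training_hints)
    counts["high_confidence_introns"] = len(high_conf)
    counts["merged_hints"] = len(merged)
    write_hints_gff(merged, out / "merged_hints.gff")
    write_hints_gff(high_conf, out / "high_confidence_introns.gff")

    # mask refinement
    def _refine():
        supported = supported_orf_intervals(reps, rnaseq, protein)
        return refine_mask(genome, supported)

    refined, mask_report = stage("refine-mask")(_refine)
    counts["unmasked_bp"] = mask_report.unmasked_bp
    counts["unmasked_loci"] = mask_report.n_loci
    refined.to_fasta(out / "genome_refined.fa")
    mask_report.to_tsv(out / "mask_report.tsv")

    # seeds
    def _seeds():
        iso_orf_models = []
        for iso in reps:
            pieces = iso.genome_cds()
            if pieces:
                iso_orf_models.append(_replace(iso.transcript, cds=pieces))
        return combine_seeds(predictions, iso_orf_models, cfg.seed_margin)

    seeds = stage("combine-seeds")(_seeds)
    counts["seeds"] = len(seeds)
    counts["seeds_isoseq_origin"] = sum(s.origin == "isoseq" for s in seeds)
    write_gff3(
        [
            s.model.with_attributes(seed_origin=s.origin)
            for s in seeds
        ],
        out / "seeds.gff3",
    )

    # classification
    records = stage("classify")(
        lambda: classify_all(predictions, reps, rnaseq, protein, cfg.min_overlap)
    )
    records_to_frame(records).to_csv(out / "support.tsv", sep="\t", index=False)
    cats = category_counts(records)
    counts.update({f"category_{k}": v for k, v in cats.items()})
    training = select_training(records)
    counts["training_genes"] = len(training)
    (out / "training_ids.txt").write_text("".join(f"{i}\n" for i in training))

    # stats
    summary = stage("stats")(lambda: summarize(predictions, records))
    summary.to_frame().to_csv(out / "summary.tsv", sep="\t", index=False)

    manifest = {
        "version": __version__,
        "config": asdict(cfg),
        "counts": counts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineResult(manifest=manifest, records=records, seeds=seeds)
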