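"""End-to-end orchestration: consensus -> filters -> inheritance -> score
gate -> ACMG report for the variant arm, and rank -> preranked GSEA for the
expression arm. Thin, config-driven layer over the library modules; the CLI
wraps these functions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from Bio import SeqIO

from .acmg import AcmgResult
from .annotations import AnnotationRecord, read_annotation_tsv
from .consequence import annotate_variant
from .genesets import read_gmt
from .gsea import permutation_stats, rank_genes, read_expression_tsv, results_frame
from .pedigree import read_ped
from .prioritization import (
    CandidateVariant,
    classify_candidates,
    FunnelReport,
    ScoreThresholds,
    annotate_cpg,
    detect_compound_het,
    detect_inheritance,
    filter_by_scores,
    filter_nonsilent,
    filter_rare,
    shared_by_affected,
)
from .transcripts import read_transcripts
from .variants import consensus_intersect, normalize_variant
from .vcfio import read_vcf

logger = logging.getLogger(__name__)

TABLE_COLUMNS = ["Chr", "Position", "Ref", "Alt", "Variant", "Effect", "Evidence", "Origin"]


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    vcf_a: Optional[str] = None
    vcf_b: Optional[str] = None
    ped: Optional[str] = None
    annotations: Optional[str] = None
    transcripts_tsv: Optional[str] = None
    cds_fasta: Optional[str] = None
    reference_fasta: Optional[str] = None
    cpg_list: Optional[str] = None
    gmt: Optional[str] = None
    expression: Optional[str] = None
    maf: float = 0.01
    sift: float = 0.05
    polyphen2: float = 0.957
    mcap: float = 0.025
    splice_window: int = 2
    gsea_exponent: float = 1.0
    n_perm: int = 1000
    seed: int = 0
    outdir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self, *, prioritization: bool = False, gsea: bool = False) -> None:
        if not 0 < self.maf <= 1:
            raise ConfigError(f"maf threshold must lie in (0,1], got {self.maf}")
        for name in ("sift", "polyphen2", "mcap"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} threshold must lie in [0,1], got {v}")
        if self.splice_window < 0:
            raise ConfigError("splice_window must be >= 0")
        required = []
        if prioritization:
            required += ["vcf_a", "vcf_b", "ped", "annotations", "transcripts_tsv",
                         "cds_fasta", "reference_fasta"]
        if gsea:
            required += ["gmt", "expression"]
        for name in required:
            p = getattr(self, name)
            if p is None:
                raise ConfigError(f"config field {name} is required")
            if not Path(p).exists():
                raise ConfigError(f"{name}: path does not exist: {p}")

    def score_thresholds(self) -> ScoreThresholds:
        return ScoreThresholds(sift_max=self.sift, polyphen2_min=self.polyphen2, mcap_min=self.mcap)

    def write_resolved(self, outdir: Path) -> None:
        (outdir / "config.resolved.yaml").write_text(yaml.safe_dump(asdict(self), sort_keys=True))


@dataclass
class PrioritizationOutput:
    report: FunnelReport
    table: pd.DataFrame
    candidates: list[CandidateVariant] = field(default_factory=list)

    @property
    def pathogenic(self) -> list[CandidateVariant]:
        return [c for c in self.candidates
                if c.acmg is not None and c.acmg.classification == "pathogenic"]


def _effect_label(result: AcmgResult) -> str:
    if result.classification == "uncertain_significance" and not result.conflict:
        return "Not enough evidence"
    return result.label()


def run_prioritization(config: PipelineConfig) -> PrioritizationOutput:
    """Execute the variant-prioritization funnel in order, logging each
    stage's count, and return the funnel report plus the candidate table."""
    config.validate(prioritization=True)
    reference = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(config.reference_fasta, "fasta")}

    def ref_lookup(chrom: str, pos: int) -> str:
        return reference[chrom][pos - 1]

    calls_a = read_vcf(config.vcf_a, "caller_a")
    calls_b = read_vcf(config.vcf_b, "caller_b")
    for recs in (calls_a, calls_b):
        for rec in recs:
            rec.variant = normalize_variant(rec.variant, ref_lookup)
    consensus = consensus_intersect(calls_a, calls_b)
    logger.info("consensus: %d of %d/%d caller records", len(consensus), len(calls_a), len(calls_b))

    ped = read_ped(config.ped)
    transcripts = read_transcripts(config.transcripts_tsv, config.cds_fasta)
    ann_table = read_annotation_tsv(config.annotations)

    candidates: list[CandidateVariant] = []
    for rec in consensus:
        consequence = annotate_variant(rec.variant, transcripts, config.splice_window)
        annotation = ann_table.get(rec.key)
        if annotation is None:
            annotation = AnnotationRecord(key=rec.key, gene=consequence.gene)
        candidates.append(
            CandidateVariant(
                variant=rec.variant,
                consequence=consequence,
                annotation=annotation,
                genotypes={c.sample: c for c in rec.calls},
            )
        )

    report = FunnelReport(total=len(candidates))
    stage = filter_rare(candidates, threshold=config.maf)
    report.rare = len(stage)
    logger.info("rare (MAF<%g in all sources): %d", config.maf, report.rare)
    stage = filter_nonsilent(stage)
    stage = shared_by_affected(stage, ped)
    report.non_silent_shared = len(stage)
    logger.info("non-silent, shared by affected: %d", report.non_silent_shared)

    if config.cpg_list:
        cpg_genes = [g.strip() for g in Path(config.cpg_list).read_text().split() if g.strip()]
    else:
        cpg_genes = [a.gene for a in ann_table.values() if a.is_cpg_gene]
    stage = annotate_cpg(stage, cpg_genes)
    report.cpg = sum(1 for c in stage if c.annotation.is_cpg_gene)

    for c in stage:
        detect_inheritance(c, ped)
    detect_compound_het(stage, ped)
    pattern_counts: dict[str, int] = {}
    for c in stage:
        for p in c.patterns:
            pattern_counts[p] = pattern_counts.get(p, 0) + 1
    report.per_pattern = pattern_counts
    logger.info("inheritance patterns: %s", pattern_counts or "none")

    stage = filter_by_scores(stage, config.score_thresholds())
    report.score_passing = len(stage)
    logger.info("score gate survivors: %d", report.score_passing)

    report.pathogenic = classify_candidates(stage)
    report.acmg_classified = len(stage)
    logger.info("ACMG pathogenic: %d", report.pathogenic)

    rows = []
    for c in stage:
        descriptor = c.consequence.hgvs_p or c.consequence.hgvs_c or c.consequence.category
        rows.append(
            {
                "Chr": c.variant.chrom,
                "Position": c.variant.pos,
                "Ref": c.variant.ref,
                "Alt": c.variant.alt,
                "Variant": f"{c.gene}.{descriptor}" if c.gene else descriptor,
                "Effect": _effect_label(c.acmg),
                "Evidence": c.annotation.evidence,
                "Origin": c.origin,
                "Category": c.consequence.category,
                "Patterns": ";".join(sorted(c.patterns)),
                "CpG": c.annotation.is_cpg_gene,
            }
        )
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS + ["Category", "Patterns", "CpG"])

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
        (outdir / "funnel.json").write_text(json.dumps(report.to_dict(), indent=1, sort_keys=True))
        (outdir / "funnel.txt").write_text(report.to_text() + "\n")
        config.write_resolved(outdir)
    return PrioritizationOutput(report=report, table=table, candidates=stage)


def run_gsea(config: PipelineConfig) -> pd.DataFrame:
    """Rank genes by log2 fold change and run preranked GSEA; results are
    sorted by NES (descending) and persisted alongside the ranked list."""
    config.validate(gsea=True)
    case, control = read_expression_tsv(config.expression)
    sets = read_gmt(config.gmt)
    ranked = rank_genes(case, control)
    results = permutation_stats(
        ranked, sets, n_perm=config.n_perm, seed=config.seed, exponent=config.gsea_exponent
    )
    df = results_frame(results)
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ranked.to_frame().to_csv(outdir / "ranked_genes.tsv", sep="\t", index=False)
        df.to_csv(outdir / "gsea_results.tsv", sep="\t", index=False)
        config.write_resolved(outdir)
    return df
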