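"""The candidate-variant funnel: rarity, non-silent consequence, shared-by-
affected carriage, cancer-predisposition-gene flags, Mendelian inheritance
patterns (de novo / autosomal recessive / X-linked / compound heterozygous
by transmission), and the four-score in-silico gate for missense variants.

Every filter returns a subset of its input, so the funnel counts are
non-increasing along the main path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .acmg import AcmgResult, classify_evidence_string
from .annotations import AnnotationRecord
from .consequence import Consequence
from .pedigree import Pedigree, PedigreeMember
from .variants import GenomicVariant, GenotypeCall

logger = logging.getLogger(__name__)

FREQUENCY_SOURCES = ("kg_asian", "exac_nontcga")
X_NAMES = frozenset({"X", "chrX"})


class PrioritizationError(ValueError):
    pass


@dataclass
class ScoreThresholds:
    """The in-silico gate for rare missense variants: all four must pass."""

    sift_max: float = 0.05  # damaging when small (inclusive)
    polyphen2_min: float = 0.957  # probably-damaging cutoff (inclusive)
    mutation_taster: str = "disease_causing"
    mcap_min: float = 0.025  # strict: score must exceed this


@dataclass
class CandidateVariant:
    variant: GenomicVariant
    consequence: Consequence
    annotation: AnnotationRecord
    genotypes: dict[str, GenotypeCall]
    patterns: set[str] = field(default_factory=set)
    origin: str = "undetermined"  # maternal | paternal | both | de_novo | undetermined
    compound_het_partner: Optional[tuple[str, int, str, str]] = None
    acmg: Optional[AcmgResult] = None

    @property
    def key(self):
        return self.variant.key

    @property
    def gene(self) -> str:
        return self.annotation.gene


@dataclass
class FunnelReport:
    """Stage-by-stage variant counts mirroring the prioritization workflow."""

    total: int = 0
    rare: int = 0
    non_silent_shared: int = 0
    cpg: int = 0
    per_pattern: dict[str, int] = field(default_factory=dict)
    score_passing: int = 0
    acmg_classified: int = 0
    pathogenic: int = 0

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "rare": self.rare,
            "non_silent_shared": self.non_silent_shared,
            "cpg": self.cpg,
            "per_pattern": dict(self.per_pattern),
            "score_passing": self.score_passing,
            "acmg_classified": self.acmg_classified,
            "pathogenic": self.pathogenic,
        }

    def to_text(self) -> str:
        lines = [
            f"consensus variants        {self.total}",
            f"rare (MAF filter)         {self.rare}",
            f"non-silent, shared        {self.non_silent_shared}",
            f"cancer predisposition     {self.cpg}",
        ]
        for pattern, n in sorted(self.per_pattern.items()):
            lines.append(f"pattern {pattern:<18}{n}")
        lines += [
            f"score gate survivors      {self.score_passing}",
            f"ACMG classified           {self.acmg_classified}",
            f"pathogenic                {self.pathogenic}",
        ]
        return "\n".join(lines)


def _is_x(chrom: str) -> bool:
    return chrom in X_NAMES or chrom.removeprefix("chr") == "X"


def filter_rare(
    candidates: Sequence[CandidateVariant],
    threshold: float = 0.01,
    sources: Sequence[str] = FREQUENCY_SOURCES,
) -> list[CandidateVariant]:
    """Keep variants rare (frequency < threshold, or absent) in EVERY source.

    Missing frequencies count as rare — the usual absent-from-controls
    convention, which also feeds the PM2 suggestion.
    """
    if not 0 < threshold <= 1:
        raise PrioritizationError(f"threshold must lie in (0,1], got {threshold}")
    for src in sources:
        if src not in FREQUENCY_SOURCES:
            raise PrioritizationError(f"unknown frequency source {src!r}; valid: {FREQUENCY_SOURCES}")
    out = []
    for c in candidates:
        freqs = c.annotation.frequencies
        if all(freqs[src] is None or freqs[src] < threshold for src in sources):
            out.append(c)
    return out


def filter_nonsilent(candidates: Sequence[CandidateVariant]) -> list[CandidateVariant]:
    """Drop synonymous and non-coding candidates."""
    for c in candidates:
        if c.consequence is None:
            raise PrioritizationError(f"candidate {c.variant} lacks a consequence annotation")
    return [c for c in candidates if c.consequence.is_non_silent]


def shared_by_affected(candidates: Sequence[CandidateVariant], ped: Pedigree) -> list[CandidateVariant]:
    """Keep variants where every affected member carries >=1 alternate allele
    (hemizygous alternate counts as carriage)."""
    affected = ped.affected
    if len(affected) < 2:
        raise PrioritizationError(
            "shared-by-affected filtering needs >=2 affected members; "
            "single-proband prioritization is out of scope"
        )
    out = []
    for c in candidates:
        carried = all(
            m.id in c.genotypes
            and not c.genotypes[m.id].is_missing
            and c.genotypes[m.id].carries_alt
            for m in affected
        )
        if carried:
            out.append(c)
    return out


def _genotypes_complete(c: CandidateVariant, members: Iterable[PedigreeMember]) -> bool:
    return all(m.id in c.genotypes and not c.genotypes[m.id].is_missing for m in members)


def detect_inheritance(candidate: CandidateVariant, ped: Pedigree) -> CandidateVariant:
    """Assign trio inheritance patterns and parental origin.

    de novo: an affected child carries the alternate while both parents are
    homozygous reference. Autosomal recessive: every affected child is
    homozygous alternate with both parents heterozygous. X-linked: chrX
    variant, every affected male hemizygous/homozygous alternate, mother a
    carrier, father reference (father-to-son X transmission is impossible).
    Origin records which parent carries the alternate allele.
    """
    children = [m for m in ped.children_with_parents() if m.affected]
    if not children:
        return candidate
    parents: set[str] = set()
    for child in children:
        parents.update([child.father, child.mother])
    needed = children + [ped.member(p) for p in parents]
    if not _genotypes_complete(candidate, needed):
        logger.warning("missing family genotype at %s; inheritance patterns skipped", candidate.key)
        return replace_patterns(candidate, set(), "undetermined")

    patterns: set[str] = set()
    fathers = {ped.member(c.father) for c in children}
    mothers = {ped.member(c.mother) for c in children}
    father_carries = any(candidate.genotypes[f.id].carries_alt for f in fathers)
    mother_carries = any(candidate.genotypes[m.id].carries_alt for m in mothers)
    child_gts = [candidate.genotypes[c.id] for c in children]

    if any(gt.carries_alt for gt in child_gts) and not father_carries and not mother_carries:
        patterns.add("de_novo")
    if (
        not _is_x(candidate.variant.chrom)
        and all(gt.is_hom_alt and not gt.is_hemizygous for gt in child_gts)
        and all(candidate.genotypes[f.id].is_het for f in fathers)
        and all(candidate.genotypes[m.id].is_het for m in mothers)
    ):
        patterns.add("autosomal_recessive")
    if _is_x(candidate.variant.chrom):
        males = [c for c in children if c.sex == "male"]
        if (
            males
            and all(candidate.genotypes[c.id].is_hom_alt for c in males)
            and mother_carries
            and not father_carries
        ):
            patterns.add("x_linked")

    if father_carries and mother_carries:
        origin = "both"
    elif mother_carries:
        origin = "maternal"
    elif father_carries:
        origin = "paternal"
    else:
        origin = "de_novo" if any(gt.carries_alt for gt in child_gts) else "undetermined"
    return replace_patterns(candidate, patterns, origin)


def replace_patterns(c: CandidateVariant, patterns: set[str], origin: str) -> CandidateVariant:
    c.patterns = patterns
    c.origin = origin
    return c


def detect_compound_het(
    candidates: Sequence[CandidateVariant], ped: Pedigree
) -> list[tuple[CandidateVariant, CandidateVariant]]:
    """Flag trans-configured variant pairs within one gene, phased by
    transmission: every affected child heterozygous at both sites, one
    variant carried by the mother only and the other by the father only.
    Pairs with the same parental origin (cis by transmission) or with a
    variant present in both parents (phase unresolvable) are never flagged.
    """
    children = [m for m in ped.children_with_parents() if m.affected]
    if not children:
        return []
    by_gene: dict[str, list[CandidateVariant]] = {}
    for c in candidates:
        if not c.gene:
            logger.warning("candidate %s has no gene symbol; skipped for compound het", c.key)
            continue
        by_gene.setdefault(c.gene.upper(), []).append(c)

    pairs: list[tuple[CandidateVariant, CandidateVariant]] = []
    for gene, group in by_gene.items():
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                a, b = group[i], group[j]
                if not (_genotypes_complete(a, ped.members) and _genotypes_complete(b, ped.members)):
                    continue
                if not all(
                    a.genotypes[c.id].is_het and b.genotypes[c.id].is_het for c in children
                ):
                    continue
                if {a.origin, b.origin} == {"maternal", "paternal"}:
                    pairs.append((a, b))
                    for cand, partner in ((a, b), (b, a)):
                        cand.patterns.add("compound_het")
                        cand.compound_het_partner = partner.key
    return pairs


def filter_by_scores(
    candidates: Sequence[CandidateVariant], thresholds: Optional[ScoreThresholds] = None
) -> list[CandidateVariant]:
    """Apply the four-score pathogenicity gate to nonsynonymous candidates.

    A missense candidate passes only when SIFT <= sift_max, PolyPhen2 >=
    polyphen2_min, MutationTaster calls it disease-causing, and M-CAP >
    mcap_min; a missing score fails the gate. All other categories
    (truncating, initial-codon, splicing, indels) pass through untouched.
    """
    th = thresholds or ScoreThresholds()
    out = []
    for c in candidates:
        if c.consequence.category != "nonsynonymous":
            out.append(c)
            continue
        a = c.annotation
        ok = (
            a.sift is not None
            and a.sift <= th.sift_max
            and a.polyphen2 is not None
            and a.polyphen2 >= th.polyphen2_min
            and a.mutation_taster is not None
            and a.mutation_taster == th.mutation_taster
            and a.mcap is not None
            and a.mcap > th.mcap_min
        )
        if ok:
            out.append(c)
    return out


def classify_candidates(candidates: Sequence[CandidateVariant]) -> int:
    """Attach an ACMG result to each candidate from its curated evidence
    string (evidence assignment is an input, never auto-derived) and return
    the number classified pathogenic. Evidence-free candidates are uncertain
    significance with a warning."""
    n_pathogenic = 0
    for c in candidates:
        if c.annotation.evidence:
            c.acmg = classify_evidence_string(c.annotation.evidence)
        else:
            logger.warning("candidate %s carries no curated ACMG evidence", c.key)
            c.acmg = AcmgResult(classification="uncertain_significance")
        if c.acmg.classification == "pathogenic":
            n_pathogenic += 1
    return n_pathogenic


def annotate_cpg(
    candidates: Sequence[CandidateVariant], cpg_genes: Iterable[str]
) -> list[CandidateVariant]:
    """Flag candidates in cancer-predisposition genes (case-insensitive
    symbol match); removes nothing."""
    genes = {g.upper() for g in cpg_genes}
    if not genes:
        logger.warning("empty cancer-predisposition gene list: no candidate will be flagged")
    for c in candidates:
        c.annotation.is_cpg_gene = bool(c.gene) and c.gene.upper() in genes
    return list(candidates)
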