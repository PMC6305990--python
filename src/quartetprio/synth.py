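"""Synthetic quartet cohorts with planted, truth-tagged variants, plus
two-condition expression matrices with a planted up-regulated pathway.

The generator emulates the study design the prioritization funnel assumes: a
nuclear family of two healthy parents and two affected sons, genotyped by
two callers. Genotypes are CONSTRUCTED per inheritance class, not sampled
from population models, so the quartet must never be treated as a
Hardy-Weinberg sample. Every planted variant is recorded in a truth table
(class, parental origin, should-survive flag) written alongside the data.

The two signature plants mirror a real compound lesion pair: an autosomal
stop-gain at codon 536 of a long gene (CGA -> TGA at CDS position 1606,
maternal dominant transmission) and an X-linked initiator-codon substitution
(c.3G>T) whose re-initiation at codon 6 deletes the first five residues,
hemizygous in both sons.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotations import AnnotationRecord, write_annotation_tsv
from .consequence import classify
from .genesets import GeneSetCollection, write_gmt
from .gsea import write_expression_tsv
from .pedigree import Pedigree, PedigreeMember, write_ped
from .transcripts import STOP_CODONS, TranscriptModel, write_transcripts
from .variants import (
    GenomicVariant,
    GenotypeCall,
    VariantRecord,
    apply_variant,
    normalize_variant,
)
from .vcfio import write_vcf

FATHER, MOTHER, SON1, SON2 = "FATHER", "MOTHER", "SON1", "SON2"
SAMPLES = (FATHER, MOTHER, SON1, SON2)

APC_LIKE = "APCL"  # autosomal, codon 536 is CGA -> stop-gain target
WAS_LIKE = "WASL"  # chrX, codon 6 is ATG -> start-loss re-initiation target

# Table-2-style curated evidence for the signature plants (input, not derived)
EVIDENCE_STOPGAIN = "PVS1, PS1, PP1-S, PM2, PP3, BP1"
EVIDENCE_STARTLOSS = "PS1, PS3, PM2, PM4, PP3"
EVIDENCE_GATE_SURVIVOR = "PM2, PP3, BP4, PM5"

_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SENSE_CODONS = [c for c in _CODONS if c not in STOP_CODONS]


class SimulationError(ValueError):
    pass


@dataclass
class PlantSpec:
    """Per-class plant counts for one simulated quartet.

    Defaults are the study conditions the funnel targets: both signature
    plants present, compound heterozygotes in three genes, no de novo and no
    autosomal-recessive hits among the shared variants, and a background of
    mostly-common variants (so the rarity filter removes ~99% of it).
    """

    shared_maternal_dominant_stopgain: int = 1
    shared_xlinked_startloss: int = 1
    compound_het_pairs: int = 3
    de_novo_singletons: int = 0
    ar_homozygous: int = 0
    common_benign: int = 150
    silent_shared: int = 10
    caller_discordant: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if name != "seed" and value < 0:
                raise SimulationError(f"{name} must be >= 0")
        if self.shared_maternal_dominant_stopgain > 1 or self.shared_xlinked_startloss > 1:
            raise SimulationError("at most one of each signature plant per family")


@dataclass
class QuartetDataset:
    records_a: list[VariantRecord]
    records_b: list[VariantRecord]
    pedigree: Pedigree
    annotations: list[AnnotationRecord]
    transcripts: list[TranscriptModel]
    reference: dict[str, str]
    cpg_genes: list[str]
    truth: dict[str, dict]  # "chrom:pos:ref:alt" -> class/origin/should_survive

    def ref_lookup(self) -> Callable[[str, int], str]:
        ref = self.reference
        return lambda chrom, pos: ref[chrom][pos - 1]


def default_pedigree() -> Pedigree:
    return Pedigree(
        members=[
            PedigreeMember(id=FATHER, father=None, mother=None, sex="male", affected=False),
            PedigreeMember(id=MOTHER, father=None, mother=None, sex="female", affected=False),
            PedigreeMember(id=SON1, father=FATHER, mother=MOTHER, sex="male", affected=True),
            PedigreeMember(id=SON2, father=FATHER, mother=MOTHER, sex="male", affected=True),
        ]
    )


def _random_cds(rng: np.random.Generator, n_codons: int, forced: dict[int, str]) -> str:
    """Random CDS of n_codons sense codons plus a stop; 1-based forced codons."""
    codons = ["ATG"]
    for i in range(2, n_codons + 1):
        codons.append(_SENSE_CODONS[rng.integers(len(_SENSE_CODONS))])
    for idx, codon in forced.items():
        codons[idx - 1] = codon
    codons.append(("TAA", "TAG", "TGA")[rng.integers(3)])
    return "".join(codons)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))


def make_toy_genes(
    n_genes: int = 24, seed: int = 0
) -> tuple[list[TranscriptModel], dict[str, str]]:
    """Build toy transcript models and a matching reference genome.

    One gene per chromosome. Two designated genes carry the signature
    coordinate facts: APCL (autosomal) has codon CGA at CDS positions
    1606-1608, WASL (on chrX) has ATG at codon 6 with no earlier in-frame
    ATG, and a proline at codon 5 so re-initiation reads p.M1-P5del. Roughly
    a quarter of the remaining genes are placed on the minus strand.
    """
    if n_genes < 2:
        raise SimulationError("need at least the two signature genes")
    rng = np.random.default_rng(seed)
    specs: list[tuple[str, str, str, int, dict[int, str]]] = []
    # (gene, chrom, strand, n_codons, forced codons)
    specs.append((APC_LIKE, "chr5", "+", 540, {536: "CGA"}))
    was_forced = {k: _SENSE_CODONS[rng.integers(len(_SENSE_CODONS))] for k in (2, 3, 4)}
    for k in (2, 3, 4):
        while was_forced[k] == "ATG":
            was_forced[k] = _SENSE_CODONS[rng.integers(len(_SENSE_CODONS))]
    was_forced[5] = "CCA"  # proline
    was_forced[6] = "ATG"
    specs.append((WAS_LIKE, "chrX", "+", 120, was_forced))
    chrom_no = 0
    for i in range(n_genes - 2):
        chrom_no += 1
        if chrom_no == 5:
            chrom_no += 1
        strand = "-" if i % 4 == 3 else "+"
        specs.append((f"G{i + 1:03d}", f"chr{chrom_no}", strand, int(rng.integers(60, 121)), {}))

    models: list[TranscriptModel] = []
    reference: dict[str, str] = {}
    for gene, chrom, strand, n_codons, forced in specs:
        cds = _random_cds(rng, n_codons, forced)
        n_exons = int(rng.integers(1, 4))
        # split CDS into n_exons chunks (transcript order), each >= 20 nt
        if n_exons > 1 and len(cds) > 20 * n_exons:
            cuts = sorted(rng.choice(np.arange(20, len(cds) - 20), size=n_exons - 1, replace=False))
            while any(b - a < 20 for a, b in zip(cuts, cuts[1:])):
                cuts = sorted(rng.choice(np.arange(20, len(cds) - 20), size=n_exons - 1, replace=False))
            bounds = [0] + list(cuts) + [len(cds)]
        else:
            n_exons = 1
            bounds = [0, len(cds)]
        chunks_tx = [cds[bounds[i] : bounds[i + 1]] for i in range(n_exons)]
        # genomic order of chunks: forward for +, reversed (and RC'd) for -
        chunks_gen = chunks_tx if strand == "+" else [
            str(Seq(c).reverse_complement()) for c in reversed(chunks_tx)
        ]
        flank = 80
        seq_parts = [_random_seq(rng, flank)]
        exons: list[tuple[int, int]] = []
        pos = flank + 1
        for i, chunk in enumerate(chunks_gen):
            exons.append((pos, pos + len(chunk) - 1))
            seq_parts.append(chunk)
            pos += len(chunk)
            if i < len(chunks_gen) - 1:
                intron = int(rng.integers(60, 151))
                seq_parts.append(_random_seq(rng, intron))
                pos += intron
        seq_parts.append(_random_seq(rng, flank))
        reference[chrom] = "".join(seq_parts)
        models.append(
            TranscriptModel(gene=gene, chrom=chrom, strand=strand, exons=tuple(exons), sequence=cds)
        )
    return models, reference


def _transcript(models: list[TranscriptModel], gene: str) -> TranscriptModel:
    for t in models:
        if t.gene == gene:
            return t
    raise SimulationError(f"gene {gene!r} not in the toy gene build")


def _snv_at_cds(t: TranscriptModel, reference: dict[str, str], cds_pos: int, alt_sense: str) -> GenomicVariant:
    gpos = t.cds_to_genomic(cds_pos)
    gref = reference[t.chrom][gpos - 1]
    galt = alt_sense if t.strand == "+" else str(Seq(alt_sense).complement())
    return GenomicVariant(chrom=t.chrom, pos=gpos, ref=gref, alt=galt)


def _pick_coding_snv(
    rng: np.random.Generator,
    t: TranscriptModel,
    reference: dict[str, str],
    used: set[tuple[str, int]],
    want_category: str,
) -> GenomicVariant:
    """Rejection-sample an exonic SNV of the requested consequence category
    (validated with the package's own classifier; plants at designed
    coordinates do not go through this path)."""
    for _ in range(3000):
        cds_pos = int(rng.integers(4, t.cds_length - 3))
        gpos = t.cds_to_genomic(cds_pos)
        if (t.chrom, gpos) in used:
            continue
        ref_sense = t.sequence[cds_pos - 1]
        alt_sense = "ACGT"[rng.integers(4)]
        if alt_sense == ref_sense:
            continue
        v = _snv_at_cds(t, reference, cds_pos, alt_sense)
        if classify(t, v).category == want_category:
            used.add((t.chrom, gpos))
            return v
    raise SimulationError(f"could not place a {want_category} SNV in {t.gene}")


def _right_shift(v: GenomicVariant, reference: dict[str, str], window: int = 25) -> GenomicVariant:
    """Rightmost equivalent representation of an anchored deletion (brute
    force over a local window): used to perturb caller B's notation without
    changing the edited haplotype. Non-deletions are returned unchanged."""
    if len(v.alt) != 1 or len(v.ref) <= 1:
        return v
    chrom_seq = reference[v.chrom]
    lo = max(1, v.pos - 1)
    hi = min(len(chrom_seq), v.end + window)
    context = chrom_seq[lo - 1 : hi]
    target = apply_variant(context, lo, v)
    best = v
    span = len(v.ref)
    for pos in range(v.pos + 1, hi - span + 2):
        ref = chrom_seq[pos - 1 : pos - 1 + span]
        if len(ref) < span or ref[0] == ref:
            continue
        try:
            cand = GenomicVariant(chrom=v.chrom, pos=pos, ref=ref, alt=ref[0])
            if apply_variant(context, lo, cand) == target:
                best = cand
        except ValueError:
            continue
    return best


def _quartet_calls(
    father: tuple[int, ...], mother: tuple[int, ...], son1: tuple[int, ...], son2: tuple[int, ...]
) -> list[GenotypeCall]:
    gts = {FATHER: father, MOTHER: mother, SON1: son1, SON2: son2}
    return [GenotypeCall(sample=s, alleles=gts[s]) for s in SAMPLES]


def _key_str(v: GenomicVariant) -> str:
    return f"{v.chrom}:{v.pos}:{v.ref}:{v.alt}"


def simulate_quartet(
    spec: PlantSpec,
    genes: list[TranscriptModel],
    reference: dict[str, str],
) -> QuartetDataset:
    """Emit two caller VCFs, pedigree, annotations, and a truth table.

    Caller B differs from caller A only in representation (indels
    right-shifted) and in lacking/adding the caller-discordant plants;
    everything else is content-identical, so consensus intersection plus
    normalization must recover exactly the jointly-called set.
    """
    rng = np.random.default_rng(spec.seed)
    ped = default_pedigree()
    apcl = _transcript(genes, APC_LIKE)
    wasl = _transcript(genes, WAS_LIKE)
    autosomal = [t for t in genes if t.chrom != "chrX" and t.gene != APC_LIKE]
    if spec.shared_xlinked_startloss and wasl.chrom != "chrX":
        raise SimulationError("X-linked plant requires a chrX gene")
    if len(autosomal) < spec.compound_het_pairs + 2:
        raise SimulationError("not enough autosomal genes for the requested compound-het pairs")

    used: set[tuple[str, int]] = set()
    gene_of_chrom = {t.chrom: t.gene for t in genes}
    records: list[tuple[VariantRecord, bool, bool]] = []  # (record, in_a, in_b)
    annotations: list[AnnotationRecord] = []
    truth: dict[str, dict] = {}

    def failing_scores() -> dict:
        """Background in-silico scores; any accidental four-way pass is
        broken by resampling SIFT above its cutoff (gate pass rate 0 for
        background by construction)."""
        s = {
            "sift": float(rng.beta(0.8, 3.0)),
            "polyphen2": float(rng.beta(2.0, 2.0)),
            "mutation_taster": "disease_causing" if rng.random() < 0.3 else "polymorphism",
            "mcap": float(rng.beta(1.0, 12.0)),
        }
        if (
            s["sift"] <= 0.05
            and s["polyphen2"] >= 0.957
            and s["mutation_taster"] == "disease_causing"
            and s["mcap"] > 0.025
        ):
            s["sift"] = float(rng.uniform(0.06, 1.0))
        return s

    def add(
        v: GenomicVariant,
        calls: list[GenotypeCall],
        cls: str,
        origin: str,
        survive: bool,
        *,
        af: Optional[tuple[float, float]] = None,
        scores: Optional[dict] = None,
        evidence: str = "",
        in_a: bool = True,
        in_b: bool = True,
    ) -> None:
        records.append((VariantRecord(variant=v, calls=calls), in_a, in_b))
        sc = scores or {}
        annotations.append(
            AnnotationRecord(
                key=v.key,
                gene=gene_of_chrom[v.chrom],
                af_kg_asian=af[0] if af else None,
                af_exac_nontcga=af[1] if af else None,
                sift=sc.get("sift"),
                polyphen2=sc.get("polyphen2"),
                mutation_taster=sc.get("mutation_taster"),
                mcap=sc.get("mcap"),
                evidence=evidence,
            )
        )
        truth[_key_str(v)] = {"class": cls, "origin": origin, "should_survive": survive}

    # --- signature plants -------------------------------------------------
    if spec.shared_maternal_dominant_stopgain:
        v = _snv_at_cds(apcl, reference, 1606, "T")  # CGA -> TGA at codon 536
        used.add((v.chrom, v.pos))
        add(
            v,
            _quartet_calls((0, 0), (0, 1), (0, 1), (0, 1)),
            "maternal_dominant_stopgain",
            "maternal",
            True,
            evidence=EVIDENCE_STOPGAIN,
        )
    if spec.shared_xlinked_startloss:
        v = _snv_at_cds(wasl, reference, 3, "T")  # ATG -> ATT initiator loss
        used.add((v.chrom, v.pos))
        add(
            v,
            _quartet_calls((0,), (0, 1), (1,), (1,)),
            "xlinked_startloss",
            "maternal",
            True,
            evidence=EVIDENCE_STARTLOSS,
        )

    # --- compound heterozygous pairs -------------------------------------
    ch_genes = [autosomal[i] for i in rng.choice(len(autosomal), size=spec.compound_het_pairs, replace=False)]
    for pair_no, t in enumerate(ch_genes):
        v_mat = _pick_coding_snv(rng, t, reference, used, "nonsynonymous")
        v_pat = _pick_coding_snv(rng, t, reference, used, "nonsynonymous")
        add(
            v_mat,
            _quartet_calls((0, 0), (0, 1), (0, 1), (0, 1)),
            "compound_het",
            "maternal",
            False,
            scores=failing_scores(),
        )
        # the first pair's paternal variant survives the score gate (but not
        # the evidence-combining step), exercising the full funnel tail
        survivor = pair_no == 0
        add(
            v_pat,
            _quartet_calls((0, 1), (0, 0), (0, 1), (0, 1)),
            "compound_het",
            "paternal",
            False,
            scores=(
                {"sift": 0.01, "polyphen2": 0.99, "mutation_taster": "disease_causing", "mcap": 0.03}
                if survivor
                else failing_scores()
            ),
            evidence=EVIDENCE_GATE_SURVIVOR if survivor else "",
        )

    remaining = [t for t in autosomal if t not in ch_genes]

    def pick_gene() -> TranscriptModel:
        return remaining[int(rng.integers(len(remaining)))]

    # --- de novo singletons (one son only -> not shared) ------------------
    for _ in range(spec.de_novo_singletons):
        v = _pick_coding_snv(rng, pick_gene(), reference, used, "nonsynonymous")
        carrier = (0, 1) if rng.random() < 0.5 else (0, 0)
        son1_gt, son2_gt = (carrier, (0, 0)) if carrier == (0, 1) else ((0, 1), (0, 0))
        add(v, _quartet_calls((0, 0), (0, 0), son1_gt, son2_gt), "de_novo", "de_novo", False,
            scores=failing_scores())

    # --- autosomal recessive homozygotes ----------------------------------
    for _ in range(spec.ar_homozygous):
        v = _pick_coding_snv(rng, pick_gene(), reference, used, "nonsynonymous")
        add(v, _quartet_calls((0, 1), (0, 1), (1, 1), (1, 1)), "ar_homozygous", "both", False,
            scores=failing_scores())

    # --- silent shared variants -------------------------------------------
    for _ in range(spec.silent_shared):
        v = _pick_coding_snv(rng, pick_gene(), reference, used, "synonymous")
        add(v, _quartet_calls((0, 0), (0, 1), (0, 1), (0, 1)), "silent_shared", "maternal", False)

    # --- caller-discordant plants (drop out at consensus) ------------------
    for i in range(spec.caller_discordant):
        v = _pick_coding_snv(rng, pick_gene(), reference, used, "nonsynonymous")
        add(
            v,
            _quartet_calls((0, 0), (0, 1), (0, 1), (0, 1)),
            "caller_discordant",
            "maternal",
            False,
            scores=failing_scores(),
            in_a=(i % 2 == 0),
            in_b=(i % 2 == 1),
        )

    # --- common background (mostly removed by the rarity filter) ----------
    for i in range(spec.common_benign):
        t = pick_gene()
        as_deletion = rng.random() < 0.2
        if as_deletion:
            v = None
            for _ in range(200):
                cds_pos = int(rng.integers(4, t.cds_length - 6))
                gpos = t.cds_to_genomic(cds_pos)
                del_len = int(rng.integers(1, 4))
                if any((t.chrom, p) in used for p in range(gpos - 1, gpos + del_len + 1)):
                    continue
                # keep anchor and deleted bases fully exonic
                if t.genomic_to_cds(gpos - 1) is None or t.genomic_to_cds(gpos + del_len) is None:
                    continue
                ref = reference[t.chrom][gpos - 2 : gpos + del_len - 1]
                try:
                    raw = GenomicVariant(chrom=t.chrom, pos=gpos - 1, ref=ref, alt=ref[0])
                    # caller A carries the left-aligned (normalized) form
                    v = normalize_variant(raw, lambda c, p: reference[c][p - 1])
                except ValueError:
                    continue
                for p in range(gpos - 1, gpos + del_len + 1):
                    used.add((t.chrom, p))
                break
            if v is None:
                continue
        else:
            try:
                v = _pick_coding_snv(rng, t, reference, used, "nonsynonymous")
            except SimulationError:
                continue
        af = (float(rng.uniform(0.02, 0.5)), float(rng.uniform(0.02, 0.5)))
        father = (0, int(rng.random() < 0.5))
        mother = (0, int(rng.random() < 0.5))
        son1 = (father[rng.integers(2)], mother[rng.integers(2)])
        son2 = (father[rng.integers(2)], mother[rng.integers(2)])
        calls = _quartet_calls(father, mother, tuple(sorted(son1)), tuple(sorted(son2)))
        add(v, calls, "common_benign", "undetermined", False, af=af,
            scores=failing_scores() if not as_deletion else None)

    # --- assemble the two caller views -------------------------------------
    order = sorted(range(len(records)), key=lambda i: (records[i][0].variant.chrom, records[i][0].variant.pos))
    records_a: list[VariantRecord] = []
    records_b: list[VariantRecord] = []
    for i in order:
        rec, in_a, in_b = records[i]
        if in_a:
            records_a.append(rec)
        if in_b:
            if rec.variant.is_indel:
                shifted = _right_shift(rec.variant, reference)
                records_b.append(VariantRecord(variant=shifted, calls=rec.calls))
            else:
                records_b.append(rec)

    cpg_pool = [t.gene for t in autosomal]
    cpg_genes = [APC_LIKE] + [cpg_pool[i] for i in rng.choice(len(cpg_pool), size=2, replace=False)]
    for a in annotations:
        a.is_cpg_gene = a.gene in cpg_genes

    return QuartetDataset(
        records_a=records_a,
        records_b=records_b,
        pedigree=ped,
        annotations=annotations,
        transcripts=genes,
        reference=reference,
        cpg_genes=cpg_genes,
        truth=truth,
    )


def audit_truth_table(data: QuartetDataset) -> None:
    """Re-derive each planted variant's class from the emitted genotypes and
    check it matches the intention; raises on any mismatch."""
    by_key = {}
    for rec, source in [(r, "a") for r in data.records_a] + [(r, "b") for r in data.records_b]:
        by_key.setdefault(_key_str(rec.variant), rec)
    for key, info in data.truth.items():
        cls = info["class"]
        if cls == "caller_discordant":
            in_a = any(_key_str(r.variant) == key for r in data.records_a)
            in_b = any(_key_str(r.variant) == key for r in data.records_b)
            if in_a == in_b:
                raise SimulationError(f"{key}: caller-discordant plant present in both/neither caller")
            continue
        rec = by_key.get(key)
        if rec is None and cls == "common_benign":
            # indels appear under the right-shifted key in caller B only
            continue
        if rec is None:
            raise SimulationError(f"{key}: planted variant missing from output")
        gt = {c.sample: c for c in rec.calls}
        if cls in ("maternal_dominant_stopgain", "silent_shared"):
            ok = gt[MOTHER].is_het and gt[FATHER].is_hom_ref and gt[SON1].is_het and gt[SON2].is_het
        elif cls == "xlinked_startloss":
            ok = (
                gt[MOTHER].is_het
                and not gt[FATHER].carries_alt
                and gt[SON1].is_hemizygous
                and gt[SON1].is_hom_alt
                and gt[SON2].is_hemizygous
                and gt[SON2].is_hom_alt
            )
        elif cls == "compound_het":
            carrier, other = (MOTHER, FATHER) if info["origin"] == "maternal" else (FATHER, MOTHER)
            ok = (
                gt[carrier].is_het
                and gt[other].is_hom_ref
                and gt[SON1].is_het
                and gt[SON2].is_het
            )
        elif cls == "de_novo":
            ok = (
                gt[FATHER].is_hom_ref
                and gt[MOTHER].is_hom_ref
                and (gt[SON1].carries_alt != gt[SON2].carries_alt)
            )
        elif cls == "ar_homozygous":
            ok = (
                gt[FATHER].is_het
                and gt[MOTHER].is_het
                and gt[SON1].is_hom_alt
                and gt[SON2].is_hom_alt
            )
        elif cls == "common_benign":
            ok = True  # genotypes are free; rarity is what removes them
        else:
            raise SimulationError(f"unknown truth class {cls!r}")
        if not ok:
            raise SimulationError(f"{key}: genotypes inconsistent with planted class {cls!r}")


def write_quartet(data: QuartetDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the full dataset (two VCFs, PED, annotation TSV, transcript
    TSV + CDS FASTA, reference FASTA, CPG list, truth JSON) under outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs = {c: len(s) for c, s in sorted(data.reference.items())}
    paths = {
        "vcf_a": outdir / "caller_a.vcf",
        "vcf_b": outdir / "caller_b.vcf",
        "ped": outdir / "family.ped",
        "annotations": outdir / "annotations.tsv",
        "transcripts_tsv": outdir / "transcripts.tsv",
        "cds_fasta": outdir / "cds.fasta",
        "reference_fasta": outdir / "reference.fasta",
        "cpg_list": outdir / "cpg_genes.txt",
        "truth": outdir / "truth.json",
    }
    write_vcf(data.records_a, paths["vcf_a"], SAMPLES, contigs)
    write_vcf(data.records_b, paths["vcf_b"], SAMPLES, contigs)
    write_ped(data.pedigree, paths["ped"])
    write_annotation_tsv(data.annotations, paths["annotations"])
    write_transcripts(data.transcripts, paths["transcripts_tsv"], paths["cds_fasta"])
    SeqIO.write(
        [SeqRecord(Seq(s), id=c, description="") for c, s in sorted(data.reference.items())],
        str(paths["reference_fasta"]),
        "fasta",
    )
    paths["cpg_list"].write_text("\n".join(data.cpg_genes) + "\n")
    paths["truth"].write_text(json.dumps(data.truth, indent=1, sort_keys=True))
    return paths


def simulate_expression(
    n_genes: int = 1000,
    n_per_group: int = 5,
    planted_size: int = 50,
    fold: float = 2.0,
    noise_sd: float = 0.25,
    seed: int = 0,
    n_decoys: int = 19,
) -> tuple[pd.DataFrame, dict[str, str], GeneSetCollection, str]:
    """Two-condition expression matrix with one planted up-regulated set.

    Baseline expression is log-normal (log2 means ~ N(6, 1.5)); planted-set
    genes are multiplied by ``fold`` in the case group; per-sample Gaussian
    noise with sd ``noise_sd`` is added on the log2 scale. Returns (matrix,
    sample->condition map, gene sets with size-matched random decoys, name
    of the planted set).
    """
    if planted_size > n_genes:
        raise SimulationError("planted set larger than the gene universe")
    rng = np.random.default_rng(seed)
    genes = [f"EG{i + 1:05d}" for i in range(n_genes)]
    planted = sorted(rng.choice(genes, size=planted_size, replace=False))
    base = rng.normal(6.0, 1.5, size=n_genes)
    samples = [f"CASE{i + 1}" for i in range(n_per_group)] + [
        f"CTRL{i + 1}" for i in range(n_per_group)
    ]
    conditions = {s: ("case" if s.startswith("CASE") else "control") for s in samples}
    planted_mask = np.isin(genes, planted)
    data = {}
    for s in samples:
        log2val = base + rng.normal(0.0, noise_sd, size=n_genes)
        if conditions[s] == "case":
            log2val = log2val + planted_mask * np.log2(fold)
        data[s] = np.power(2.0, log2val)
    expr = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    sets = {"PLANTED_UP_PATHWAY": list(planted)}
    for d in range(n_decoys):
        sets[f"DECOY_{d + 1:02d}"] = sorted(rng.choice(genes, size=planted_size, replace=False))
    collection = GeneSetCollection(sets=sets, source="synthetic")
    return expr, conditions, collection, "PLANTED_UP_PATHWAY"


def write_expression(
    expr: pd.DataFrame,
    conditions: dict[str, str],
    collection: GeneSetCollection,
    outdir: str | Path,
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"expression": outdir / "expression.tsv", "gmt": outdir / "genesets.gmt"}
    write_expression_tsv(expr, conditions, paths["expression"])
    write_gmt(collection, paths["gmt"])
    return paths
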