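"""Functional consequence classification with simplified HGVS c./p. strings.

Categories follow the usual exonic annotation vocabulary (stop-gain,
start-loss, frameshift, splicing, ...). The start-loss model assumes
translational re-initiation at the next in-frame ATG, so destroying the
initiator of a protein whose codon 6 is ATG is reported as a deletion of the
first five residues ("p.M1-P5del") rather than the agnostic "p.Met1?".
Protein descriptors use the compact one-letter dialect with "X" for a stop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.Seq import Seq

from .transcripts import STOP_CODONS, TranscriptModel
from .variants import GenomicVariant

CATEGORIES = (
    "stop_gain",
    "frameshift_indel",
    "start_loss",
    "splicing",
    "stop_loss",
    "nonsynonymous",
    "inframe_indel",
    "synonymous",
    "non_coding",
)
# severity rank: lower index = more severe
_SEVERITY = {cat: i for i, cat in enumerate(CATEGORIES)}

NON_SILENT = frozenset(
    {"splicing", "frameshift_indel", "nonsynonymous", "stop_gain", "stop_loss", "start_loss", "inframe_indel"}
)


class ConsequenceError(ValueError):
    pass


@dataclass(frozen=True)
class Consequence:
    category: str
    gene: str = ""
    hgvs_c: str = ""
    hgvs_p: str = ""
    affected_residue: Optional[tuple[int, int]] = None  # 1-based inclusive range
    whole_protein_loss: bool = False

    def __post_init__(self) -> None:
        if self.category not in _SEVERITY:
            raise ConsequenceError(f"unknown category {self.category!r}")

    @property
    def is_non_silent(self) -> bool:
        return self.category in NON_SILENT

    @property
    def severity(self) -> int:
        return _SEVERITY[self.category]


def cds_position_to_codon(cds_pos: int, cds_length: Optional[int] = None) -> tuple[int, int]:
    """Map a 1-based CDS coordinate to (codon index, offset within codon).

    Both outputs are 1-based; e.g. CDS position 1606 lies at the first base
    of codon 536. The inverse map is ``3*(codon-1) + offset``.
    """
    if cds_pos < 1 or (cds_length is not None and cds_pos > cds_length):
        raise ConsequenceError(f"CDS position {cds_pos} out of range")
    return (cds_pos - 1) // 3 + 1, (cds_pos - 1) % 3 + 1


def _translate_codon(codon: str) -> str:
    if codon in STOP_CODONS:
        return "X"
    return str(Seq(codon).translate())


def classify_substitution(t: TranscriptModel, v: GenomicVariant) -> Consequence:
    """Classify an SNV that lies in the CDS of ``t`` (strand-aware)."""
    if not v.is_snv:
        raise ConsequenceError("classify_substitution requires an SNV")
    cds_pos = t.genomic_to_cds(v.pos)
    if cds_pos is None:
        return Consequence(category="non_coding", gene=t.gene)
    ref_sense = t.sense_base(v.ref)
    alt_sense = t.sense_base(v.alt)
    if t.sequence[cds_pos - 1] != ref_sense:
        raise ConsequenceError(
            f"{t.gene}: REF {v.ref} (sense {ref_sense}) does not match CDS base "
            f"{t.sequence[cds_pos - 1]} at c.{cds_pos}"
        )
    codon_index, offset = cds_position_to_codon(cds_pos, t.cds_length)
    codon = t.sequence[(codon_index - 1) * 3 : codon_index * 3]
    mutant = codon[: offset - 1] + alt_sense + codon[offset:]
    ref_aa = _translate_codon(codon)
    alt_aa = _translate_codon(mutant)
    hgvs_c = f"c.{cds_pos}{ref_sense}>{alt_sense}"
    hgvs_p = f"p.{ref_aa}{codon_index}{alt_aa}"
    if alt_aa == ref_aa:
        category = "synonymous"
    elif alt_aa == "X":
        category = "stop_gain"
    elif ref_aa == "X":
        category = "stop_loss"
    else:
        category = "nonsynonymous"
    return Consequence(
        category=category,
        gene=t.gene,
        hgvs_c=hgvs_c,
        hgvs_p=hgvs_p,
        affected_residue=(codon_index, codon_index),
    )


def classify_start_loss(t: TranscriptModel, v: GenomicVariant) -> Consequence:
    """Classify an SNV in the initiator codon under the re-initiation model.

    Scans downstream for the next in-frame ATG at codon k; the consequence is
    a deletion of residues 1..k-1 ("p.M1-<aa><k-1>del"). With no downstream
    in-frame ATG the whole protein is flagged as lost.
    """
    cds_pos = t.genomic_to_cds(v.pos)
    if cds_pos is None or cds_pos > 3:
        raise ConsequenceError("classify_start_loss requires an SNV in CDS positions 1-3")
    alt_sense = t.sense_base(v.alt)
    mutant_start = t.sequence[:3][: cds_pos - 1] + alt_sense + t.sequence[cds_pos:3]
    if mutant_start == "ATG":  # initiator preserved; not a start-loss
        return classify_substitution(t, v)
    hgvs_c = f"c.{cds_pos}{t.sense_base(v.ref)}>{alt_sense}"
    protein = t.protein
    next_atg: Optional[int] = None
    for k in range(2, t.cds_length // 3 + 1):
        if t.sequence[(k - 1) * 3 : k * 3] == "ATG":
            next_atg = k
            break
    if next_atg is None:
        return Consequence(
            category="start_loss",
            gene=t.gene,
            hgvs_c=hgvs_c,
            hgvs_p="p.M1?",
            affected_residue=(1, len(protein) - 1),
            whole_protein_loss=True,
        )
    last_deleted = next_atg - 1
    return Consequence(
        category="start_loss",
        gene=t.gene,
        hgvs_c=hgvs_c,
        hgvs_p=f"p.M1-{protein[last_deleted - 1]}{last_deleted}del",
        affected_residue=(1, last_deleted),
    )


def classify_splice(t: TranscriptModel, v: GenomicVariant, window: int = 2) -> Optional[Consequence]:
    """Splicing call for variants within ``window`` intronic bases of an
    internal exon boundary (canonical donor/acceptor dinucleotides at the
    default window of 2); None when outside the window."""
    if window <= 0:
        return None
    for pos in range(v.pos, v.end + 1):
        d = t.intron_distance(pos)
        if d is not None and d <= window:
            return Consequence(category="splicing", gene=t.gene)
    return None


def classify_indel(t: TranscriptModel, v: GenomicVariant, window: int = 2) -> Consequence:
    """Frameshift / in-frame classification for an indel overlapping the CDS.

    An indel that touches both exonic and intronic sequence is a splice-
    junction lesion and is reported as splicing (precedence over frameshift).
    """
    if not v.is_indel:
        raise ConsequenceError("classify_indel requires an insertion or deletion")
    covered = range(v.pos, v.end + 1)
    exonic = [p for p in covered if t.genomic_to_cds(p) is not None]
    if not exonic:
        return classify_splice(t, v, window) or Consequence(category="non_coding", gene=t.gene)
    if len(exonic) < len(covered):
        return Consequence(category="splicing", gene=t.gene)
    delta = len(v.alt) - len(v.ref)
    category = "inframe_indel" if delta % 3 == 0 else "frameshift_indel"
    cds_pos = t.genomic_to_cds(min(covered) if t.strand == "+" else max(covered))
    codon_index, _ = cds_position_to_codon(cds_pos, t.cds_length)
    return Consequence(
        category=category,
        gene=t.gene,
        hgvs_c=f"c.{cds_pos}indel",
        hgvs_p=f"p.{t.protein[codon_index - 1]}{codon_index}fs" if category == "frameshift_indel" else "",
        affected_residue=(codon_index, codon_index),
    )


def classify(t: TranscriptModel, v: GenomicVariant, splice_window: int = 2) -> Consequence:
    """One consequence for (variant, transcript): dispatch on variant type
    and position, with splicing checked for near-exon intronic variants."""
    if v.is_snv:
        cds_pos = t.genomic_to_cds(v.pos)
        if cds_pos is None:
            return classify_splice(t, v, splice_window) or Consequence(category="non_coding", gene=t.gene)
        if cds_pos <= 3:
            return classify_start_loss(t, v)
        return classify_substitution(t, v)
    return classify_indel(t, v, splice_window)


def annotate_variant(
    v: GenomicVariant, transcripts: Sequence[TranscriptModel], splice_window: int = 2
) -> Consequence:
    """Most severe consequence of ``v`` across all transcripts on its
    chromosome (severity order: stop_gain > frameshift > start_loss >
    splicing > stop_loss > nonsynonymous > inframe_indel > synonymous >
    non_coding)."""
    best: Optional[Consequence] = None
    for t in transcripts:
        if t.chrom != v.chrom:
            continue
        c = classify(t, v, splice_window)
        if best is None or c.severity < best.severity:
            best = c
    return best if best is not None else Consequence(category="non_coding")
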