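"""Toy transcript models: exon structure, CDS coordinates, serialization.

A transcript is a set of non-overlapping exons (1-based closed genomic
intervals, here coding from the first to the last base, i.e. no UTRs) plus
the spliced CDS sequence on the sense strand. Genomic <-> CDS coordinate
mapping is strand-aware: on the minus strand CDS position 1 is the last base
of the genomically-last exon and bases are complemented.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STOP_CODONS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class TranscriptError(ValueError):
    pass


@dataclass(frozen=True)
class TranscriptModel:
    gene: str
    chrom: str
    strand: str  # "+" or "-"
    exons: tuple[tuple[int, int], ...]  # sorted, non-overlapping, 1-based closed
    sequence: str  # spliced CDS, sense strand, ATG..stop

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise TranscriptError(f"strand must be + or -, got {self.strand!r}")
        prev_end = 0
        for start, end in self.exons:
            if start <= prev_end or end < start:
                raise TranscriptError(f"exons must be sorted and non-overlapping: {self.exons}")
            prev_end = end
        exon_len = sum(end - start + 1 for start, end in self.exons)
        if exon_len != len(self.sequence):
            raise TranscriptError(
                f"{self.gene}: exon length {exon_len} != CDS length {len(self.sequence)}"
            )
        if len(self.sequence) % 3 != 0:
            raise TranscriptError(f"{self.gene}: CDS length not divisible by 3")
        if not self.sequence.startswith("ATG"):
            raise TranscriptError(f"{self.gene}: CDS must begin with ATG")
        if self.sequence[-3:] not in STOP_CODONS:
            raise TranscriptError(f"{self.gene}: CDS must end with a stop codon")

    @property
    def cds_start(self) -> int:
        return self.exons[0][0]

    @property
    def cds_end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return len(self.sequence)

    @property
    def protein(self) -> str:
        """Translation of the CDS including the terminal '*'."""
        return str(Seq(self.sequence).translate())

    def genomic_to_cds(self, pos: int) -> Optional[int]:
        """1-based CDS coordinate for a genomic position, or None if intronic
        or outside the transcript."""
        offset = 0
        if self.strand == "+":
            for start, end in self.exons:
                if start <= pos <= end:
                    return offset + (pos - start) + 1
                offset += end - start + 1
        else:
            for start, end in reversed(self.exons):
                if start <= pos <= end:
                    return offset + (end - pos) + 1
                offset += end - start + 1
        return None

    def cds_to_genomic(self, cds_pos: int) -> int:
        if not 1 <= cds_pos <= self.cds_length:
            raise TranscriptError(f"CDS position {cds_pos} outside 1..{self.cds_length}")
        remaining = cds_pos - 1
        if self.strand == "+":
            for start, end in self.exons:
                span = end - start + 1
                if remaining < span:
                    return start + remaining
                remaining -= span
        else:
            for start, end in reversed(self.exons):
                span = end - start + 1
                if remaining < span:
                    return end - remaining
                remaining -= span
        raise AssertionError("unreachable")

    def sense_base(self, genomic_base: str) -> str:
        """Convert a genomic-strand base to the transcript's sense strand."""
        b = genomic_base.upper()
        return b if self.strand == "+" else b.translate(_COMPLEMENT)

    def overlaps(self, start: int, end: int) -> bool:
        return any(s <= end and start <= e for s, e in self.exons)

    def intron_distance(self, pos: int) -> Optional[int]:
        """Distance (>=1) from an intronic position to the nearest internal
        exon boundary; None for exonic or fully intergenic positions."""
        if self.genomic_to_cds(pos) is not None:
            return None
        if pos < self.cds_start or pos > self.cds_end:
            return None
        dist = None
        for i in range(len(self.exons) - 1):
            intron_lo = self.exons[i][1] + 1
            intron_hi = self.exons[i + 1][0] - 1
            if intron_lo <= pos <= intron_hi:
                dist = min(pos - intron_lo + 1, intron_hi - pos + 1)
        return dist


def write_transcripts(models: list[TranscriptModel], tsv_path: str | Path, fasta_path: str | Path) -> None:
    rows = [
        {
            "gene": t.gene,
            "chrom": t.chrom,
            "strand": t.strand,
            "exon_starts": ",".join(str(s) for s, _ in t.exons),
            "exon_ends": ",".join(str(e) for _, e in t.exons),
        }
        for t in models
    ]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    SeqIO.write(
        [SeqRecord(Seq(t.sequence), id=t.gene, description="") for t in models],
        str(fasta_path),
        "fasta",
    )


def read_transcripts(tsv_path: str | Path, fasta_path: str | Path) -> list[TranscriptModel]:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    models = []
    for row in df.itertuples(index=False):
        if row.gene not in seqs:
            raise TranscriptError(f"no CDS sequence for gene {row.gene!r} in {fasta_path}")
        starts = [int(x) for x in row.exon_starts.split(",")]
        ends = [int(x) for x in row.exon_ends.split(",")]
        models.append(
            TranscriptModel(
                gene=row.gene,
                chrom=row.chrom,
                strand=row.strand,
                exons=tuple(zip(starts, ends)),
                sequence=seqs[row.gene],
            )
        )
    return models
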