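"""Per-variant annotation records: population frequencies, in-silico scores,
cancer-predisposition-gene flags, and (optionally) curated ACMG evidence.

The TSV dialect has a documented header:

    chrom pos ref alt gene af_kg_asian af_exac_nontcga sift polyphen2
    mutation_taster mcap is_cpg_gene [evidence]

Frequencies and scores are blank when missing; ``mutation_taster`` is a
categorical call (``disease_causing`` or anything else); ``evidence`` is a
comma-separated ACMG token list curated upstream (never auto-derived here).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "af_kg_asian",
    "af_exac_nontcga",
    "sift",
    "polyphen2",
    "mutation_taster",
    "mcap",
    "is_cpg_gene",
    "evidence",
]

VariantKey = tuple[str, int, str, str]


@dataclass
class AnnotationRecord:
    key: VariantKey
    gene: str
    af_kg_asian: Optional[float] = None
    af_exac_nontcga: Optional[float] = None
    sift: Optional[float] = None
    polyphen2: Optional[float] = None
    mutation_taster: Optional[str] = None
    mcap: Optional[float] = None
    is_cpg_gene: bool = False
    evidence: str = ""

    def __post_init__(self) -> None:
        for name in ("af_kg_asian", "af_exac_nontcga", "sift", "polyphen2", "mcap"):
            val = getattr(self, name)
            if val is not None and not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} must lie in [0,1], got {val}")

    @property
    def frequencies(self) -> dict[str, Optional[float]]:
        return {"kg_asian": self.af_kg_asian, "exac_nontcga": self.af_exac_nontcga}


def read_annotation_tsv(path: str | Path) -> dict[VariantKey, AnnotationRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = set(COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: annotation TSV missing columns {sorted(missing)}")
    out: dict[VariantKey, AnnotationRecord] = {}
    for row in df.itertuples(index=False):
        def opt(v):
            return None if pd.isna(v) else float(v)

        key = (row.chrom, int(row.pos), row.ref, row.alt)
        out[key] = AnnotationRecord(
            key=key,
            gene=str(row.gene),
            af_kg_asian=opt(row.af_kg_asian),
            af_exac_nontcga=opt(row.af_exac_nontcga),
            sift=opt(row.sift),
            polyphen2=opt(row.polyphen2),
            mutation_taster=None if pd.isna(row.mutation_taster) else str(row.mutation_taster),
            mcap=opt(row.mcap),
            is_cpg_gene=bool(row.is_cpg_gene),
            evidence="" if not hasattr(row, "evidence") or pd.isna(row.evidence) else str(row.evidence),
        )
    return out


def write_annotation_tsv(records: list[AnnotationRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        chrom, pos, ref, alt = r.key
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "gene": r.gene,
                "af_kg_asian": r.af_kg_asian,
                "af_exac_nontcga": r.af_exac_nontcga,
                "sift": r.sift,
                "polyphen2": r.polyphen2,
                "mutation_taster": r.mutation_taster,
                "mcap": r.mcap,
                "is_cpg_gene": r.is_cpg_gene,
                "evidence": r.evidence,
            }
        )
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, sep="\t", index=False)
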