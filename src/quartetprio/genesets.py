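"""Gene-set collections and GMT parsing (MSigDB-style)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path


class GmtParseError(ValueError):
    pass


@dataclass
class GeneSetCollection:
    """Named gene sets with uppercased, deduplicated symbols; order preserved."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise GmtParseError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def read_gmt(path: str | Path, source: str = "") -> GeneSetCollection:
    """Parse a GMT file: tab-separated name, description, gene symbols.

    Duplicate genes within one line are deduplicated keeping first occurrence;
    symbols are uppercased.
    """
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise GmtParseError(f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
        name = fields[0]
        genes: list[str] = []
        seen: set[str] = set()
        for g in fields[2:]:
            g = g.strip().upper()
            if g and g not in seen:
                seen.add(g)
                genes.append(g)
        if not genes:
            raise GmtParseError(f"{path}:{lineno}: gene set {name!r} has no genes")
        sets[name] = genes
    if not sets:
        raise GmtParseError(f"{path}: no gene sets found")
    return GeneSetCollection(sets=sets, source=source or str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, collection.source or "na"] + genes)
        for name, genes in collection.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
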