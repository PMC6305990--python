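"""Pedigree model and 6-column PED parsing."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional


class PedigreeError(ValueError):
    pass


@dataclass(frozen=True)
class PedigreeMember:
    id: str
    father: Optional[str]
    mother: Optional[str]
    sex: str  # "male" | "female" | "unknown"
    affected: bool


@dataclass
class Pedigree:
    members: list[PedigreeMember]

    def __post_init__(self) -> None:
        ids = [m.id for m in self.members]
        if len(set(ids)) != len(ids):
            raise PedigreeError("duplicate member ids")
        by_id = {m.id: m for m in self.members}
        for m in self.members:
            for parent in (m.father, m.mother):
                if parent is not None and parent not in by_id:
                    raise PedigreeError(f"unknown parent id {parent!r} for member {m.id!r}")
        self._check_acyclic(by_id)

    def _check_acyclic(self, by_id: dict[str, PedigreeMember]) -> None:
        # DFS over parent links; a member reachable from itself is a cycle
        state: dict[str, int] = {}

        def visit(mid: str) -> None:
            if state.get(mid) == 1:
                raise PedigreeError(f"cyclic parentage involving {mid!r}")
            if state.get(mid) == 2:
                return
            state[mid] = 1
            m = by_id[mid]
            for parent in (m.father, m.mother):
                if parent is not None:
                    visit(parent)
            state[mid] = 2

        for m in self.members:
            visit(m.id)

    def member(self, member_id: str) -> PedigreeMember:
        for m in self.members:
            if m.id == member_id:
                return m
        raise KeyError(member_id)

    @property
    def affected(self) -> list[PedigreeMember]:
        return [m for m in self.members if m.affected]

    @property
    def sample_ids(self) -> list[str]:
        return [m.id for m in self.members]

    def children_with_parents(self) -> list[PedigreeMember]:
        """Members whose father and mother are both in the pedigree."""
        return [m for m in self.members if m.father is not None and m.mother is not None]


def read_ped(path: str | Path) -> Pedigree:
    """Parse a 6-column PED file (family, id, father, mother, sex, phenotype).

    Father/mother "0" means unknown; sex 1=male, 2=female; phenotype 2=affected.
    """
    members: list[PedigreeMember] = []
    sex_map = {"1": "male", "2": "female"}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise PedigreeError(f"{path}:{lineno}: expected 6 PED columns, got {len(fields)}")
        _fam, mid, father, mother, sex, pheno = fields[:6]
        members.append(
            PedigreeMember(
                id=mid,
                father=None if father == "0" else father,
                mother=None if mother == "0" else mother,
                sex=sex_map.get(sex, "unknown"),
                affected=(pheno == "2"),
            )
        )
    if not members:
        raise PedigreeError(f"{path}: no pedigree members found")
    return Pedigree(members=members)


def write_ped(ped: Pedigree, path: str | Path, family_id: str = "FAM1") -> None:
    sex_map = {"male": "1", "female": "2", "unknown": "0"}
    lines = []
    for m in ped.members:
        lines.append(
            "\t".join(
                [
                    family_id,
                    m.id,
                    m.father or "0",
                    m.mother or "0",
                    sex_map[m.sex],
                    "2" if m.affected else "1",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
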