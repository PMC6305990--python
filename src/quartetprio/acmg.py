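"""ACMG-AMP evidence combining: criterion codes, strength overrides, and the
fixed clause table mapping evidence counts to a five-tier classification.

Strength overrides use the common suffix notation: "PP1-S" is the PP1
criterion applied at strong level (e.g. when segregation data in a family is
extensive), and it counts as a strong criterion in the combining rules.
Pathogenic clauses are labelled Ia-Id (very-strong-anchored), II (two
strongs) and III (one strong plus moderates/supportings); the earliest
satisfied label is reported. A conflict (uncertain significance) is declared
only when the pathogenic and benign sides BOTH reach a likely/definite
classification on their own; isolated benign-supporting evidence does not
veto an otherwise pathogenic combination.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

PATHOGENIC_CODES = (
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
)
BENIGN_CODES = ["BA1"] + [f"BS{i}" for i in range(1, 5)] + [f"BP{i}" for i in range(1, 8)]
VALID_CODES = frozenset(PATHOGENIC_CODES + BENIGN_CODES)

_DEFAULT_STRENGTH = {
    "PVS": "very_strong",
    "PS": "strong",
    "PM": "moderate",
    "PP": "supporting",
    "BA": "stand_alone",
    "BS": "strong",
    "BP": "supporting",
}
_SUFFIX = {"VS": "very_strong", "S": "strong", "M": "moderate", "P": "supporting"}
PATHOGENIC_LEVELS = ("very_strong", "strong", "moderate", "supporting")
BENIGN_LEVELS = ("stand_alone", "strong", "supporting")


class EvidenceError(ValueError):
    pass


@dataclass(frozen=True)
class AcmgEvidence:
    code: str
    strength: str

    def __post_init__(self) -> None:
        if self.code not in VALID_CODES:
            raise EvidenceError(
                f"unknown ACMG code {self.code!r}; valid codes: {', '.join(sorted(VALID_CODES))}"
            )
        if self.is_benign and self.strength not in BENIGN_LEVELS:
            raise EvidenceError(f"benign code {self.code} cannot take level {self.strength!r}")
        if not self.is_benign and self.strength not in PATHOGENIC_LEVELS:
            raise EvidenceError(f"pathogenic code {self.code} cannot take level {self.strength!r}")

    @property
    def is_benign(self) -> bool:
        return self.code.startswith("B")


@dataclass(frozen=True)
class AcmgResult:
    classification: str  # pathogenic | likely_pathogenic | uncertain_significance | likely_benign | benign
    tier: Optional[str] = None  # Ia | Ib | Ic | Id | II | III, pathogenic only
    conflict: bool = False

    def label(self) -> str:
        names = {
            "pathogenic": "Pathogenic",
            "likely_pathogenic": "Likely pathogenic",
            "uncertain_significance": "Uncertain significance",
            "likely_benign": "Likely benign",
            "benign": "Benign",
        }
        base = names[self.classification]
        return f"{base}({self.tier})" if self.tier else base


def _default_strength(code: str) -> str:
    for prefix in ("PVS", "PS", "PM", "PP", "BA", "BS", "BP"):
        if code.startswith(prefix):
            return _DEFAULT_STRENGTH[prefix]
    raise EvidenceError(f"unknown ACMG code {code!r}")


def parse_evidence(tokens: Iterable[str] | str) -> list[AcmgEvidence]:
    """Parse code tokens with optional strength suffixes.

    Accepts a comma-separated string or a token iterable; "PP1-S" yields PP1
    at strong, "PM2" keeps its default moderate level. Duplicate codes are an
    error.
    """
    if isinstance(tokens, str):
        tokens = [t for t in (s.strip() for s in tokens.split(",")) if t]
    out: list[AcmgEvidence] = []
    seen: set[str] = set()
    for token in tokens:
        token = token.strip().upper()
        code, _, suffix = token.partition("-")
        if code not in VALID_CODES:
            raise EvidenceError(
                f"unknown ACMG code {code!r}; valid codes: {', '.join(sorted(VALID_CODES))}"
            )
        if code in seen:
            raise EvidenceError(f"duplicate ACMG code {code!r}")
        seen.add(code)
        if suffix:
            if suffix not in _SUFFIX:
                raise EvidenceError(f"unknown strength suffix {suffix!r} in {token!r}")
            strength = _SUFFIX[suffix]
        else:
            strength = _default_strength(code)
        out.append(AcmgEvidence(code=code, strength=strength))
    return out


def _pathogenic_side(vs: int, s: int, m: int, p: int) -> tuple[Optional[str], Optional[str]]:
    """(classification, tier) from pathogenic-level counts, or (None, None)."""
    if vs >= 1:
        if s >= 1:
            return "pathogenic", "Ia"
        if m >= 2:
            return "pathogenic", "Ib"
        if m == 1 and p == 1:
            return "pathogenic", "Ic"
        if p >= 2:
            return "pathogenic", "Id"
    if s >= 2:
        return "pathogenic", "II"
    if s == 1 and (m >= 3 or (m == 2 and p >= 2) or (m == 1 and p >= 4)):
        return "pathogenic", "III"
    # likely pathogenic clauses
    if vs >= 1 and m == 1:
        return "likely_pathogenic", None
    if s == 1 and 1 <= m <= 2:
        return "likely_pathogenic", None
    if s == 1 and p >= 2:
        return "likely_pathogenic", None
    if m >= 3:
        return "likely_pathogenic", None
    if m == 2 and p >= 2:
        return "likely_pathogenic", None
    if m == 1 and p >= 4:
        return "likely_pathogenic", None
    return None, None


def _benign_side(stand_alone: int, strong: int, supporting: int) -> Optional[str]:
    if stand_alone >= 1 or strong >= 2:
        return "benign"
    if (strong == 1 and supporting >= 1) or supporting >= 2:
        return "likely_benign"
    return None


def combine_evidence(evidence: Sequence[AcmgEvidence]) -> AcmgResult:
    """Apply the combining rules to a parsed evidence list.

    Counting is by effective level, so overrides participate at their
    overridden strength. Neither side reaching a classification, or both
    sides reaching one (conflict), yields uncertain significance.
    """
    path = Counter(e.strength for e in evidence if not e.is_benign)
    ben = Counter(e.strength for e in evidence if e.is_benign)
    p_class, tier = _pathogenic_side(
        path["very_strong"], path["strong"], path["moderate"], path["supporting"]
    )
    b_class = _benign_side(ben["stand_alone"], ben["strong"], ben["supporting"])
    if p_class and b_class:
        return AcmgResult(classification="uncertain_significance", conflict=True)
    if p_class:
        return AcmgResult(classification=p_class, tier=tier)
    if b_class:
        return AcmgResult(classification=b_class)
    return AcmgResult(classification="uncertain_significance")


def classify_evidence_string(tokens: str) -> AcmgResult:
    """Convenience: parse a comma-separated token string and combine."""
    return combine_evidence(parse_evidence(tokens))


def suggest_pm2(af_values: Sequence[Optional[float]], threshold: float = 0.0001) -> bool:
    """Convenience flag: PM2 (absent from controls) is plausible when every
    configured population frequency is missing or below ``threshold``. This
    is a suggestion only; evidence assignment remains a curation input."""
    return all(v is None or v < threshold for v in af_values)
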