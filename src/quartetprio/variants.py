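"""Normalized genomic variants, genotype calls, and dual-caller consensus.

Coordinates are 1-based and fully closed, as in VCF. Every internal key is
the normalized ``(chrom, pos, ref, alt)`` tuple, so that the same indel
written differently by two callers (e.g. left- vs right-shifted in a repeat)
intersects correctly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


class NormalizationError(ValueError):
    """REF field disagrees with the reference sequence at the stated position."""


@dataclass(frozen=True)
class GenomicVariant:
    """One alternate allele at a 1-based genomic position.

    ``chrom`` is kept exactly as read ("chr" prefix preserved). ``ref`` and
    ``alt`` are non-empty uppercase A/C/G/T strings; multiallelic records are
    split before a :class:`GenomicVariant` is constructed.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or set(allele) - _BASES:
                raise ValueError(f"{name} must be a non-empty A/C/G/T string, got {allele!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) is not a variant")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def end(self) -> int:
        """Last reference base covered (== pos for SNVs)."""
        return self.pos + len(self.ref) - 1

    def is_normalized(self) -> bool:
        if len(self.ref) > 1 and len(self.alt) > 1:
            if self.ref[-1] == self.alt[-1] or self.ref[0] == self.alt[0]:
                return False
        # parsimony: a shared trailing base is never allowed
        if len(self.ref) > 1 or len(self.alt) > 1:
            if self.ref[-1] == self.alt[-1] and min(len(self.ref), len(self.alt)) > 1:
                return False
        return True


@dataclass(frozen=True)
class GenotypeCall:
    """Per-sample GT field after multiallelic splitting.

    ``alleles`` holds 0/1 indices (or None for missing); hemizygous calls are
    a length-1 tuple, permitted only for male samples on X/Y. Input phase
    separators are recorded but every caller output is treated as unphased.
    """

    sample: str
    alleles: tuple[Optional[int], ...]
    phased: bool = False

    def __post_init__(self) -> None:
        if len(self.alleles) not in (1, 2):
            raise ValueError(f"expected 1 or 2 alleles, got {self.alleles}")
        for a in self.alleles:
            if a is not None and a not in (0, 1):
                raise ValueError(f"allele index must be 0/1 after splitting, got {a}")

    @property
    def is_missing(self) -> bool:
        return any(a is None for a in self.alleles)

    @property
    def is_hemizygous(self) -> bool:
        return len(self.alleles) == 1

    @property
    def n_alt(self) -> int:
        return sum(1 for a in self.alleles if a == 1)

    @property
    def carries_alt(self) -> bool:
        return self.n_alt > 0

    @property
    def is_hom_ref(self) -> bool:
        return not self.is_missing and all(a == 0 for a in self.alleles)

    @property
    def is_het(self) -> bool:
        return len(self.alleles) == 2 and set(self.alleles) == {0, 1}

    @property
    def is_hom_alt(self) -> bool:
        return not self.is_missing and all(a == 1 for a in self.alleles)


@dataclass
class VariantRecord:
    """A variant together with the per-sample genotype calls of one caller."""

    variant: GenomicVariant
    calls: list[GenotypeCall] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return self.variant.key

    def call_for(self, sample: str) -> GenotypeCall:
        for c in self.calls:
            if c.sample == sample:
                return c
        raise KeyError(sample)


RefLookup = Callable[[str, int], str]


def normalize_variant(v: GenomicVariant, ref_lookup: RefLookup) -> GenomicVariant:
    """Reduce ``v`` to its minimal left-aligned representation.

    The procedure is the standard parsimony/left-alignment loop: shared
    trailing bases are trimmed (extending to the left with reference bases
    whenever an allele would empty), then shared leading bases are trimmed
    while both alleles keep length > 1. Idempotent by construction.

    ``ref_lookup(chrom, pos)`` must return the reference base at the 1-based
    position; it is used both to validate REF and to left-extend indels.
    """
    ref, alt, pos = v.ref, v.alt, v.pos
    for i, base in enumerate(ref):
        expect = ref_lookup(v.chrom, pos + i).upper()
        if base != expect:
            raise NormalizationError(
                f"REF mismatch at {v.chrom}:{pos + i}: variant says {base}, reference has {expect}"
            )
    while True:
        if ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos == 1:
                    raise NormalizationError(f"cannot left-extend {v} past the chromosome start")
                pos -= 1
                left = ref_lookup(v.chrom, pos).upper()
                ref, alt = left + ref, left + alt
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return replace(v, pos=pos, ref=ref, alt=alt)


def apply_variant(context: str, context_start: int, v: GenomicVariant) -> str:
    """Apply ``v`` to a reference ``context`` beginning at 1-based ``context_start``.

    Returns the edited haplotype; used to prove that normalization preserves
    the edit (two representations are equivalent iff the edited sequences
    agree).
    """
    off = v.pos - context_start
    if off < 0 or off + len(v.ref) > len(context):
        raise ValueError("variant outside provided context")
    if context[off : off + len(v.ref)].upper() != v.ref:
        raise NormalizationError(f"context does not carry REF for {v}")
    return context[:off] + v.alt + context[off + len(v.ref) :]


def consensus_intersect(
    calls_a: Sequence[VariantRecord], calls_b: Sequence[VariantRecord]
) -> list[VariantRecord]:
    """Variants jointly detected by two callers, keyed on (chrom, pos, ref, alt).

    Both inputs must already be normalized. Genotypes are taken from the
    first caller; a warning is logged for records where the two callers'
    genotype strings disagree.
    """
    for rec in list(calls_a) + list(calls_b):
        if not rec.variant.is_normalized():
            raise ValueError(f"un-normalized input to consensus: {rec.variant}")
    keys_b = {rec.key: rec for rec in calls_b}
    out: list[VariantRecord] = []
    for rec in calls_a:
        other = keys_b.get(rec.key)
        if other is None:
            continue
        if [c.alleles for c in rec.calls] != [c.alleles for c in other.calls]:
            logger.warning(
                "genotype disagreement between callers at %s:%d %s>%s; keeping first caller's calls",
                *rec.key,
            )
        out.append(rec)
    return out


def variant_keys(records: Iterable[VariantRecord]) -> set[tuple[str, int, str, str]]:
    return {rec.key for rec in records}
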