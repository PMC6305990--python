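"""VCF reading/writing via pysam, with multiallelic splitting and GT remapping.

Whole-file streaming only (no tabix random access). Multiallelic sites are
split into one :class:`~quartetprio.variants.VariantRecord` per alternate
allele; per-sample genotype indices are remapped per split allele, with
non-tracked alternates collapsed to the reference-equivalent "other" index 0
(logged once per file).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import pysam

from .variants import GenomicVariant, GenotypeCall, VariantRecord

logger = logging.getLogger(__name__)


class VcfParseError(ValueError):
    pass


def _remap_allele(orig: Optional[int], tracked_alt: int) -> Optional[int]:
    """Map an original allele index onto the biallelic split for one ALT."""
    if orig is None:
        return None
    if orig == tracked_alt:
        return 1
    return 0  # reference or a non-tracked alternate ("other")


def read_vcf(path: str | Path, caller_tag: str = "") -> list[VariantRecord]:
    """Read a VCF 4.x file into split, per-allele variant records.

    Sample column order is preserved. Missing genotypes (./.) are kept as
    calls with ``None`` alleles so later stages can exclude them explicitly.
    Records with symbolic or non-ACGT alleles are skipped with a warning.
    """
    path = Path(path)
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: malformed VCF header: {exc}") from exc
    samples = list(vf.header.samples)
    records: list[VariantRecord] = []
    other_alt_logged = False
    n = 0
    try:
        for n, rec in enumerate(vf, start=1):
            alts = rec.alts or ()
            for alt_index, alt in enumerate(alts, start=1):
                if alt is None or set(alt.upper()) - set("ACGT") or set(rec.ref.upper()) - set("ACGT"):
                    logger.warning("%s: skipping non-ACGT allele at record %d", path, n)
                    continue
                variant = GenomicVariant(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref.upper(),
                    alt=alt.upper(),
                    id=rec.id,
                )
                calls: list[GenotypeCall] = []
                for sample in samples:
                    gt = rec.samples[sample].get("GT", (None,))
                    phased = bool(rec.samples[sample].phased)
                    if gt is None or len(gt) == 0:
                        gt = (None,)
                    if len(alts) > 1 and any(a not in (None, 0, alt_index) for a in gt):
                        if not other_alt_logged:
                            logger.warning(
                                "%s: non-tracked alternate alleles collapsed to 0 during splitting",
                                path,
                            )
                            other_alt_logged = True
                    alleles = tuple(_remap_allele(a, alt_index) for a in gt)
                    calls.append(GenotypeCall(sample=sample, alleles=alleles, phased=phased))
                records.append(VariantRecord(variant=variant, calls=calls))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: malformed VCF record near record {n + 1}: {exc}") from exc
    finally:
        vf.close()
    if not records:
        logger.warning("%s: no variant records read%s", path, f" ({caller_tag})" if caller_tag else "")
    return records


def make_vcf_header(samples: Sequence[str], contigs: dict[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for name, length in contigs.items():
        header.add_line(f"##contig=<ID={name},length={length}>")
    for s in samples:
        header.add_sample(s)
    return header


def write_vcf(
    records: Sequence[VariantRecord],
    path: str | Path,
    samples: Sequence[str],
    contigs: dict[str, int],
) -> None:
    """Write biallelic records to an uncompressed VCF 4.2 file."""
    header = make_vcf_header(samples, contigs)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            v = rec.variant
            row = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt), id=v.id
            )
            # stop defaults to start+len(ref) via alleles; make it explicit
            row.stop = v.pos - 1 + len(v.ref)
            for call in rec.calls:
                row.samples[call.sample]["GT"] = tuple(call.alleles)
                row.samples[call.sample].phased = call.phased
            out.write(row)
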