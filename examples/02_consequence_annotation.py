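"""Annotate the two signature coding consequences on toy transcripts.

A stop-gain: c.1606C>T turns the CGA (Arg) codon at CDS 1606-1608 into TGA,
truncating the protein at residue 536 (p.R536X). A start-loss: c.3G>T
destroys the initiator ATG; under the re-initiation model translation
restarts at the next in-frame ATG (codon 6), deleting residues 1-5
(p.M1-P5del).
"""

from quartetprio import GenomicVariant, classify, make_toy_genes

genes, reference = make_toy_genes(seed=0)

stopgain_host = next(t for t in genes if t.sequence[1605:1608] == "CGA")
startloss_host = next(t for t in genes if t.chrom == "chrX")

for t, cds_pos, alt in [(stopgain_host, 1606, "T"), (startloss_host, 3, "T")]:
    gpos = t.cds_to_genomic(cds_pos)
    v = GenomicVariant(t.chrom, gpos, reference[t.chrom][gpos - 1], alt)
    c = classify(t, v)
    first, last = c.affected_residue
    print(
        f"{t.gene} ({t.chrom}, CDS {t.cds_length} nt): {c.hgvs_c} -> "
        f"{c.category}, {c.hgvs_p} (residues {first}-{last})"
    )

# Expected output:
#   the autosomal gene reports stop_gain p.R536X at residue 536,
#   the chrX gene reports start_loss p.M1-P5del spanning residues 1-5.
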