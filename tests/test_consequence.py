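"""Consequence classification against a full-translation oracle, plus the
two signature lesions: a stop-gain at codon 536 and an initiator-codon loss
re-initiating at codon 6."""

import numpy as np
import pytest
from Bio.Seq import Seq

from quartetprio.consequence import (
    ConsequenceError,
    cds_position_to_codon,
    classify,
    classify_indel,
    classify_splice,
    classify_start_loss,
    classify_substitution,
)
from quartetprio.transcripts import TranscriptModel
from quartetprio.variants import GenomicVariant


def oracle_substitution(t: TranscriptModel, cds_pos: int, alt_sense: str):
    """Translate the full reference and mutant CDS and diff the peptides;
    independent of codon arithmetic in the implementation."""
    mutant = t.sequence[: cds_pos - 1] + alt_sense + t.sequence[cds_pos:]
    ref_prot = str(Seq(t.sequence).translate())
    mut_prot = str(Seq(mutant).translate())
    if ref_prot == mut_prot:
        return "synonymous", None
    diffs = [i for i, (a, b) in enumerate(zip(ref_prot, mut_prot)) if a != b]
    i = diffs[0]
    if mut_prot[i] == "*":
        return "stop_gain", i + 1
    if ref_prot[i] == "*":
        return "stop_loss", i + 1
    return "nonsynonymous", i + 1


def snv_at(t: TranscriptModel, reference, cds_pos: int, alt_sense: str) -> GenomicVariant:
    gpos = t.cds_to_genomic(cds_pos)
    gref = reference[t.chrom][gpos - 1]
    galt = alt_sense if t.strand == "+" else str(Seq(alt_sense).complement())
    return GenomicVariant(t.chrom, gpos, gref, galt)


class TestCodonMath:
    @pytest.mark.parametrize("cds_pos,expected", [(1606, (536, 1)), (3, (1, 3)), (1, (1, 1)), (4, (2, 1))])
    def test_examples(self, cds_pos, expected):
        assert cds_position_to_codon(cds_pos) == expected

    def test_roundtrip_inverse(self):
        for cds_pos in range(1, 400):
            codon, offset = cds_position_to_codon(cds_pos)
            assert 3 * (codon - 1) + offset == cds_pos

    def test_out_of_range(self):
        with pytest.raises(ConsequenceError):
            cds_position_to_codon(0)
        with pytest.raises(ConsequenceError):
            cds_position_to_codon(10, cds_length=9)


class TestSubstitution:
    def test_stop_gain_at_codon_536(self, apcl, toy_reference):
        """c.1606C>T on a CGA codon spanning 1606-1608 truncates at R536."""
        v = snv_at(apcl, toy_reference, 1606, "T")
        c = classify_substitution(apcl, v)
        assert c.category == "stop_gain"
        assert c.hgvs_c == "c.1606C>T"
        assert c.hgvs_p == "p.R536X"
        assert c.affected_residue == (536, 536)

    def test_synonymous_ala(self, toy_reference):
        # GCT -> GCC at codon 2: both alanine
        seq = "ATG" + "GCT" + "TTTTAA"  # wrong length; build properly below
        seq = "ATGGCTTTTTAA"
        t = TranscriptModel(gene="T", chrom="c", strand="+", exons=((1, 12),), sequence=seq)
        ref = {"c": seq}
        v = GenomicVariant("c", 6, "T", "C")
        c = classify_substitution(t, v)
        assert c.category == "synonymous"
        assert c.hgvs_p == "p.A2A"

    def test_matches_full_translation_oracle(self, toy_genes, toy_reference, rng):
        """Random exonic SNVs across random toy transcripts agree with the
        peptide-diff oracle in category and affected residue."""
        checked = 0
        while checked < 400:
            t = toy_genes[int(rng.integers(len(toy_genes)))]
            cds_pos = int(rng.integers(4, t.cds_length + 1))  # beyond the initiator
            ref_sense = t.sequence[cds_pos - 1]
            alt_sense = "ACGT"[int(rng.integers(4))]
            if alt_sense == ref_sense:
                continue
            v = snv_at(t, toy_reference, cds_pos, alt_sense)
            got = classify_substitution(t, v)
            category, residue = oracle_substitution(t, cds_pos, alt_sense)
            assert got.category == category, (t.gene, cds_pos, ref_sense, alt_sense)
            if residue is not None:
                assert got.affected_residue == (residue, residue)
            checked += 1

    def test_ref_mismatch_raises(self, apcl, toy_reference):
        gpos = apcl.cds_to_genomic(100)
        wrong = "A" if toy_reference[apcl.chrom][gpos - 1] != "A" else "C"
        with pytest.raises(ConsequenceError, match="does not match"):
            classify_substitution(apcl, GenomicVariant(apcl.chrom, gpos, wrong, "G"))


class TestStartLoss:
    def test_reinitiation_at_codon_6(self, wasl, toy_reference):
        """c.3G>T destroys the initiator; the next in-frame ATG is codon 6,
        deleting residues 1-5 (p.M1-P5del)."""
        v = snv_at(wasl, toy_reference, 3, "T")
        c = classify(wasl, v)
        assert c.category == "start_loss"
        assert c.hgvs_c == "c.3G>T"
        assert c.hgvs_p == "p.M1-P5del"
        assert c.affected_residue == (1, 5)
        assert not c.whole_protein_loss

    def test_any_third_base_change_is_start_loss(self, wasl, toy_reference):
        v = snv_at(wasl, toy_reference, 3, "A")  # ATG -> ATA (Ile)
        assert classify(wasl, v).category == "start_loss"

    def test_no_downstream_atg_flags_whole_protein_loss(self):
        # hand-built CDS with no ATG after the initiator
        seq = "ATG" + "CCT" * 5 + "TGA"
        t = TranscriptModel(gene="N", chrom="c", strand="+", exons=((1, len(seq)),), sequence=seq)
        # oracle: scan codons 2..n for ATG
        codons = [seq[i : i + 3] for i in range(3, len(seq), 3)]
        assert "ATG" not in codons
        v = GenomicVariant("c", 3, "G", "T")
        c = classify_start_loss(t, v)
        assert c.category == "start_loss" and c.whole_protein_loss

    def test_deletion_count_matches_atg_scan(self, toy_genes, toy_reference):
        """For every toy gene, the start-loss deletion span is k-1 where k is
        the first downstream in-frame ATG found by direct scanning."""
        for t in toy_genes:
            codons = [t.sequence[i : i + 3] for i in range(0, t.cds_length, 3)]
            ks = [i + 1 for i, c in enumerate(codons) if c == "ATG" and i > 0]
            v = snv_at(t, toy_reference, 3, "T" if t.sequence[2] != "T" else "A")
            c = classify_start_loss(t, v)
            if ks:
                assert c.affected_residue == (1, ks[0] - 1)
            else:
                assert c.whole_protein_loss


class TestIndelAndSplice:
    def _transcript(self):
        rng = np.random.default_rng(5)
        # two exons with a 100 bp intron
        cds = "ATG" + "".join(
            np.random.default_rng(8).choice(["GCT", "CCT", "GAT", "TCT"], size=20)
        ) + "TAA"
        exon1 = (101, 101 + 32)
        exon2 = (exon1[1] + 101, exon1[1] + 101 + (len(cds) - 33) - 1)
        genome = "A" * 100 + cds[:33] + "G" * 100 + cds[33:] + "A" * 50
        t = TranscriptModel(gene="E", chrom="c", strand="+", exons=(exon1, exon2), sequence=cds)
        return t, {"c": genome}

    def test_frameshift_and_inframe(self):
        t, ref = self._transcript()
        pos = t.cds_to_genomic(10)
        base = ref["c"][pos - 1]
        del1 = GenomicVariant("c", pos, base + ref["c"][pos], base)  # 1 bp deletion
        assert classify_indel(t, del1).category == "frameshift_indel"
        del3 = GenomicVariant("c", pos, ref["c"][pos - 1 : pos + 3], base)
        assert classify_indel(t, del3).category == "inframe_indel"
        ins4 = GenomicVariant("c", pos, base, base + "ACGT")
        assert classify_indel(t, ins4).category == "frameshift_indel"

    def test_indel_spanning_junction_is_splicing(self):
        t, ref = self._transcript()
        end = t.exons[0][1]
        v = GenomicVariant("c", end - 1, ref["c"][end - 2 : end + 2], ref["c"][end - 2])
        assert classify_indel(t, v).category == "splicing"

    @pytest.mark.parametrize("offset,window,expected", [(1, 2, "splicing"), (3, 2, None), (1, 0, None)])
    def test_splice_window(self, offset, window, expected):
        t, ref = self._transcript()
        pos = t.exons[0][1] + offset
        base = ref["c"][pos - 1]
        alt = "C" if base != "C" else "T"
        v = GenomicVariant("c", pos, base, alt)
        got = classify_splice(t, v, window)
        if expected is None:
            assert got is None
        else:
            assert got.category == expected


class TestStrandSymmetry:
    def test_minus_strand_equivalent_consequences(self, rng):
        """A transcript and its reverse-complement twin yield identical
        consequences for corresponding genomic variants."""
        cds = "ATG" + "".join(
            ["ACT", "GGA", "CTT", "AGC", "TTC", "GAC", "CAT", "GGC"] * 3
        ) + "TAG"
        genome_plus = "TTTTT" + cds + "AAAAA"
        L = len(genome_plus)
        genome_minus = str(Seq(genome_plus).reverse_complement())
        t_plus = TranscriptModel(
            gene="P", chrom="p", strand="+", exons=((6, 5 + len(cds)),), sequence=cds
        )
        t_minus = TranscriptModel(
            gene="M", chrom="m", strand="-", exons=((L - (5 + len(cds)) + 1, L - 6 + 1),), sequence=cds
        )
        comp = str.maketrans("ACGT", "TGCA")
        for _ in range(200):
            cds_pos = int(rng.integers(1, len(cds) + 1))
            ref_sense = cds[cds_pos - 1]
            alt_sense = "ACGT"[int(rng.integers(4))]
            if alt_sense == ref_sense:
                continue
            vp = GenomicVariant("p", 5 + cds_pos, ref_sense, alt_sense)
            gpos_m = L - (5 + cds_pos) + 1
            vm = GenomicVariant("m", gpos_m, ref_sense.translate(comp), alt_sense.translate(comp))
            cp, cm = classify(t_plus, vp), classify(t_minus, vm)
            assert (cp.category, cp.hgvs_c, cp.hgvs_p) == (cm.category, cm.hgvs_c, cm.hgvs_p)


class TestSeverityDispatch:
    def test_intronic_far_from_exon_is_non_coding(self, toy_genes, toy_reference):
        multi = next(t for t in toy_genes if len(t.exons) > 1)
        pos = multi.exons[0][1] + 10
        base = toy_reference[multi.chrom][pos - 1]
        v = GenomicVariant(multi.chrom, pos, base, "A" if base != "A" else "C")
        assert classify(multi, v).category == "non_coding"
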