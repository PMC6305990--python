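"""The funnel filters, inheritance-pattern detection, and the compound-het
transmission-phasing logic."""

import itertools

import pytest

from quartetprio.annotations import AnnotationRecord
from quartetprio.consequence import Consequence
from quartetprio.pedigree import Pedigree, PedigreeMember
from quartetprio.prioritization import (
    CandidateVariant,
    PrioritizationError,
    ScoreThresholds,
    annotate_cpg,
    detect_compound_het,
    detect_inheritance,
    filter_by_scores,
    filter_nonsilent,
    filter_rare,
    shared_by_affected,
)
from quartetprio.synth import FATHER, MOTHER, SON1, SON2, default_pedigree
from quartetprio.variants import GenomicVariant, GenotypeCall

HOM_REF, HET, HOM_ALT = (0, 0), (0, 1), (1, 1)


def candidate(
    chrom="chr1",
    pos=100,
    ref="A",
    alt="T",
    category="nonsynonymous",
    gene="G1",
    gts=None,
    **ann,
):
    gts = gts or {FATHER: HOM_REF, MOTHER: HET, SON1: HET, SON2: HET}
    return CandidateVariant(
        variant=GenomicVariant(chrom, pos, ref, alt),
        consequence=Consequence(category=category, gene=gene),
        annotation=AnnotationRecord(key=(chrom, pos, ref, alt), gene=gene, **ann),
        genotypes={s: GenotypeCall(s, a) for s, a in gts.items()},
    )


class TestFilterRare:
    def test_kept_below_threshold_in_both(self):
        c = candidate(af_kg_asian=0.005, af_exac_nontcga=0.005)
        assert filter_rare([c]) == [c]

    def test_removed_when_common_in_one_source(self):
        c = candidate(af_kg_asian=0.005, af_exac_nontcga=0.02)
        assert filter_rare([c]) == []

    def test_missing_frequencies_kept(self):
        assert len(filter_rare([candidate()])) == 1

    def test_threshold_monotonicity(self):
        cands = [candidate(pos=100 + i, af_kg_asian=i / 100) for i in range(1, 40)]
        survivors = {t: {c.key for c in filter_rare(cands, threshold=t)} for t in (0.005, 0.01, 0.1)}
        assert survivors[0.005] <= survivors[0.01] <= survivors[0.1]

    def test_unknown_source(self):
        with pytest.raises(PrioritizationError, match="unknown frequency source"):
            filter_rare([candidate()], sources=["gnomad"])


class TestFilterNonsilent:
    @pytest.mark.parametrize(
        "category,kept",
        [
            ("synonymous", False), ("non_coding", False), ("stop_gain", True),
            ("start_loss", True), ("splicing", True), ("frameshift_indel", True),
            ("inframe_indel", True), ("stop_loss", True), ("nonsynonymous", True),
        ],
    )
    def test_categories(self, category, kept):
        out = filter_nonsilent([candidate(category=category)])
        assert bool(out) == kept

    def test_unannotated_errors(self):
        c = candidate()
        c.consequence = None
        with pytest.raises(PrioritizationError):
            filter_nonsilent([c])


class TestSharedByAffected:
    def test_both_sons_het_kept(self):
        assert len(shared_by_affected([candidate()], default_pedigree())) == 1

    def test_single_carrier_removed(self):
        c = candidate(gts={FATHER: HOM_REF, MOTHER: HET, SON1: HET, SON2: HOM_REF})
        assert shared_by_affected([c], default_pedigree()) == []

    def test_het_plus_hemizygous_kept(self):
        c = candidate(
            chrom="chrX",
            gts={FATHER: (0,), MOTHER: HET, SON1: (1,), SON2: (1,)},
        )
        assert len(shared_by_affected([c], default_pedigree())) == 1

    def test_missing_genotype_excluded(self):
        c = candidate(gts={FATHER: HOM_REF, MOTHER: HET, SON1: HET, SON2: (None, None)})
        assert shared_by_affected([c], default_pedigree()) == []

    def test_fewer_than_two_affected_refused(self):
        ped = Pedigree(members=[PedigreeMember("P", None, None, "male", True)])
        with pytest.raises(PrioritizationError, match="single-proband"):
            shared_by_affected([candidate()], ped)


class TestDetectInheritance:
    def test_x_linked_maternal(self):
        c = candidate(chrom="chrX", gts={FATHER: (0,), MOTHER: HET, SON1: (1,), SON2: (1,)})
        detect_inheritance(c, default_pedigree())
        assert c.patterns == {"x_linked"} and c.origin == "maternal"

    def test_autosomal_dominant_maternal_no_trio_pattern(self):
        c = candidate()  # mother het, father ref, sons het
        detect_inheritance(c, default_pedigree())
        assert c.patterns == set() and c.origin == "maternal"

    def test_de_novo(self):
        c = candidate(gts={FATHER: HOM_REF, MOTHER: HOM_REF, SON1: HET, SON2: HET})
        detect_inheritance(c, default_pedigree())
        assert c.patterns == {"de_novo"} and c.origin == "de_novo"

    def test_autosomal_recessive(self):
        c = candidate(gts={FATHER: HET, MOTHER: HET, SON1: HOM_ALT, SON2: HOM_ALT})
        detect_inheritance(c, default_pedigree())
        assert c.patterns == {"autosomal_recessive"} and c.origin == "both"

    def test_missing_parent_genotype_warns(self, caplog):
        c = candidate(gts={FATHER: (None, None), MOTHER: HET, SON1: HET, SON2: HET})
        with caplog.at_level("WARNING"):
            detect_inheritance(c, default_pedigree())
        assert c.patterns == set() and c.origin == "undetermined"

    def test_never_de_novo_when_parent_carries(self):
        """Property over all parental genotype combinations: de novo requires
        both parents homozygous reference."""
        for f, m in itertools.product([HOM_REF, HET, HOM_ALT], repeat=2):
            c = candidate(gts={FATHER: f, MOTHER: m, SON1: HET, SON2: HET})
            detect_inheritance(c, default_pedigree())
            if "de_novo" in c.patterns:
                assert f == HOM_REF and m == HOM_REF

    def test_never_x_linked_off_chromosome_x(self):
        for chrom in ("chr1", "chr22"):
            c = candidate(chrom=chrom, gts={FATHER: HOM_REF, MOTHER: HET, SON1: HOM_ALT, SON2: HOM_ALT})
            detect_inheritance(c, default_pedigree())
            assert "x_linked" not in c.patterns


class TestCompoundHet:
    def _pair(self, father2, mother2):
        ped = default_pedigree()
        v1 = candidate(pos=100, gene="G", gts={FATHER: HOM_REF, MOTHER: HET, SON1: HET, SON2: HET})
        v2 = candidate(pos=200, gene="G", gts={FATHER: father2, MOTHER: mother2, SON1: HET, SON2: HET})
        for c in (v1, v2):
            detect_inheritance(c, ped)
        return detect_compound_het([v1, v2], ped), v1, v2

    def test_trans_pair_flagged(self):
        pairs, v1, v2 = self._pair(HET, HOM_REF)
        assert len(pairs) == 1
        assert v1.patterns == {"compound_het"}
        assert v1.compound_het_partner == v2.key

    def test_cis_by_transmission_not_flagged(self):
        pairs, *_ = self._pair(HOM_REF, HET)  # both maternal
        assert pairs == []

    def test_exhaustive_parental_genotypes_match_phase_oracle(self):
        """v1 is maternal-only; over all 3x3 parental genotype combinations
        for v2, a pair is flagged iff transmission phases v2 to the father
        alone (the brute-force trans-configuration rule)."""
        for f2, m2 in itertools.product([HOM_REF, HET, HOM_ALT], repeat=2):
            pairs, *_ = self._pair(f2, m2)
            father_only = f2 != HOM_REF and m2 == HOM_REF
            assert bool(pairs) == father_only, (f2, m2)

    def test_missing_gene_symbol_skipped(self, caplog):
        ped = default_pedigree()
        v1 = candidate(pos=100, gene="")
        v2 = candidate(pos=200, gene="")
        with caplog.at_level("WARNING"):
            assert detect_compound_het([v1, v2], ped) == []


class TestScoreGate:
    def _missense(self, **ann):
        return candidate(**ann)

    def test_all_four_pass(self):
        c = self._missense(sift=0.01, polyphen2=0.99, mutation_taster="disease_causing", mcap=0.03)
        assert filter_by_scores([c]) == [c]

    def test_boundary_inclusivity(self):
        kept = self._missense(sift=0.05, polyphen2=0.957, mutation_taster="disease_causing", mcap=0.026)
        assert filter_by_scores([kept]) == [kept]
        dropped = self._missense(sift=0.05, polyphen2=0.957, mutation_taster="disease_causing", mcap=0.025)
        assert filter_by_scores([dropped]) == []

    def test_missing_score_fails(self):
        c = self._missense(sift=0.01, polyphen2=0.99, mutation_taster="disease_causing")  # no mcap
        assert filter_by_scores([c]) == []

    def test_truncating_passes_through_scoreless(self):
        c = candidate(category="stop_gain")
        assert filter_by_scores([c]) == [c]

    def test_custom_thresholds(self):
        c = self._missense(sift=0.2, polyphen2=0.5, mutation_taster="disease_causing", mcap=0.5)
        assert filter_by_scores([c], ScoreThresholds(sift_max=0.3, polyphen2_min=0.4)) == [c]


class TestCpgAndComposition:
    def test_flag_count_equals_intersection(self, rng):
        genes = [f"G{i}" for i in range(30)]
        cands = [candidate(pos=100 + i, gene=g) for i, g in enumerate(genes)]
        cpg = {g for g in genes if rng.random() < 0.3}
        annotate_cpg(cands, cpg)
        assert sum(c.annotation.is_cpg_gene for c in cands) == len(cpg)

    def test_empty_cpg_list_warns(self, caplog):
        with caplog.at_level("WARNING"):
            annotate_cpg([candidate()], [])

    def test_independent_filters_commute(self):
        cands = [
            candidate(pos=100, category="synonymous", af_kg_asian=0.005),
            candidate(pos=101, category="stop_gain", af_kg_asian=0.2),
            candidate(pos=102, category="nonsynonymous"),
            candidate(pos=103, category="non_coding"),
        ]
        ab = filter_nonsilent(filter_rare(cands))
        ba = filter_rare(filter_nonsilent(cands))
        assert {c.key for c in ab} == {c.key for c in ba}

    def test_every_filter_returns_subset(self):
        cands = [candidate(pos=100 + i) for i in range(10)]
        keys = {c.key for c in cands}
        for fn in (filter_rare, filter_nonsilent, filter_by_scores):
            assert {c.key for c in fn(cands)} <= keys
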