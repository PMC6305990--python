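# Methods

## Problem setting

The package targets a specific study design: a nuclear family with two
healthy parents and two (or more) affected children, whole-genome genotyped
by two independent variant-calling pipelines, where the causal hypothesis
is one or more rare germline variants shared by the affected sibs. The
variant arm narrows a genome-scale call set down to a handful of
classifiable candidates; the expression arm asks whether a pathway of
interest is coordinately up- or down-regulated between two conditions.

## Variant representation and consensus

Coordinates are 1-based and fully closed, as in VCF. Multiallelic records
are split before anything else: for each alternate allele, per-sample
genotype indices are remapped so the tracked allele becomes 1 and
everything else (reference or a non-tracked alternate) becomes 0; the
collapse is logged. Hemizygous calls (single-allele genotypes, e.g. males
on chrX) are preserved as length-1 allele tuples.

Normalization reduces every allele pair to the minimal left-aligned
representation: shared trailing bases are trimmed (left-extending with
reference bases whenever an allele would become empty), then shared leading
bases are trimmed while both alleles keep length > 1. The procedure is
idempotent and preserves the edited haplotype, which the test suite proves
against a brute-force oracle that enumerates every parsimonious equivalent
representation in a context window. Consensus intersection then keys on
normalized `(chrom, pos, ref, alt)`; genotypes are taken from the first
caller, with a logged warning when the two callers disagree — the analysis
needs carrier status more than exact genotype concordance, and the first
caller is by convention the pedigree-aware one.

## Consequence model

Transcripts are exon lists plus a spliced CDS (ATG…stop, length divisible
by 3, no UTRs). Classification is strand-aware; a minus-strand transcript
gives the same consequence as its reverse-complemented twin (property
tested). One consequence is reported per variant; across multiple
transcripts the most severe wins, with severity ordered stop_gain >
frameshift > start_loss > splicing > stop_loss > nonsynonymous >
inframe_indel > synonymous > non_coding.

Substitutions translate the affected codon only, which the tests check
against a full-CDS translation diff. Stops are written `X` in the compact
one-letter protein dialect (`p.R536X`), matching clinical reporting of
truncating variants rather than three-letter HGVS.

Start-loss calls use a re-initiation model: any SNV destroying the
initiator ATG scans downstream for the next in-frame ATG at codon *k* and
reports a deletion of residues 1..k−1 (`p.M1-P5del` when *k* = 6). The
agnostic `p.Met1?` notation is deliberately not used because the model here
assumes the shortened protein is produced; with no downstream in-frame ATG
the call carries a whole-protein-loss flag instead. The splice window is 2
intronic bases (canonical GT/AG dinucleotides), configurable; indels that
touch both exonic and intronic bases are reported as splicing, taking
precedence over frameshift.

## The prioritization funnel

Stages run in a fixed order, each returning a subset of its input:

1. **Rarity** — keep variants with frequency < 0.01 in *every* configured
   source (1000 Genomes Asian-ancestry and ExAC non-TCGA columns in the
   annotation table). The conjunctive reading is the stricter of the two
   possible interpretations of a multi-source MAF filter and the common
   practice. Missing frequency counts as rare (absent-from-controls), which
   also drives the PM2 convenience suggestion.
2. **Non-silent** — drop synonymous and non-coding.
3. **Shared by affected** — every affected member carries ≥ 1 alternate
   allele (hemizygous alternate counts). Requires ≥ 2 affected members;
   single-proband analysis is out of scope.
4. **Cancer-predisposition flagging** — annotate-only, case-insensitive
   symbol match against a user-supplied gene list.
5. **Inheritance patterns** — de novo (affected child carries, both parents
   homozygous reference), autosomal recessive (affected homozygous
   alternate, parents het), X-linked (chrX, affected males
   hemizygous/homozygous alternate, mother a carrier, father reference —
   father-to-son X transmission being impossible), and compound
   heterozygotes phased by transmission: within one gene, both affected
   children het at two sites, one variant carried by the mother only and
   the other by the father only. A variant present in both parents is
   phase-unresolvable by transmission and is never flagged; homozygous
   children route to the recessive pattern instead.
6. **Score gate** (missense only) — SIFT ≤ 0.05 AND PolyPhen2 ≥ 0.957 AND
   MutationTaster "disease causing" AND M-CAP > 0.025. A missing score
   fails the gate: the gate exists to demand affirmative computational
   support, and treating absence as a pass would let unscored variants
   through the strictest stage. Truncating, initial-codon, splicing and
   indel candidates bypass the gate entirely.
7. **ACMG-AMP combining** — see below. Evidence *assignment* is a curation
   input carried in the annotation table; deciding that a variant merits
   PVS1 or PS1 needs disease-gene knowledge the package does not model.
   Only a PM2 suggestion from missing population frequencies is offered.

The funnel report records counts at each stage; they are non-increasing by
construction along the main path.

## ACMG-AMP engine

Evidence tokens are codes with optional strength suffixes (`PP1-S` = PP1 at
strong). Counting is by *effective* level, so overrides participate at
their overridden strength — this is what lets a strong-applied segregation
criterion combine with PVS1 to fire the top clause. Pathogenic clauses, in
reporting order Ia (≥1 very strong + ≥1 strong), Ib (+ ≥2 moderate), Ic
(+ 1 moderate + 1 supporting), Id (+ ≥2 supporting), II (≥2 strong), III
(1 strong with moderate/supporting combinations); the earliest satisfied
label is reported. Likely-pathogenic and benign-side clauses follow the
standard table. A conflict (→ uncertain significance with a flag) is
declared only when both sides independently reach a likely/definite
classification; isolated benign-supporting evidence does not veto a
pathogenic combination. The test suite proves the engine equal to a literal
clause-table enumeration over all evidence multisets with ≤ 2 criteria per
level, plus permutation invariance and pathogenic-side monotonicity.

## Preranked GSEA

Genes are ranked by `log2(mean_case + ε) − log2(mean_control + ε)` with
ε = 1.0 by default (guards zero expression; configurable), descending, ties
broken lexicographically so ranking is deterministic. The enrichment score
is the signed maximum deviation of the weighted running sum (hit increments
|score|^exponent normalized over hits, miss decrements 1/(N−N_hits);
exponent 1 by default). Exact ties between peak and trough resolve to the
positive peak. The vectorized ES and a hit-position-only fast path used for
permutations are proven equal to a brute-force running-sum enumeration, and
the weighted ES is cross-checked against an independent open-source GSEA
implementation on a small instance.

The null permutes *gene labels* (sets of matched size drawn uniformly
without replacement) — the only null available to a preranked list, since
sample labels are not part of the input. Nominal p uses a pseudo-count,
`(1 + #{same-sign null ES at least as extreme}) / (1 + #same-sign null)`,
so it is never 0. NES divides ES by the mean |null ES| of the same sign;
FDR q is the NES-ratio estimator (pooled-null tail fraction over observed
tail fraction), clipped to [0, 1]. These follow the original published
estimators; exact numeric agreement of NES/p/q with any particular desktop
tool is not promised, only the documented construction. Default 1000
permutations; fewer than 100 is refused because the tail estimates become
unstable.

## Synthetic cohorts

`make_toy_genes` builds one gene per toy chromosome: random CDSs (60–120
codons) over 1–3 exons, a quarter of the background genes on the minus
strand, plus two designated hosts — an autosomal 540-codon gene with CGA at
CDS 1606–1608 (so `c.1606C>T` truncates at residue 536) and a chrX gene
with ATG at codon 6, no earlier in-frame ATG, and a proline at codon 5 (so
`c.3G>T` yields `p.M1-P5del`).

`simulate_quartet` plants, per class: the two signature variants (maternal
dominant stop-gain; X-linked start-loss hemizygous in both sons), compound
heterozygous missense pairs in three genes by default, optional de novo and
autosomal-recessive variants, shared synonymous variants, caller-discordant
variants present in only one caller's output, and a common background
(default 150 variants, allele frequencies uniform on 0.02–0.5, so the
rarity filter removes them; ~20 % are deletions that caller B emits
right-shifted, exercising normalization inside the consensus). Genotypes
are constructed per class, not drawn from a population model — the quartet
is deliberately not a Hardy–Weinberg sample. Background in-silico scores
are drawn from Beta distributions skewed benign (SIFT ~ Beta(0.8, 3),
PolyPhen2 ~ Beta(2, 2), M-CAP ~ Beta(1, 12), 30 % "disease causing"); any
accidental four-way pass is broken by resampling SIFT above its cutoff, so
background missense never passes the gate. One compound-het variant is
given gate-passing scores and moderate/supporting-only evidence so the
funnel's last two stages are exercised by a candidate that survives scoring
but not classification. Curated evidence strings for the signature plants
are part of the generated annotation table (evidence is an input to the
engine, so the generator supplies it the way a curator would). Every
dataset ships a truth table (class, origin, should-survive flag) and passes
a self-audit that re-derives each class from the emitted genotypes;
generation is a pure function of (spec, seed) and is byte-identical across
runs.

`simulate_expression` draws log-normal baselines (log2 means ~ N(6, 1.5)),
multiplies a planted set (default 50 genes) by `fold` in the case group,
adds N(0, noise_sd²) on the log2 scale per sample (defaults: fold 2, noise
0.25, 5 samples per group, 19 size-matched random decoy sets). These
defaults define the recovery condition the tests check: the planted set
top-ranked by NES with q < 0.05 in ≥ 18 of 20 seeds, and approximately
uniform nominal p at fold 1.

What the synthetic data does *not* emulate: linkage disequilibrium and
population structure, sequencing error and coverage variation, multi-gene
chromosomes, UTR/regulatory annotation, and realistic score correlation
between the four in-silico predictors. Passing tests therefore demonstrate
the correctness of the pipeline's logic under clean Mendelian signal, not
its robustness to real-data artifacts.

## Problem sizes and numeric choices

Test and acceptance runs use deliberately small instances chosen as the
smallest sizes at which every code path is exercised: quartets with ~20
genes and 60–150 background variants across 20 seeds; expression matrices
of 1000 genes × 10 samples with 200 permutations per set (the package
default is 1000 permutations). Funnel recovery is exact by design (the
generator guarantees background never passes the gate), so those checks use
equality, not tolerance. Floating-point tie-breaks: ES sign ties resolve
positive within 1e-9; gene-rank ties resolve lexicographically; equal-count
ACMG clauses resolve to the earliest label.

## Known limitations

- Evidence assignment is manual by design; the engine only combines.
- No gVCF, structural variants, tabix random access, or phased input
  (caller phase flags are read but ignored — phasing is re-derived from
  transmission).
- X-inactivation, mosaicism and incomplete penetrance are not modeled; the
  X-linked rule assumes full penetrance in hemizygous males.
- The GSEA FDR estimator is the simple NES-ratio form without the running
  minimum some implementations apply; q values can exceed nominal p for
  mid-ranked sets.
- Real accession loaders are out of scope; the expression arm expects the
  documented two-header TSV.
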