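"""Preranked GSEA on a synthetic two-condition expression matrix.

Plants a 50-gene pathway up-regulated 2-fold in the case group (log2-scale
noise sd 0.25), ranks all genes by log2 fold change, and tests the planted
set against 19 size-matched random decoys with a gene-label permutation
null.
"""

from quartetprio import permutation_stats, rank_genes, simulate_expression

expr, conditions, gene_sets, planted_name = simulate_expression(
    n_genes=1000, n_per_group=5, planted_size=50, fold=2.0, noise_sd=0.25, seed=7
)
case = expr[[s for s in expr if conditions[s] == "case"]]
control = expr[[s for s in expr if conditions[s] == "control"]]

ranked = rank_genes(case, control)
results = permutation_stats(ranked, gene_sets, n_perm=500, seed=7)

print(f"{'set':22s} {'size':>4} {'ES':>7} {'NES':>7} {'p':>8} {'q':>6}")
for r in results[:5]:
    print(f"{r.name:22s} {r.n_hits:>4} {r.es:>7.3f} {r.nes:>7.3f} {r.p_nominal:>8.4f} {r.fdr_q:>6.3f}")

top = results[0]
print(
    f"\ntop set is the planted pathway: {top.name == planted_name}; "
    f"leading edge carries {len(top.leading_edge)}/{top.n_hits} members"
)

# The planted pathway tops the ranking with ES near 1, a nominal p at the
# permutation floor (no null draw is as extreme), and FDR q below 0.05;
# decoy sets hover around |NES| ~ 1 with large p.
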