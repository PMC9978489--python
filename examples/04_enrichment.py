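"""Hypergeometric over-representation analysis with BH FDR.

One gene set is planted to share 20 genes with the query; it should
rank first at a p-value far below the 0.05 (-log10 p > 1.3) threshold,
while the random sets hover near uniform.
"""

from cernax import gen_gene_sets, run_ora

universe = [f"GENE{i:04d}" for i in range(300)]
collection, query, planted = gen_gene_sets(
    universe, n_sets=12, planted_query_overlap=20, seed=7
)
results = run_ora(query, collection, universe)

print(f"query of {len(query)} genes vs {len(collection)} sets (universe {len(universe)})")
print(f"{'set':22s} {'k/K':>7s} {'p':>10s} {'FDR':>10s}  significant")
for r in results[:5]:
    print(
        f"{r.set_name:22s} {r.k:>3d}/{r.K:<3d} {r.p_value:>10.2e} {r.fdr:>10.2e}  "
        f"{r.significant_fdr}"
    )
print(f"planted set {planted!r} ranks first: {results[0].set_name == planted}")
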