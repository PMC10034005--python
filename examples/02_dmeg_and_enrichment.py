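"""Intersect methylation and expression calls into the four DMEG groups,
union across regions, and test a gene set for over-representation.
"""

from epidrug import differential, dmeg, synthetic

cfg = synthetic.CohortConfig(
    n_tumor=60, n_normal=60, n_genes=120,
    planted_dmeg={"HyperUp": 10, "HyperDown": 10, "HypoUp": 10, "HypoDown": 10},
    seed=1,
)
beta, manifest, truth = synthetic.generate_methylation(cfg)
expr = synthetic.generate_expression(cfg, truth)
tumor, normal = synthetic.sample_ids(cfg)
groups = {s: "tumor" for s in tumor} | {s: "normal" for s in normal}

deg = differential.diff_expression(expr, groups)
tables = []
for region in ("Body", "TSS200", "TSS1500"):
    meth = differential.diff_methylation(differential.aggregate_probes(beta, manifest, region), groups)
    tables.append(dmeg.intersect_dmeg(meth, deg, region))

union, counts = dmeg.union_dmeg(tables)
print("DMEG group counts:", counts, "| union size:", len(union))
print("(the four groups always partition the union: counts sum to the union size)")

# over-representation of the HyperDown genes inside a gene set that contains them
query = sorted(union.loc[union["group"] == "HyperDown", "gene"])
collection = {"planted_hyperdown": truth.dmeg_genes["HyperDown"] + ["G00001"]}
res = dmeg.ora_enrichment(query, collection, universe=list(expr.index))
row = res.iloc[0]
print(f"ORA: overlap {row['overlap']}/{row['set_size']} of the set, "
      f"hypergeometric p = {row['p']:.3g} (tiny p = the query is enriched in the set)")
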