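"""Call region-level differential methylation and differential expression
on a synthetic cohort with planted effects, and count the recovered genes.
"""

from epidrug import differential, synthetic

cfg = synthetic.CohortConfig(
    n_tumor=60, n_normal=60, n_genes=120,
    planted_dmeg={"HyperUp": 10, "HyperDown": 10, "HypoUp": 10, "HypoDown": 10},
    seed=1,
)
beta, manifest, truth = synthetic.generate_methylation(cfg)
expr = synthetic.generate_expression(cfg, truth)
tumor, normal = synthetic.sample_ids(cfg)
groups = {s: "tumor" for s in tumor} | {s: "normal" for s in normal}

for region in ("Body", "TSS200", "TSS1500"):
    region_beta = differential.aggregate_probes(beta, manifest, region)
    res = differential.diff_methylation(region_beta, groups)
    hyper = (res["status"] == "Hyper").sum()
    hypo = (res["status"] == "Hypo").sum()
    print(f"{region:8s}: {hyper} hypermethylated, {hypo} hypomethylated genes")

deg = differential.diff_expression(expr, groups)
print(f"expression: {(deg['status'] == 'Up').sum()} up, {(deg['status'] == 'Down').sum()} down")
print("planted per group: 10 hyper + 10 hypo in methylation, 10 up + 10 down in expression;")
print("counts above should match because planted effects exceed the FDR<0.01, |effect| thresholds.")
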