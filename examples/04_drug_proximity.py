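"""Screen drugs by weighted network proximity to a disease module and rank
them by permutation z-score.
"""

from epidrug import proximity, synthetic

G, drug_table, truth = synthetic.generate_network(synthetic.NetworkConfig(seed=5))
drugs = {d: set(g["target_gene"]) for d, g in drug_table.groupby("drug_id")}

result = proximity.screen_drugs(truth.disease_genes, drugs, G, n_perm=10_000, seed=5)
print(result.head(5).to_string(index=False, float_format=lambda x: f"{x:.3f}"))
print(f"\nplanted proximal drugs: {truth.proximal_drugs}")
print("d_obs is the mean shortest-path distance of a drug's targets to the disease")
print("module, minus ln(degree+1) for targets inside it; z standardizes d_obs against")
print("size-matched random target sets. The most negative z = the most proximal drug.")
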