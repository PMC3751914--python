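"""Simulate a factorial sorting experiment and rank genes by PWF.

Generates 1000 genes over 3 experiments x (sorted pos/neg) x
(treated/untreated), fits the per-transcript mixed model, and ranks
genes by proportion-weighted F for the 'sorted' term.
"""

import pwfrank as pw

config = pw.SimulationConfig(
    n_genes=1000,
    proportions=(0.10, 0.05, 0.02),  # sorted / treatment / interaction classes
    effect_mean=2.0,                 # log2 units
    noise_sd=0.25,
    seed=42,
)
expr, design, truth = pw.simulate_expression(config)
print(f"expression matrix: {expr.shape[0]} genes x {expr.shape[1]} samples")

stats = pw.fit_all_transcripts(expr, design, method="blocked")
rankings = pw.compute_pwf(stats)
sorted_ranking = rankings["sorted"]

top10 = pw.top_genes(sorted_ranking, 10)
print("\ntop 10 genes for the sorted term (gene, PWF, true class):")
for gene in top10:
    row = sorted_ranking.loc[gene]
    cls = truth.genes.loc[gene, "effect_class"]
    print(f"  {gene}  pwf={row['pwf']:9.1f}  rank={int(row['rank']):4d}  {cls}")

hits = (truth.genes.loc[pw.top_genes(sorted_ranking, 100), "effect_class"]
        == "sorted").sum()
print(f"\n{hits}/100 of the top-100 sorted-term genes are true sorted-class "
      "genes -- the PWF ranking recovers the planted single-factor signal.")

z = pw.zscore_matrix(expr, top10)
print(f"z-scored heat-map matrix for the top genes: {z.shape}, "
      f"row means ~0, row SDs ~1")
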