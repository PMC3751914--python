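"""Cross-platform validation arithmetic on the bundled fold-change panel.

Regresses qPCR on microarray signed-log10 fold changes, checks per-gene
direction agreement, and demonstrates the delta-delta-Ct round trip and
the phosphoprotein ratio filter.
"""

import pwfrank as pw

x, y = pw.validation_regression_inputs()
fit = pw.crossplatform_regression(x, y)
print("microarray vs qPCR regression (signed log10 fold changes):")
print(f"  slope={fit['slope']:.2f}  intercept={fit['intercept']:.2f}  "
      f"R^2={fit['r_squared']:.2f}  n={fit['n_points']}")

series = pw.validation_direction_inputs()
agree = pw.direction_concordance(series["microarray"], series["qpcr"])
discordant = list(agree.index[~agree["concordant"]])
print(f"\nmRNA direction concordance: {int(agree['concordant'].sum())}/"
      f"{len(agree)} genes agree; discordant: {discordant}")

table = pw.simulate_ct_table({"CCR7": -2.70, "THBD": 3.06}, seed=0)
for gene in ("CCR7", "THBD"):
    out = pw.delta_delta_ct(table, gene, "pos", "neg")
    print(f"\nddCt round trip for {gene}: ddCt={out['ddct']:+.2f}, "
          f"RQ={out['relative_quantity']:.3f}, FC={out['fold_change']:+.2f}")

ratios = {"CDK1/2": 1.45, "Rb": 1.31, "MEK1/2": 0.72, "ERK1": 0.83, "p38a": 1.18}
passing = pw.phospho_ratio_filter(ratios, threshold_pct=25)
print(f"\nphosphoproteins changed by >25%: {passing} "
      "(symmetric multiplicative bound)")
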