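"""Compare an observed PWF curve against a permutation null envelope.

Sample labels are shuffled within experiment blocks 500 times; each
shuffle yields a sorted PWF-by-rank curve, and the envelope records the
mean and 95th percentile at every rank.  A real sorted-status signal
pushes the observed curve far above the envelope over the top ranks.
"""

import pwfrank as pw

config = pw.SimulationConfig(
    n_genes=1000, proportions=(0.10, 0, 0),
    effect_mean=3.0, noise_sd=0.2, seed=7,
)
expr, design, _ = pw.simulate_expression(config)

envelope = pw.build_envelope(expr, design, n_permutations=500, seed=8)
rankings = pw.compute_pwf(pw.fit_all_transcripts(expr, design, method="blocked"))

print("term         ranks above 95th pctile   contiguous run from rank 1")
for term in pw.TERMS:
    out = pw.summarize_exceedance(rankings[term], envelope.curves[term])
    print(f"{term:12s} {out['n_exceed']:8d} / 1000          "
          f"{out['contiguous_from_top']:6d}")

print(
    "\nThe sorted term exceeds the null envelope over a long top-rank run\n"
    "(the planted 10% of sorted-class genes), while treatment and\n"
    "interaction stay at chance level -- the curve-level analogue of a\n"
    "significance test for each model term."
)
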