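# pwfrank

Factor-specific transcript ranking and gene-set enrichment for small
replicated factorial expression designs.

## The problem

A recurring design in cell-sorting transcriptomics: cultures from a few
independent experiments are split by a surface marker ("sorted":
marker-positive vs marker-negative cells) and by a culture treatment
("treatment": treated vs untreated), giving a 2×2 layout per experiment
(e.g. 3 experiments × 4 conditions = 12 arrays).  The question is not
only *which* transcripts change, but *which factor* each transcript
responds to — sorting status, treatment, or their interaction — and
which pathways those factor-specific transcripts implicate.

`pwfrank` implements that inference chain as a library:

1. **Per-transcript linear mixed model.**  Each gene's log2 profile is
   fit with three 1-df fixed effects (sorted, treatment,
   sorted:treatment; ±½ sum coding) and a random intercept for the
   experiment block; each term's F statistic equals the squared t of
   its coefficient.  Fits that fail or collapse to the zero-variance
   boundary are refit with experiment as fixed blocks; a vectorized
   fixed-block path (`method="blocked"`) gives identical F values on
   balanced designs at matrix scale.

2. **Proportion-weighted F (PWF).**  Raw F does not single out
   transcripts that depend on *one* factor specifically, so each term's
   F is weighted by its share of the gene's total F:

       PWF_t = F_t · F_t / (F_sorted + F_treatment + F_interaction)

   A pure single-factor gene keeps its full F; a gene dominated by
   another factor is de-emphasized.  Genes are ranked per term by
   descending PWF (ties broken by gene id).

3. **Permutation null envelopes.**  Sample labels are permuted within
   experiment blocks (default 500×); each permutation's sorted
   PWF-by-rank curve is aggregated into per-rank mean and 95th
   percentile curves.  An observed curve above the envelope over a long
   top-rank run indicates real factor-specific structure.

4. **CERNO gene-set enrichment.**  Coincident Extreme Ranks in
   Numerical Observations: S = −2 Σ ln(rank_i/N) over a set's members,
   χ² with 2k df under the null, Benjamini–Hochberg FDR across the
   catalog.  Sets with q below a threshold and their genes with PWF
   quantile below a threshold form a binary **design structure matrix**
   (sets × genes) ordered by average-linkage clustering on Canberra
   distance.

5. **Concordance validation.**  Signed fold-change conventions
   (x-fold down = −x), ΔΔCt relative quantification against a reference
   gene, signed-log10 cross-platform regression, direction-of-change
   concordance, and a symmetric multiplicative ratio filter for
   phosphoprotein panels.  A 15-gene microarray/qPCR/protein validation
   panel is bundled.

A synthetic-data generator (`simulate_expression`, `simulate_gene_sets`,
`simulate_ct_table`) produces datasets with this exact structure plus
ground-truth labels, so every stage is testable by recovery.

## Worked example

```python
import pwfrank as pw

config = pw.SimulationConfig(n_genes=1000, proportions=(0.10, 0.05, 0.02),
                             effect_mean=2.0, noise_sd=0.25, seed=42)
expr, design, truth = pw.simulate_expression(config)
stats = pw.fit_all_transcripts(expr, design, method="blocked")
ranking = pw.compute_pwf(stats)["sorted"]
top = pw.top_genes(ranking, 100)
print((truth.genes.loc[top, "effect_class"] == "sorted").sum())
```

prints `99`: 99 of the top-100 genes in the sorted-term PWF ranking are
true sorted-class genes.  Running `python examples/02_permutation_envelope.py`
prints

```
term         ranks above 95th pctile   contiguous run from rank 1
sorted            166 / 1000             154
treatment           5 / 1000               2
interaction         1 / 1000               1
```

— the planted sorted-status signal (10% of genes, 3 log2-unit effects)
lifts the observed sorted curve above the 95th-percentile null envelope
over the top 154 ranks, while the treatment and interaction curves stay
at the ~5%-of-ranks chance level.  `examples/04_validation_concordance.py`
prints the bundled-panel regression
`slope=1.60  intercept=0.16  R^2=0.78  n=14` and the single discordant
mRNA (`TNFA`).  One narrative script per capability lives in
`examples/`; a thin CLI (`pwfrank simulate|rank|mirna|permtest|cerno|dsm|
concordance|ddct|run-all`) wraps the same functions for shell use.

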