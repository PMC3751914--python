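# Methods

## Model

Each transcript g with log2 profile y_g over n samples is modelled as

    y_g = μ + β_s·s + β_t·t + β_st·s·t + b_e + ε,
    b_e ~ N(0, σ²_exp),  ε ~ N(0, σ²),

where s, t ∈ {−½, +½} encode sorted status and treatment (sum coding)
and b_e is a random intercept shared by all arrays of experiment e.
With one array per 2×2 cell per experiment the three fixed-effect
columns are mutually orthogonal and orthogonal to the block structure,
so each term's Wald F equals the squared t of its coefficient and —
for any positive variance-component estimate — equals the F from the
model with experiment as fixed blocks.  p-values use the F(1, ν)
reference with ν = n − 4 − (n_exp − 1) residual degrees of freedom
(the within-block df; ν = 6 at 12 samples), for both engines.

Fitting engines:

- `mixed` — statsmodels `MixedLM`, REML, per gene.  The fit falls back
  to fixed experiment blocks (`fit_method = "fixed-fallback"`) when the
  optimizer fails, does not converge, or the experiment variance
  component lands at its zero boundary.  The boundary test is
  σ̂²_exp ≤ 10⁻³·σ̂²: below that the REML solution is a numerically
  smeared zero and its Wald F drifts from the blocked F only through
  the arbitrary stopping point, so the blocked refit is the cleaner
  description of the same model.  Empirically the two engines then
  agree to well under 1% on essentially all genes when σ²_exp = 0
  (tested).
- `blocked` — one vectorized OLS with experiment dummies for all genes
  at once.  Permutation work (500 refits of the whole matrix) uses this
  path; the balanced design makes it F-equivalent to the mixed fit, and
  that equivalence is itself under test rather than assumed.

Constant profiles are flagged degenerate: no F values, ranked after all
rankable genes, excluded from the ranking denominator N so quantiles
reflect rankable genes only.

## PWF ranking

PWF_t(g) = F_t(g)²/Σ_u F_u(g), and 0 where all three F vanish.  The
form has the properties that motivate it: PWF_t ≤ F_t with equality iff
the other terms are zero; Σ_t PWF_t ≤ max_t F_t (Cauchy–Schwarz); and
the top term by PWF is the top term by F.  These are verified
exhaustively over 10⁵ random F triples.  Ranks are descending in PWF
with ties broken by ascending gene id — a platform-independent total
order (ties are measure-zero on real data but the rule makes serialized
outputs byte-stable).

## Permutation envelopes

Null curves are produced by permuting the (sorted, treatment) label
pairs *within* each experiment block, preserving the block structure
the random effect conditions on (the alternative — global permutation —
would mix experiment intercepts into the null and inflate it).  Each
permutation's per-term PWF values are sorted descending; the envelope
is the per-rank mean and the nearest-rank empirical 95th percentile
over permutations.  Sorted curves are non-increasing, and order
statistics of sorted curves inherit that monotonicity.  Permutations
leaving a condition cell globally empty are redrawn and counted; with
every block containing all four cells this cannot trigger.

The exceedance summary counts ranks where the observed PWF strictly
exceeds the 95th-percentile curve, plus the contiguous run from rank 1.
On exchangeable null data the per-rank exceedance probability is 5% by
construction, but the indicators are strongly correlated along the
curve (it is a curve of order statistics), so a single dataset's
exceedance *fraction* is nearly all-or-nothing (SD ≈ 0.11 across
realizations).  Coverage is therefore tested as an average over
independent null replicate datasets scored against a shared envelope —
valid because the blocked fit absorbs block intercepts, making the null
F distribution identical across replicate datasets of the same
configuration.

## CERNO and selection

S = −2 Σ_{i∈set} ln(rank_i/N) over the k members with measured ranks;
p is the upper χ²_{2k} tail.  The χ² null is exact for k = 1 at any N
and is a with-replacement approximation for k > 1: against the exact
distribution over distinct-rank subsets the tail error is O(k/N) —
up to ~0.14 at N = 12 but below 0.02 by N = 100 (verified by exhaustive
enumeration), a non-issue at transcriptome scale.  Sets with k = 0
after intersecting the ranking are untestable and excluded from the
BH family; BH is the standard step-up (statsmodels), checked against a
brute-force oracle.  Selection for the design structure matrix uses
strict inequalities: set q < 10⁻⁴, gene PWF quantile < 0.01 (or 0.001
for a stricter gene list), and genes must belong to a selected set.

## DSM clustering

Membership is binary sets × genes.  Both axes are ordered by
average-linkage agglomerative clustering on Canberra distance
(Σ|u−v|/(|u|+|v|), 0/0 → 0; on binary vectors this is the Hamming
distance over coordinates not both zero).  Average linkage is the
package's choice for binary membership profiles; leaf order resolves
dendrogram child order deterministically by the smaller minimum
original index, so repeated runs give identical orders.  Gene columns
are clustered on membership vectors, not expression profiles — the
matrix is a statement about set structure; the companion heat map
(z-scored expression via `zscore_matrix`) carries the expression
information.

## Concordance arithmetic

Signed fold changes map a log2 difference Δ to 2^Δ (Δ ≥ 0) or −2^(−Δ)
(Δ < 0); no valid value lies in (−1, 1) and the mapping round-trips
exactly.  ΔΔCt: ΔCt = Ct_gene − Ct_ref per condition, ΔΔCt differenced
across conditions, RQ = 2^(−ΔΔCt) under the exact-doubling assumption.
The cross-platform regression transforms both axes by sign(fc)·log10|fc|
and fits OLS of qPCR on microarray; entries sharing an index (several
array probes per qPCR assay) are averaged after transformation, and
non-determined entries are excluded.  The phosphoprotein filter is
symmetric on the multiplicative scale: ratio > 1 + θ/100 or
< 1/(1 + θ/100), both strict.

The bundled validation panel records one row per microarray probe for
15 genes (17 rows).  One transcription note: the IL-10 qPCR entry is
recorded as −2.10; the alternative reading −210 is inconsistent with
the rest of the panel (every other qPCR value carries two decimals and
comparable magnitude) and with the panel-level regression fit.  Under
the package's pairing convention the panel regression gives slope 1.60,
intercept 0.16, R² 0.78 on 14 points, and exactly one mRNA direction
discordance (TNFα).

## Synthetic data: what it emulates and what it does not

The generator draws baseline + per-experiment intercept + class effect
+ Gaussian noise on the log2 scale.  Defaults are the study conditions
the pipeline targets: 3 experiments × 4 cells (12 samples), baseline
7.0 (typical RMA-scale intensity), experiment SD 0.25, residual SD
0.25, absolute effect sizes ~N(2.0, 0.25²) log2 units with random sign,
class proportions 10% sorted / 5% treatment / 2% interaction.
Interaction genes receive their effect in the (pos, treated) cell only,
producing the treatment-by-subpopulation contrast pattern that
motivates the interaction term.  Enriched gene sets draw 80% of members
(≥ 50% guaranteed) from the target class.

Not emulated: mean–variance trends and heavy-tailed noise of real
arrays, probe-level effects and cross-hybridization, correlated gene
modules, gene–gene correlation within sets beyond class labels, or
qPCR efficiency ≠ 2.  Passing recovery tests therefore shows the chain
is correct *given its model assumptions*; it does not certify behavior
under real-array artifacts.

## Problem sizes and numerics

Tests and the acceptance script use 10³–10⁴ genes, 500 permutations,
10⁴ null gene sets and 10⁵ random F triples — sizes chosen so each
property is measured with comfortable statistical margin while the
whole suite stays interactive.  Degenerate-variance tolerance is 10⁻¹²
on the per-gene variance; mixed-fit convergence follows statsmodels
defaults (lbfgs then powell, 100 iterations).  The 95th percentile is
nearest-rank (index ⌈0.95·B⌉ of the sorted B permutation values):
reproducible, no interpolation ambiguity.  All TSV writers emit a
`# pwfrank <kind> v1` header (GMT excepted, to stay interchangeable
with other GMT readers); quantiles are recomputed on re-read, never
trusted from disk.

## Known limitations

- The mixed engine at 12 samples has little information to estimate
  σ²_exp; roughly half of all fits on weak-block data land on the
  boundary and use the fixed-block refit.  This is by design, not a
  failure mode.
- CERNO's χ² null is anti-conservative for very small rankings
  (N ≲ 50) at k > 1; use exact enumeration there.
- The envelope compares curves rank-wise, not gene-wise; it supports
  statements about the ranking as a whole, not per-gene permutation
  p-values.
- The cross-platform regression is OLS with error in both variables;
  its slope is attenuation-biased when the x platform is noisy, and
  panel regressions on ~14 points are sensitive to single entries.
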