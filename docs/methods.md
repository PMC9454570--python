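# Methods

## Study design and data model

All stages assume a four-condition design — control (C), treated control
(C+P), disease (D), treated disease (D+P) — with n ≥ 3 biological
replicates per condition and expression stored as log2 intensities in a
probes-by-samples matrix. Detection flags (`P`/`A`), when present, mark
whether the array feature-extraction software judged a spot positive and
significant; all filtering logic operates on these flags and on the NAs
they induce. Matrices supplied in linear scale must be declared as such
and are transformed as log2(x + 1) first.

The quantity of scientific interest is the *rescue pattern*: a profile
shifted by the disease but restored to control levels by the treatment,
with the treatment alone leaving controls unaffected. All arithmetic is
additive in log2 space, so "effect" parameters read directly as fold
changes.

## Synthetic-data generator

`simulate` draws per-row baselines from a normal distribution in log2
space (genes: mean 8, SD 1.5; miRNAs: mean 6 — typical array brightness),
adds group shifts and Gaussian residual noise of SD `sigma` (default
0.3 log2 units, i.e. ~23% CV, consistent with replicate scatter on
two-color arrays). Planted structure:

- **Rescue patterns.** A fraction `frac_up_rescued` of rows gets
  mean(D) = mean(C) + `effect` with all other groups at mean(C);
  `frac_down_rescued` mirrors this. Defaults: 5% + 5%, effect 2.0.
- **miRNA→target repression.** For each of `n_true_pairs` couplings a
  target gene (drawn from the unpatterned genes) is re-drawn as
  μ_g − β·(m − μ_m) + ε, where m is the miRNA's realized per-sample
  level. Regressing the target on the miRNA (rather than using a joint
  latent factor) gives a closed-form expected Pearson correlation,
  r = −β·sd(m)/√(β²·var(m) + σ²), used as the oracle in tests. Planted
  miRNAs are taken preferentially from the rescue-patterned ones, whose
  between-group variance makes the anti-correlation strong (r ≈ −0.95
  at β = 1, effect = 2, σ = 0.3) — the situation the filter is meant to
  detect.
- **Detection dropout.** Independent Bernoulli `A` flags per cell at
  rate `dropout_p` (default 5%); the simplest mechanism that exercises
  both NA-filter rules.
- **Decoy predictions.** Each simulated prediction table contains every
  true pair plus `round(decoy_rate · n_true)` decoys drawn uniformly,
  without replacement and independently per source, from the non-planted
  (miRNA, gene) combinations.

Identical seeds give bit-identical outputs; every internal generator is
derived from (`seed`, stream-index) pairs so the mRNA, miRNA, prediction
and Ct streams do not interact.

What the generator does **not** emulate: probe sequences and
hybridization physics, spatial/batch effects, heavy-tailed or
intensity-dependent noise, correlated dropout, miRNAs targeting multiple
genes with saturating combinatorics. Passing tests therefore demonstrate
the correctness and calibration of the *procedures* under the stated
model, not performance on any real dataset.

## Preprocessing

- **Flag masking** sets flagged-absent cells to NA and is an error when
  no flags exist (callers must skip it explicitly).
- **Probe filter**: a probe is dropped iff in at least one condition the
  NA fraction strictly exceeds 50% — "more than" is read literally, so a
  probe at exactly half NA in every group is retained.
- **miRNA filter**: zero undetected values allowed; a single flagged or
  missing sample removes the miRNA. This yields complete rows for the
  loess step.
- **Quantile normalization** is NA-aware: ranks are computed per sample
  on observed values (ties averaged), the reference distribution is the
  mean of the per-sample empirical quantile curves interpolated onto a
  common grid, and each observed value is replaced by the reference at
  its rank position. On complete matrices this is the textbook procedure
  and is exactly idempotent; with NAs idempotence holds only
  approximately because the reference is re-estimated from interpolated
  curves.
- **Cyclic loess** fits, for every unordered sample pair, a lowess curve
  (span 0.7, degree 1 — conventional defaults, configurable) of
  M = x_i − x_j on A = (x_i + x_j)/2 and moves each sample half the
  fitted trend toward the other, preserving the pair average A exactly;
  three sweeps over all pairs by default.
- Pipeline order is flags → NA-filter → normalization; the order is
  recorded in the run manifest since it is a convention, not a law.

## Differential expression

Per-probe two-sample t-tests on log2 values; Welch (unequal variance) by
default because at n = 3 a variance-homogeneity assumption is
uncheckable, with Student's t and Holm's step-down available behind
flags. Probes with fewer than two observed values in either group are
reported *untested* and excluded from the Bonferroni denominator m —
adjusting for untestable hypotheses would inflate the correction
arbitrarily. Adjusted p = min(1, p·m); significance at α = 0.05. The
comparisons feeding the Venn decomposition default to
{D vs C, C+P vs C, D+P vs D, D+P vs C+P} and are configurable. Venn
regions are the exclusive decomposition: region(S) = ∩_{i∈S} sig_i \
∪_{j∉S} sig_j.

A note on power: at n = 3, σ = 0.3 and a 2-log2 effect, the *per-probe*
Bonferroni power at 0.05/2000 is on the order of 1% (the t denominator
with 2–4 degrees of freedom is too unstable for 5-digit p-values). The
pipeline's rescue-pattern inference therefore rests on clustering, which
pools hundreds of profiles, and on the FWER guarantee (no excess false
positives), not on single-probe power.

## SOTA clustering

The Self-Organizing Tree Algorithm grows a binary tree of centroid
cells. The initial system is a root with two leaf cells seeded at the
data mean (this counts as the first growth cycle). Each epoch presents
every profile, in input order, to its nearest leaf; the winner moves
toward the profile by α_w = 0.01, and when the winner's sibling is also
a leaf, the parent and sibling move by α_p = 0.005 and α_s = 0.001 —
the rates mirror the defaults of the classic microarray implementation.
Symmetry between identically-seeded siblings is broken by the first
presentation (the winner moves ten times further than its sister), which
keeps the procedure fully deterministic; a seeded shuffle of the
presentation order is available. An epoch loop ends when the summed
nearest-leaf distance changes by less than ε = 1e-8 (relative) or after
`epochs_per_cycle` epochs. The leaf with the largest *resource* R (mean
member-to-centroid distance) then splits into two children seeded at its
centroid. Growth stops after `max_cycles` cycles, when max R falls at or
below `variability_threshold`, or when the worst leaf has R = 0. Final
assignment is nearest-leaf; reported cluster centroids are member means.

Distances: Pearson dissimilarity 1 − r (the convention for expression
profiles, default), Euclidean, or the average dot product of
z-standardized profiles converted to a dissimilarity by subtracting from
the dataset maximum similarity (the form used for the miRNA heatmaps;
for standardized data it equals Pearson r up to the n/(n−1) factor).
Profiles are mean-centered per row ("expression relative to the gene's
average over all samples") before clustering.

Pattern labels come from the cluster centroid's four group means:
`up_rescued` iff D − C > δ and both |C+P − C| ≤ δ and |D+P − C| ≤ δ;
mirrored for `down_rescued`; `other` otherwise. The label is invariant
to adding a constant to all four means. δ must be chosen relative to the
effect size of interest; when derived from data the package uses half
the median |D − C| difference over the significant genes. Cluster
centroids are diluted toward zero by whatever unpatterned profiles join
the cluster, so δ well below the expected effect (e.g. effect/4 rather
than effect/2) is the safer choice when clusters are coarse.

Sample dendrograms use complete-linkage agglomeration (scipy) on either
Pearson or average-dot-product dissimilarities, with Newick export;
constant samples are rejected by name since their correlation is
undefined.

## miRNA–target filtering

Prediction tables are unioned; `min_support` (default 1) optionally
requires multi-algorithm consensus — the union default reflects that an
intersection rule across heterogeneous predictors is not obviously
better and is left to the caller. The expression filter computes Pearson
r across all shared samples jointly (a condition-stratified mode is
possible but the default treats the 12-sample series as one), a
one-sided p for r < 0 from the t transform with n − 2 degrees of
freedom, and BH q over all pairs with computable statistics (constant or
too-sparse vectors get NA and leave the family). Retention is strict:
r < −0.5 **and** q < 0.05; a pair at exactly −0.5 is dropped. Under a
full null the expected false-retained fraction equals the BH level
(measured ≈ 2–3% because the r < −0.5 condition binds as well).

The bundled seed-match scanner reports canonical 6mer / 7mer-A1 /
7mer-m8 / 8mer sites (reverse complement of miRNA positions 2–8, with
the A opposite position 1 where applicable), each match at its strongest
type with 0-based half-open coordinates. It exists to generate
prediction tables when none are supplied and makes no claim to replicate
any published predictor's scoring.

## Network assembly

Nodes are retained miRNAs, their targets, and PPI partners within one
hop of a target (hop count configurable); edges are typed
`mirna_target` or `ppi`; PPI input is a tab file with official-symbol
columns, deduplicated as unordered pairs with self-interactions dropped.
Node attributes log2ratio_D_vs_DP and log2ratio_D_vs_C are stored as
differences of group means (additive, symmetric, NA-safe); for a
rescue-patterned profile the two ratios coincide in expectation, which
is the visual signature of rescue in the network rendering. Exports:
GraphML (round-trips byte-identically through the package's reader) and
SIF.

## Enrichment

ORA uses the exact hypergeometric upper tail on a caller-supplied
universe (default in the pipeline: all probes surviving filters, not the
genome — enrichment against an unmeasurable background is
uninterpretable), with the EASE variant (overlap − 1) behind a flag and
BH q over the collection. The GSEA enrichment score is the weighted KS
running sum (hits advance by |score|^w normalized to the in-set total,
misses retreat by 1/(N − N_h); ES is the maximum signed deviation); the
null is size-matched *gene-set* permutation with a seeded generator —
phenotype permutation is degenerate at n = 3 per arm. miRNA family and
cluster enrichment applies the same hypergeometric machinery per
annotation category with BH FDR across all tested terms.

## qPCR

Technical replicates are averaged per (sample, gene) first. ΔΔCt:
ΔCt = Ct_target − Ct_reference per sample; ΔΔCt = group mean minus
calibrator-group mean; RQ = 2^(−ΔΔCt) (calibrator RQ ≡ 1; any
per-sample additive shift applied to both genes cancels). ΔCt reports
2^(−ΔCt) per sample without a calibrator; group means of ΔCt values
equal the ΔΔCt RQs up to the calibrator factor. Reference candidates are
ranked by ascending SD of Ct across all samples (ties alphabetical) —
the simplest defensible reading of "most stable"; a geNorm-style
pairwise-variation scheme is out of scope. Candidates missing in more
than 20% of samples are excluded. Platform validation is the Pearson
correlation of paired values, by default the four group means;
categories: strong r ≥ 0.7 (boundary inclusive), moderate 0.5 < r < 0.7
(open at both ends, so r = 0.5 exactly is weak), weak otherwise.

## Calibration scenarios and problem sizes

`mirrescue.calibration` measures the pipeline's operating
characteristics by repeated seeded simulation; the test suite and
`scripts/acceptance.py` run these at the following sizes, chosen so the
full suite completes in about a minute on one CPU while keeping the
Monte-Carlo standard errors a factor of several below the margins being
tested:

- FWER of the Bonferroni multiple t-test: 200 global-null datasets of
  2000 probes (effect 0, σ 0.3, complete matrices). Pass bound:
  0.05 + 2·√(0.05·0.95/200) ≈ 0.081.
- Anti-correlation filter null FDR: 100 datasets, β = 0 **and**
  effect = 0, 500 candidate pairs each (250 planted-but-uncoupled plus
  250 decoys). With β = 0 every retained pair is a false discovery, so
  the per-dataset false-retained fraction is 1 when anything is retained
  and 0 otherwise; the mean must stay within 5% plus two SEs. The fully
  flat design is deliberate: with planted rescue patterns but no
  coupling, pattern-driven anti-correlations between opposite-direction
  profiles are *real* correlations, and counting them as filter failures
  would measure the simulation's confounding rather than the filter's
  calibration.
- Planted-pair recovery: 100 datasets, β = 1, σ = 0.3, 12 samples,
  decoys at rate 1.0; sensitivity ≥ 0.9 and empirical FDR ≤ 0.05.
- SOTA vs exhaustive optimum: 100 instances of 10 six-dimensional
  profiles in two groups separated by 4σ per coordinate; a one-split
  SOTA run must match the brute-force minimum within-cluster-distance
  2-partition in ≥ 95% of instances.
- Rescue-pattern recovery: 300 genes, effect 2, σ 0.3, 10% up + 10%
  down planted; ≥ 90% of planted genes must land in matching-labeled
  clusters at δ = effect/2.

## Numerical choices and degenerate inputs

- Zero-variance t-tests: equal means give t = 0, p = 1; unequal means
  with zero pooled SE give |t| = ∞, p = 0.
- |r| = 1 correlations bypass the t transform (p = 0 or 1).
- SOTA distance to a constant centroid under correlation metrics is
  defined as 1 (r treated as 0).
- Ranking ties share average ranks; stability-ranking ties break
  alphabetically; SOTA winner ties break toward the lowest leaf index.
- All text outputs are written with 6 significant digits so manifest
  hashes are platform-stable.

## Known limitations

- "Adjusted Bonferroni" is implemented as plain Bonferroni over tested
  probes (Holm behind a flag); the historical tool's exact variant is
  not documented.
- The SOTA stopping rule that produced any particular published cluster
  numbering is not reproducible; cluster IDs here are tree-growth
  indices, not biological anchors.
- The FDR scope of the anti-correlation filter is the set of pairs
  surviving prediction consensus in the current run; filtering the same
  pairs in separate runs changes the BH family.
- NA-aware quantile normalization is only approximately idempotent (see
  above); complete matrices are exact.
- Enrichment results depend entirely on the user-supplied gene sets and
  annotation tables; the package ships none.
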