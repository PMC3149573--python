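# Methods

This note documents the statistical models implemented in `qttnet`, the
defaults and why they were chosen, what the synthetic cohort generator does
and does not emulate, and the numerical conventions that affect results.

## Study design assumed

The package targets a small multi-breed cohort profiled in several tissues:
by default 16 animals (4 breeds × ~2 sexes, one line imbalanced at 3M/1F),
five tissues, log2-scale array intensities, and 12 plasma metabolites per
animal. All analyses condition on sex and breed; nothing assumes balance or
large n, but residual degrees of freedom are checked everywhere (at the
default design the covariate model has rank p = 5: intercept, 1 sex and 3
breed indicators).

## Metabolite models

Each metabolite is modelled as `y = μ + sex + breed + e` by ordinary least
squares. Factor p-values are partial (Type II) F-tests — the F-test for
dropping all of a factor's indicator columns from the two-factor model.
Type II was chosen because it is invariant to factor order, which matters
under the mild sex×breed imbalance; sequential (Type I) tests would give
order-dependent answers. A zero-variance trait has no testable effects and
reports p = 1 for both factors. Trait–trait Pearson correlations use
pairwise-complete observations (≥ 3 pairs enforced); constant traits are
flagged and reported as r = 0.

Breed dendrograms cluster standardized per-breed mean profiles with average
linkage on the distance `1 − r`: identical profiles merge at 0, uncorrelated
at 1, exactly opposite at 2. Average linkage (UPGMA) keeps merge heights
interpretable on that scale. Expression-space profiles are per-breed means
of per-probeset z-scores — a deliberately plain standardization.

## QTT calling

For probeset *i* and trait *t*:
`y_t = μ + sex + breed + β_i x_i + e`; *i* is a QTT when the two-sided
t-test of `β_i` gives p < α (default α = 0.01). The implementation runs the
algebraically identical partial-correlation route — correlate the
sex/breed-residualized trait with the residualized expression and use
`t = r√df/√(1−r²)`, `df = n − p − 1` — which vectorizes over all probesets;
the explicit regression route is kept as a cross-check in the tests and the
two agree to < 1e-8 in p. Probesets with zero residual variance are
excluded (p set to 1) rather than imputed. Samples missing a trait value
are dropped for that trait only.

**Permutation FDR.** Whole phenotype rows (trait together with sex and
breed) are randomly re-assigned to samples; the expression matrix is left
untouched, so the transcriptome correlation structure is preserved exactly,
and because the covariates travel with the trait the trait–covariate
structure survives under the null as well (permuting the trait alone would
break the adjusted model's null). `FDR = mean permuted QTT count /
observed count` over 20 permutations by default; the mean (not median) is
the conventional plug-in estimator and is stable at 20 iterations. A zero
observed count leaves the FDR undefined (reported as missing, not 0/0).

## Cross-tissue overlap

For one trait and two tissues with QTT sets A and B over a shared universe
of N probesets: expected overlap `|A||B|/N`, fold = observed/expected, and
p from the hypergeometric upper tail, identical to a one-sided Fisher's
exact test (enrichment only — the question is whether sharing *exceeds*
chance). The scan over all (trait, tissue-pair) combinations applies
Bonferroni with family size `n_traits × C(n_tissues, 2)` (120 at 12 traits
and 5 tissues). The universe is the full array (all probesets), not the
per-tissue tested counts; with the published per-tissue QTT counts and
N = 24,123 this choice reproduces every published fold value at one
decimal, which is why it is the default.

## GSEA

Probesets are collapsed to genes by per-sample averaging (a gene with
several probesets gets their mean), then genes are ranked by partial
correlation with the trait conditional on sex and breed — the same
residualization as QTT calling, so the ranking metric equals the QTT
`r_partial` at gene level. The enrichment score is the weighted
Kolmogorov–Smirnov running sum: members add `|metric|^w / Σ|metric|^w`
(default weight w = 1), non-members subtract `1/(N − N_hit)`; ES is the
signed maximum deviation. Ties in the ranking are broken by gene
identifier, trading a little speed for exact reproducibility.

Null scores come from phenotype-row permutations with full re-ranking each
time (gene-label permutation would ignore the covariates). NES divides ES
by the mean |null ES| of the same sign; nominal p is the same-sign null
tail fraction (with the +1 continuity correction); the FDR q-value is the
standard positive/negative-tail ratio of null-to-observed tail fractions,
capped at 1. Defaults: 1000 permutations for production runs; the tests use
100–200, which is where the planted-signal and calibration checks are run.

A plain hypergeometric over-representation test with Benjamini–Hochberg
correction is provided for annotating discrete gene lists (e.g. module
members against category collections).

## Single-tissue networks

Networks are built on sex/breed residuals. Unsigned adjacency
`a_ij = |r_ij|^β` (signed variants are out of scope; the unsigned form is
what the connectivity statistics below assume). β is chosen per network as
the smallest candidate in 1..20 whose connectivity distribution fits the
scale-free criterion with R² ≥ 0.8, falling back to the argmax R². The fit
regresses `log10 p(K)` on `log10 K` over 10 equal-width bins of K and
reports R² = 0 when the slope is positive or the distribution is
degenerate — a scale-free law requires a decreasing p(K). (Equal-width,
not equal-count, bins: equal-count bins have constant frequency by
construction and would make the regression vacuous.) With only 16 arrays
the chosen β is noisy across simulations; the criterion itself (smallest β
reaching the cut) is what the package guarantees.

Topological overlap dissimilarity:
`d_ij = 1 − (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(K_i, K_j) + 1 − a_ij)`,
`d_ii = 0`; entries provably lie in [0, 1] for adjacencies in [0, 1].

Modules come from average-linkage clustering of `d` followed by an adaptive
("dynamic tree") cut: starting from a cut at 99% of the tallest merge,
branches are recursively split while both sub-branches hold at least
`min_module_size` nodes (default 30); everything failing the size floor is
left unassigned (label 0), and modules are relabelled 1..M by decreasing
size. This is the deterministic tree variant; the PAM-like reassignment
stage of hybrid dynamic cutting is intentionally omitted (known
limitation: borderline nodes near module boundaries stay unassigned rather
than being rescued).

Connectivity: `K_i = Σ_{j≠i} a_ij` (so K ≤ N − 1), and intramodular
`K_intra,i` sums only over same-module partners; label-0 nodes get
K_intra = 0.

## Multi-tissue network

For one trait, the per-tissue QTT columns of the residual matrices are
pooled as (tissue, probeset) nodes — the same probeset called in two
tissues is two distinct nodes. β is re-chosen on the pooled matrix rather
than reused from single-tissue fits. On the pooled adjacency:

* standardized inter-tissue connectivity of node *i* is its **mean**
  adjacency to the N_ot nodes of other tissues — dimensionless, in [0, 1],
  and comparable across tissues with very different QTT counts; averaged
  within a tissue pair it reduces to the pair-strength formula below;
* tissue-pair connection strength `C(t1,t2) = (1/N_1N_2) ΣΣ a_ij` over
  cross-tissue pairs;
* module–tissue enrichment is the hypergeometric upper tail of each
  tissue's share in each module, BH-corrected over (module × tissue) tests;
* hubs are the top `ceil(0.10 · N_m)` nodes per module by intramodular
  connectivity, ties broken by node identifier;
* hub–hub edges use the Pearson correlation of residual profiles with a
  two-sided t-test at `df = (n − p) − 2`, where p design columns were
  removed by residualization — ignoring the consumed degrees of freedom
  would inflate significance badly at n = 16. Edges need nominal p < 1e-4
  and BH q < 0.05 over the tested hub pairs (the FDR family is the hub
  pairs, i.e. what is reported; a flag on `significant_edges` allows using
  all pairs instead).

## Synthetic cohort generator

Latent-factor construction throughout: a module of size s shares a factor
f, and each member is `√ρ·f + √(1−ρ)·ε` (unit variance), so the expected
pairwise within-module correlation equals ρ exactly and generation is
O(N). Trait association is planted the same way — trait and its associated
probesets share a factor with loadings chosen so the *partial* correlation
(given sex and breed) equals the requested value in expectation. Breed and
sex effects are added to every trait and transcript *before* association is
read off, so the covariate-adjusted analysis is the correct analysis.
Planted QTT positions are shared across tissues (same array), giving the
cross-tissue overlap and multi-tissue stages real structure to find.
Defaults: 16 samples as above, 5 tissues, 2000 probesets, 12 traits with a
NEFA-like trait carrying 50 associated probesets per tissue at partial
correlation 0.85, three 50-probeset modules per tissue at ρ = 0.7,
baselines Uniform(2, 12), noise SD 0.5, breed/sex effect SDs 0.3/0.2 —
values a practitioner would call realistic for log2 array data on a small
cohort, chosen once.

What the generator does **not** emulate: probe-level array noise,
batch/hybridization effects, heavy-tailed intensity distributions,
missingness mechanisms, or correlated traits. Tests passing on these
cohorts therefore demonstrate correctness and calibration of the methods,
not robustness to real-array artefacts.

## Numerical conventions and reproducibility

* Residualization is the orthogonal projection `I − H` computed via QR;
  rank-deficient designs are rejected with the confounded factor named.
* One global seed; every randomized operation derives its own stream from
  (seed, operation label) so stage order cannot change results. Reruns with
  the same config and seed are byte-identical, which the test suite checks
  file-by-file.
* Degenerate inputs: constant probesets/genes/traits are excluded or scored
  0 and counted in log records, never silently imputed; 0/0 ratios (FDR
  with no observed calls, fold with zero expectation) are reported as
  undefined rather than 0.
* Problem sizes in the test and acceptance runs (hundreds to 2000
  probesets, 20–200 permutations, 20 simulation seeds) are scaled to keep
  the full suite fast while leaving every statistical check comfortably
  powered; production defaults (1000 GSEA permutations, β scan to 20) are
  unchanged.

## Known limitations

* Tree-variant dynamic cut only (no hybrid PAM stage).
* Unsigned networks only; no module eigengenes or preservation statistics.
* No mixed models or kinship correction; breed is a fixed factor.
* The Bonferroni family for the overlap scan is configurable but defaults
  to traits × tissue-pairs; other choices change only the corrected p.
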