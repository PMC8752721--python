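# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions a maintainer needs.

## Differential expression (P_D)

**Counts (NB Wald).** Library sizes are normalized by median-of-ratios
size factors: factor_j = median over reference genes of x_gj / geometric
mean, where the reference set is the genes with positive counts in every
sample (an error, with a remediation hint, if that set is empty). Group
means are estimated on normalized counts. The gene-wise NB dispersion α is
a method-of-moments estimate from the pooled within-group variance,
Var(q) ≈ μ·mean(1/s) + α·μ², clamped to [1e-8, 10] and shrunk halfway (on
the log scale) toward the across-gene mean — a deliberately simple stand-in
for trend-based shrinkage that stabilizes small-m estimates without extra
machinery. The Wald statistic is log2FC / SE with a delta-method SE and a
standard-normal reference; log2FC uses a 0.5 pseudo-count on normalized
means, so copied groups give exactly zero. Under permuted-label null
simulations the test's type-I error at 0.05 is within ±0.02 (verified in
the suite). No independent filtering or outlier handling is done; with
one-directional differential expression in a large fraction of genes the
median-of-ratios normalization is predictably biased — that is a property
of the estimator, not of this implementation.

**Continuous (moderated t).** Per-gene two-group linear fit; residual
variances s²_g are shrunk toward a scaled-inverse-chi-square prior
(d₀, s₀²) fitted by moment matching on log s² (digamma/trigamma inversion).
The moderated t uses posterior variance (d₀s₀² + d·s²)/(d₀+d) with d₀+d
degrees of freedom. `prior_df=0` recovers the ordinary t exactly (tested);
the data-driven prior never loses power against it in planted-shift
simulations. Continuous data are assumed log-scale; a `log2(x+1)` transform
is available for counts entering the network stage.

**Multi-group / time series (LRT).** Nested designs are dummy-coded from
annotation columns; nesting is verified by rank comparison. Gaussian data
use the profile-likelihood statistic n·log(RSS_reduced/RSS_full); counts
use an NB GLM (statsmodels) with a per-gene method-of-moments dispersion
from a Poisson pre-fit and log-size-factor offsets. The statistic is
referred to χ² with df = rank difference. The reported effect size is the
range of fitted values (a maximal contrast), since a single fold change is
undefined for ≥3 groups.

All p-values are clamped to ≥ 1e-300 so −log is finite downstream, and
adjusted by Benjamini–Hochberg. The FET foreground set defaults to
adjusted p < 0.05 (`de_fdr`); the threshold is a configuration choice, not
a modeling claim.

## Network inference

**COEN.** Unsigned adjacency a_ij = |Pearson r|^β (signed networks offer
no benefit for the planted-copy structure the generator produces and the
unsigned form is the common default). β is the smallest integer in 1..20
whose connectivity distribution fits a power law with R² ≥ 0.85 — computed
from 10 linear connectivity bins of log10 p(k) vs log10 k, plain R² without
the sign convention — falling back to the argmax-R² power with a warning
when no power reaches the target (typical for small simulated panels).
Constant genes are dropped before correlation, using a relative tolerance
(a numerically constant row has std ~ eps·|mean|, not exactly 0). The
topological overlap measure is

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    l_ij = Σ_u a_iu·a_uj,  k_i = Σ_u a_iu,  TOM_ii = 1,

verified against a triple-loop oracle to 1e-12. TOM is symmetric; direction
is imposed by restricting edge sources to the regulator rows. At scale, only
the regulator rows of the TOM are computed (the values are identical; memory
stays linear in the regulator count), in float32 for the G×G correlation.

**GRN.** Each gene is regressed on the (standardized) regulators —
excluding itself when it is one — with a random forest (default 1000
trees, min leaf 1, mtry = ⌈√p⌉; the ceiling keeps tiny regulator panels
from forcing splits on uninformative features). W_ij is regulator i's
impurity importance rescaled so the column sums to the model's explained
variance (out-of-bag R², floored at 0). Targets with out-of-bag R² ≤ 0
(threshold configurable) are removed as poor models: their expression is
essentially unpredictable from the regulators. Each target draws its own
child seed from one seed sequence, so results are bit-identical for any
worker count.

**Topology.** All unmasked regulator→gene weights are ranked; exactly
⌈fraction × candidates⌉ edges are kept (default fraction 0.05; the
denominator is the number of unmasked regulator→gene pairs, not G²). Ties
at the cutoff break by weight desc, then regulator ID, then target ID.
Nodes without a retained edge are dropped. Out-degree counts distinct
successors; out-closeness is closeness centrality on the reversed digraph
with the Wasserman–Faust reachable-set correction (nodes with no outgoing
edges score 0) — a convention choice, since closeness is undefined on
disconnected digraphs.

## Enrichment (P_E)

**FET.** For a regulon of size s with overlap K against M differential
genes in the N-gene network universe, p = P(X ≥ K) for
X ~ Hypergeom(N, M, s), computed with `scipy.stats.hypergeom.sf` and
verified against exact rational enumeration over the full (N ≤ 30, M, s, K)
grid to 1e-12. The universe defaults to all network nodes (overridable);
differential genes outside it are excluded. Regulons with < 3 genes in the
universe (configurable) are reported NA rather than yielding unstable tails.

**GSEA.** The ranking metric r is the z-scored −ln p (any log base gives
the same z; ties break by gene ID; an all-equal vector degenerates to zeros
with a warning). The running difference ΔP rises by normalized |r| at hits
and falls by 1/(N−N_H) at misses; since its extrema occur immediately
after or immediately before a hit (and ΔP_N = 0), ES is computed from hit
positions alone in O(N_H) — verified against a full prefix recomputation
to 1e-12. The null shuffles the gene labels of r: one shared stream of
permutations (default 1000) serves all regulators, which is cheaper and
makes p-values comparable across regulators. The empirical p is one-sided
on the observed sign with a +1 pseudo-count in both numerator and
denominator, where the denominator counts only same-sign null scores — so
the floor is 1/(1 + same-sign count), and 1/(n_perm+1) only in the
degenerate all-same-sign case. Under randomly drawn target sets the mean
empirical p is 0.5 ± 0.05 (verified). Note that gene-permutation nulls are
anti-conservative for strongly co-expressed regulons (the permutation
destroys the clustering of correlated genes in the ranked list); the final
ranking combines P_E with P_D, which restores discrimination in practice.

## Ranking

score = f(−ln P_E) + f(−ln P_D) with the min-max map f; a constant channel
maps to all zeros so an uninformative channel contributes nothing. NA
inputs (regulator absent from DE, NA enrichment) count as p = 1. Ties break
by smaller p_e, then smaller p_d, then ID; ranks are dense from 1. The
score is invariant to the log base and to any positive affine rescaling of
−log p (both tested), and symmetric in its two channels.

## Synthetic generator

The generator emulates a two-state experiment: m regulators with baselines
drawn once from N(10, 2) (positive, heterogeneous levels), within-group sd
`reg_sd` = 1; k bona fide regulators get a group-B mean shift
`effect_size` = 2 (two baseline sd — a clearly detectable but not trivial
effect); each regulator drives t ~ U{targets_min..targets_max} targets
(defaults 3..50), each target being the regulator's expression plus
N(0, `target_noise_sd` = 1) noise, which fixes the regulator–target
correlation at σ_reg/√(σ_reg² + σ_noise²). Total genes = m + Σt exactly.
Group labels are A/B with the first ⌈N/2⌉ samples in A. A `counts=True`
option exponentiates (base 2, capped) and Poisson-samples to exercise the
count path. Down-sampling draws n/2 per group without replacement (n must
be even). Knockdown multiplies one regulator by `knock_fraction` in the
silenced group and shifts each of its targets by the same reduction —
reusing the original noise draw makes the propagation exact and the
fixture deterministic.

What the generator does **not** emulate: mutual-information-style
nonlinear dependencies, library-size and batch artifacts beyond the
Poisson option, overlapping regulons (each target belongs to exactly one
regulator), and regulator–regulator cross-talk. Passing the planted
benchmarks therefore demonstrates correctness of the machinery and
sensible behavior under the stated noise model, not performance on real
transcriptomes.

## Benchmark problem sizes

The suite's end-to-end benchmarks run at reduced scale chosen to keep the
whole suite fast while preserving the qualitative regime: the down-sampling
benchmark uses 100 regulators (10 planted, t ∈ [3, 20]) across sample sizes
100/50/20/10/6 with 5 seeds; the knockdown benchmark uses 120 regulators
(t ∈ [3, 20]), 20+20 samples, 12 seeds. The reference-scale generator run
(500 regulators, t ∈ [3, 50], 100 samples) is exercised by the gene-count
check and `scripts/acceptance.py`.

## Known limitations

- The DE stage implements simplified equivalents of the standard NB-Wald
  and moderated-t procedures (no dispersion trend fitting, no independent
  filtering, no outlier refitting); gene rankings agree well with the
  planted truth but p-values are not interchangeable with those of the
  reference implementations.
- Gene-permutation GSEA is anti-conservative under co-expression (above).
- The bundled regulator list is a convenience stand-in of well-known human
  TF symbols, not a curated census; real analyses should supply their own.
- COEN memory is quadratic in gene count (float32 correlation matrix);
  ~20k genes need a few GiB.
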