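# Methods

`coexorder` implements weighted gene co-expression network analysis (WGCNA)
together with moderated-t differential expression, and uses both to compare
two orderings of the same workflow: filtering the expression matrix by
differentially expressed genes (DEGs) *before* building the network, versus
building the network on the full matrix and filtering by DEGs *afterwards*.
This note records the models, the defaults and why they were chosen, what
the synthetic data do and do not emulate, and the numerical decisions a
maintainer would want to know about.

## The network model

All networks are **unsigned**: the co-expression similarity between genes
*m* and *n* is |cor<sub>mn</sub>| (Pearson, across samples), and the
adjacency is

  a<sub>mn</sub> = |cor<sub>mn</sub>|<sup>β</sup>

for an integer soft-threshold power β. The unsigned choice deliberately
connects both positively and negatively correlated genes: in processes such
as gonadal sex differentiation, active down-regulation in one group is as
informative as up-regulation, so inhibition and activation edges are not
distinguished. Signed networks are out of scope.

**Connectivity** is k<sub>i</sub> = Σ<sub>j≠i</sub> a<sub>ij</sub>; the
adjacency diagonal is stored as 1 for convenience but never counted.

**Scale-free fit.** Connectivities (k > 0) are split into `n_bins` (default
10) equal-width bins; for each non-empty bin the mean k and the fraction of
genes p(k) are computed, and log₁₀ p(k) is regressed on log₁₀ k by ordinary
least squares. The reported index is the signed fit
−sign(slope)·R²: positive only when frequency decays with connectivity.
β is chosen as the smallest power whose signed R² reaches 0.8; failing
that, the power maximizing signed R², with ties broken toward the smaller
power (which preserves higher mean connectivity). The slope is reported so
a user can check it lies near −1, the canonical scale-free regime.
Equal-width binning is the transparent choice; with a discrete,
hub-dominated degree distribution (e.g. a preferential-attachment graph)
the sparse tail bins bias the fitted slope steeper than the underlying
exponent — the diagnostic is for *relative* comparison of candidate powers
and matrices, not unbiased exponent estimation.

**Topological overlap.** The unsigned TOM is used for clustering:

  TOM<sub>ij</sub> = (ℓ<sub>ij</sub> + a<sub>ij</sub>) /
  (min(k<sub>i</sub>, k<sub>j</sub>) + 1 − a<sub>ij</sub>),
  ℓ<sub>ij</sub> = Σ<sub>u≠i,j</sub> a<sub>iu</sub> a<sub>uj</sub>

computed by a single matrix product with the diagonal zeroed, then
symmetrized against floating-point noise and clipped to [0, 1].

## Module detection

Genes are clustered by average-linkage (UPGMA) hierarchical clustering of
the dissimilarity 1 − TOM. Module extraction then has three stages:

1. **Core cut.** Every distinct merge height is a candidate cut, excluding
   the top 0.5% of the height range: in that terminal agglomeration band
   unrelated genes chain together into spuriously large clusters under
   average linkage, and a count-maximizing cut taken there returns noise
   fragments rather than modules. Among the remaining candidates, the cut
   producing the most clusters of at least `min_module_size` (default 30)
   genes wins, ties going to the lower (purer) height. Undersized branches
   are unassigned ("grey").
2. **Membership refinement.** The core cut is deliberately conservative —
   complete modules and low contamination cannot be had at a single tree
   height. Each iteration recomputes module eigengenes, reassigns every
   gene to the module whose eigengene it best correlates with (|kME|),
   greys genes whose best |kME| is below 0.7, and dissolves modules that
   fall under the minimum size; it converges in a few iterations. The 0.7
   floor means a module member shares at least half its variance with the
   module summary profile. This step is what makes recovery robust: at 20
   samples the sampling spread of a null correlation is ≈ 0.23, so weakly
   attached background genes are otherwise indistinguishable from module
   periphery on the tree alone.
3. **Eigengene merge.** Modules whose eigengenes are closer than 0.25 in
   the *signed* dissimilarity 1 − cor(ME<sub>a</sub>, ME<sub>b</sub>) are
   merged (i.e. eigengene correlation above 0.75), eigengenes recomputed,
   until stable. Only positively correlated modules can merge.

**Eigengenes** are the first principal component of the module's
standardized genes × samples block (via SVD), sign-aligned so the eigengene
correlates non-negatively with the module mean profile (falling back to
the first gene when the mean is degenerate, e.g. a gene and its negation),
and scaled to unit variance. Variance explained is reported.

Modules are named with the conventional 40-color vocabulary in decreasing
size order (turquoise, blue, brown, ...); beyond 40 modules, labels
"M41..." are used; "grey" always means unassigned.

## Differential expression

Per gene, a two-group contrast gives the difference of group means and the
pooled within-group variance s²<sub>g</sub> with d = n − 2 degrees of
freedom. Variances are shrunk toward a prior estimated by moment matching
on log s² across genes (the standard moderated-t construction; the
hyperparameters (d₀, s₀²) solve the trigamma moment equations, with d₀ = ∞
when the observed spread of log s² is no larger than expected from χ²
noise):

  s̃²<sub>g</sub> = (d₀ s₀² + d s²<sub>g</sub>) / (d₀ + d),
  t̃<sub>g</sub> = diff<sub>g</sub> / (s̃<sub>g</sub> √(1/n₁ + 1/n₂)),
  t̃<sub>g</sub> ~ t(d₀ + d).

`prior_df=0` disables shrinkage (exactly the ordinary pooled t — the oracle
route in the tests); `prior_df=inf` shrinks fully. The implementation
agrees with the reference R implementation (limma) to ~1e−14 on shared
inputs, which the test suite verifies through `Rscript`.

Benjamini–Hochberg adjustment is implemented directly as the step-up
definition (stable ranks for ties, capped at 1) because it is itself a
tested contract here; it is cross-checked against both a brute-force
enumeration and `statsmodels`. DEGs are genes with adjusted p strictly
below α (default 0.05); raw-p calling is available but not the default.

The DEG contrast used by the pipeline defaults to the trait contrast over
**all** samples. In the synthetic design the trait acts identically at both
stages, and at 5 samples per design cell a single-stage 5v5 contrast is
powerless by construction: the within-group SD of a module gene includes
the shared factor noise, so the standardized effect is bounded by the
trait effect δ, and with δ = 2 the smallest attainable p (~0.013) can
never survive FDR control across 2,000 genes. Stage-restricted contrasts
(`deg_stage="stage1"`) remain available and drive the early-biomarker
analysis.

## Trait association and gene filters

Module–trait association is the Pearson correlation between the module
eigengene and the 0/1 trait (0 = female, 1 = male by convention), with the
two-sided p from t = r√((n−2)/(1−r²)). Selection requires |r| > `r_min`
(default 0.5) and p < `p_max`. `p_max` defaults to 0.001; for small
designs (n ≲ 20) the appropriate value is 0.01 — at n = 20 a module whose
factor separates the groups by two factor-SDs has population r ≈ 0.707 and
*expected* p ≈ 5e−4, so the 0.001 cut rejects a genuine trait module in a
large fraction of datasets on sampling noise alone. `small_sample_config()`
packages these small-n settings.

Gene-level scores: GS (gene significance) is primarily the gene–trait
correlation, with the −log₁₀ p variant (GS_logp) computed alongside and
selectable (`gs_definition="logp"`); kME is the gene–eigengene correlation
(computed against every module); kIM is the intramodular adjacency sum,
reported raw and max-normalized. The module screen retains a candidate
module only when gene-wise |kME| and |GS| correlate positively
(r ≥ `mmgs_r_min`, p < `mmgs_p_max`) — a module whose hubs are not its most
trait-associated genes is suspect. The default `mmgs_r_min` is 0.5; the
small-sample configuration uses 0.3 because GS estimation noise at n = 20
(se ≈ 0.12) caps the attainable correlation of even a perfectly coherent
module near 0.4–0.7. The final gene filter keeps genes of retained modules
with |GS| > 0.2 and |kME| > 0.8, strict inequalities; the
membership measure can be switched to normalized kIM
(`membership="kim_norm"`).

## The four methods

1. **DEGs only** — the DEG list at the configured contrast.
2. **Network only** — full-matrix WGCNA, module selection, screen, gene
   filters; no DEG information.
3. **Filter-then-network** — the DEG list defines the matrix handed to
   WGCNA; the power β is re-selected on that submatrix; then the same
   module/gene filters.
4. **Network-then-filter** — the method-2 pipeline, then intersection of
   its gene list with the same DEG list.

Method 4's list is a subset of method 2's by construction; method 3's list
is a subset of its DEG list. Methods share no hidden randomness — identical
inputs and configuration give byte-identical outputs, which the CLI tests
assert literally. For topology reporting, each network method's "top
module" (largest |r| to the trait among selected modules) is thresholded at
edge weight > 0.2 (strict) and summarized with node/edge counts, mean/max
degree, characteristic path length over connected pairs (disconnected
pairs ignored, keeping the statistic finite), degree heterogeneity
(population coefficient of variation), and maximum normalized betweenness —
the summary a network-viewer tool would report on the exported edges.
Method 3 variants with the other pre-filters in common use (top-variance
or top-expressed fraction) are available via `prefilter=`.

## The synthetic data

Each module m has a latent per-sample factor
u<sub>m</sub>(s) ~ N(δ<sub>m</sub>·sex + γ<sub>m</sub>·stage, 1); gene i of
the module is λ<sub>i</sub>·u<sub>m</sub>(s) + ε, ε ~ N(0, σ²), and
background genes are pure noise. The single-factor form was chosen over
explicit correlation-matrix sampling because high-λ genes are hubs
automatically and every expectation needed by the tests has a closed form
(within-module correlation λ<sub>i</sub>λ<sub>j</sub>σ²<sub>u</sub>/…,
gene-level DE effect λ<sub>i</sub>δ<sub>m</sub>).

The documented fixture (`default_paper_like_spec`): 2,000 genes; four
planted modules of 150/120/100/80 genes — one strong trait module (δ = 2)
with 20% connectors, one moderate (δ = 1), two trait-null; 1,550
background genes; 5 samples per (sex × stage) cell, n = 20 (above the
~15-sample minimum recommended for network construction); σ = 1. Loadings
are Uniform(1.2, 3.0): the 2.5-fold spread produces hub heterogeneity and
gives the membership/significance screen real ranking signal, while
keeping within-module correlations (~0.6–0.95) high enough for recovery at
n = 20. **Connectors** are the lowest-loading module genes, their loading
rescaled so the per-gene standardized trait effect is 0.5σ — co-expressed
with the module, individually underpowered for DE at this n. Calibrating
to a fixed standardized effect (rather than a target p-value) keeps the
generator independent of the test implementation. Key genes are the ten
highest-loading non-connector genes of the strongest trait module.

Randomness is hierarchical: one root seed spawns one substream per module
plus one each for the design and the background, so a module's data depend
only on the root seed and the module's position in the spec. Identical
spec + seed ⇒ bit-identical output.

What the generator does **not** emulate: probe-level microarray effects,
RNA-seq count noise (negative binomial), batch structure, multi-factor
module membership, or stage × trait interactions. Passing tests therefore
demonstrate correctness of the machinery and the direction of the
ordering contrast under a clean factor model — not performance on real
transcriptomes, where weaker, overlapping modules will lower every
recovery number.

A note on connectors and sample size: a connector's population correlation
with its module factor is ≈ 0.33, while the sampling spread of a null
correlation at n = 20 is ≈ 0.23. No assignment rule can both keep 1,550
background genes out of the modules (needed for accurate recovery) and
capture most connectors — the distributions overlap too much. The package
therefore measures what pre-filtering actually destroys at the network
level: connectors are present in the full-matrix network of methods 2/4
(their kME/kIM are computed and reported) and absent from method 3's
DEG-filtered network, because they are essentially never DEGs.

## Numerical choices and degenerate inputs

- Zero-variance genes are dropped (with a warning) before correlation.
- Correlations are clipped to [−1, 1]; TOM symmetrized and clipped to
  [0, 1]; an empty network has TOM ≡ 0 off-diagonal.
- A constant connectivity vector (regular network) is a degenerate single
  bin and raises; fewer than 3 usable bins raises.
- Genes with s² = 0 get finite moderated t through shrinkage; if *all*
  variances are zero the prior is unidentifiable and fitting raises.
- The scale-free scan computes the correlation matrix once and powers it
  per β (O(G²) memory, no recomputation).
- Sample-outlier detection (average-linkage Euclidean tree over samples)
  flags branches that separate above a *user-supplied* cutoff and contain
  fewer than half the samples; the cutoff is never defaulted because it is
  dataset-scale-dependent.
- Missing values are rejected at load time unless the caller opts into
  dropping incomplete genes.

## Problem sizes

The test suite and the acceptance script run the full fixture (2,000
genes × 20 samples, methods 1–4) over 10 seeds, which completes in well
under a minute on a single core; oracle equivalences use 20×20 matrices,
graphs of ≤ 8 nodes, and 1,000 random p-vectors. These sizes were chosen
so the whole battery is quick to iterate on while every pipeline stage is
exercised end to end.

## Known limitations

- The tree cut is a transparent global-height rule plus kME refinement,
  not the dynamic hybrid branch-splitting algorithm; very close or nested
  modules that the hybrid cut separates may be merged or greyed here.
- Only two-group contrasts (no multi-factor designs, no paired samples,
  no voom-style count weights).
- Only Pearson correlation (no biweight midcorrelation or Spearman), and
  no block-wise approximation — matrices are dense O(G²), practical to
  roughly 20–30k genes in 8 GiB.
- Quantitative traits are supported only through Pearson correlation with
  the trait vector.
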