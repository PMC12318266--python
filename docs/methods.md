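# Methods

This note documents the statistical models implemented in `hepzone`, the
synthetic data the tests run on, and the design choices made where the
analysis recipe left details open.

## Synthetic lobule model

Each nucleus carries a latent lobular coordinate u ~ U(0, 1), with u = 0 at
the central vein and u = 1 at the portal triad. Genes belong to four classes
with expected expression μ_g(u):

* **pericentral / periportal monotone** — logistic ramps
  μ(u) = lo + (hi − lo)/(1 + exp(±s(u − 0.5))) with hi/lo equal to the
  configured `gradient_fold` (default 2) and steepness s = 8; lo and hi are
  set so the profile's mean over u equals `base_mean`.
* **mid-peaked** — a Gaussian bump of width 0.12 centered at u = 0.5.
* **flat** — constant at `base_mean`.

Counts are gamma–Poisson: given a per-nucleus log-normal library factor
(σ_log = 0.25) the count mean is scaled and drawn with
Var = μ + φμ², φ = `nb_dispersion` (default 0.15; φ = 0 is the Poisson
limit). The knockout genotype replaces designated genes' profiles by their
mean over u (**flatten**: bulk level preserved, zonation lost), by a 2% floor
(**ablate**), or by their maximum everywhere (**expand**: ectopic
expression). The default knockout flattens both monotone programs, ablating
a small pericentral subset and expanding a small periportal subset —
mirroring loss of a pericentral program with ectopic spread of its
periportal counterpart.

The default panel is 1000 genes (150 + 150 monotone, 75 mid-peaked, 600
flat, 25 mitochondrial) at `base_mean` = 2, i.e. roughly 2000 counts and
850 detected genes per nucleus, with 2 × 2000 nuclei. These sizes are a
deliberate desk-scale reduction of a hepatocyte snRNA-seq experiment chosen
so that (a) the QC thresholds (500 detected genes, 2% mitochondrial) are
meaningful, and (b) per-nucleus positional information is comparable to real
data, where thousands of zonated genes inform the lobular coordinate. What
the generator does **not** emulate: ambient RNA, doublets, batch structure,
gene–gene correlation beyond the shared coordinate, and multi-lobule tiling
— so passing tests demonstrate correctness of the pipeline's statistics, not
robustness to those artifacts.

One configuration seed is expanded into independent substreams (coordinate,
library sizes, counts) via `numpy.random.SeedSequence`, making every stage
bit-reproducible.

## QC, normalization, scoring, clustering

Nuclei are kept when detected genes ≥ 500 AND mitochondrial fraction < 0.02
(the 2% boundary itself is discarded, matching the rule "at least 2% … were
discarded"). The mitochondrial fraction is computed on the raw matrix.
Normalization is log1p(count · 10⁴ / library size) — a deliberate,
integration-free simplification of variance-stabilizing transforms, adequate
for synthetic data without batch structure. Marker scores are means of
per-gene z-scores over a marker set (no control-feature subtraction, unlike
Seurat's AddModuleScore); zero-variance genes contribute 0, using a relative
tolerance so numerically constant genes are treated as constant. Clustering
is PCA (12 PCs, resolution 0.12 by default) → symmetrized kNN connectivity
graph (k = 20) → Louvain community detection (python-igraph), seeded, with
labels renumbered by first appearance so ties break toward the lowest
nucleus index.

## Diffusion pseudodistance

PCA to 30 components; Gaussian kernel with a single global bandwidth equal
to the median distance to the 15th nearest neighbor; Coifman–Lafon density
normalization with α = 1; row-normalization to a Markov matrix whose
spectrum is computed through the symmetric conjugate for stability. The
trivial eigenpair is dropped and component signs are fixed deterministically.
This global-bandwidth kernel is a documented divergence from Destiny's
locally scaled kernel; on simulated lobules it recovers the latent
coordinate equally well and is simpler to reason about. Diffusion
pseudotime from a root nucleus is the Euclidean distance in
eigenvalue-rescaled component space (weights λ/(1 − λ)); the root is the
nucleus with the maximum periportal score (the analysis recipe names no
root; this choice is deterministic and biologically anchored, and DPD is
stable to swapping in any of the top periportal candidates). DPT is min–max
rescaled to [0, 1] and flipped, if needed, so that DPD correlates negatively
with the pericentral score: DPD = 0 is the pericentral end. A constant
pericentral score leaves the orientation unchanged and is flagged
`ambiguous`. The embedding is computed jointly over both genotypes (they
share one coordinate system); this is an assumption — the alternative,
per-genotype embeddings, would preclude comparing profiles on a common axis.

## Zonation testing

DPD is cut into equal-width bins (80 for testing; DPD = 1 belongs to the
last bin). For each gene and genotype the per-bin mean expression is
regressed on a cubic B-spline basis of the bin midpoint with 4 basis
functions (one interior knot at 0.5, intercept excluded) by weighted least
squares, weights = bin occupancy, and compared with the intercept-only model
by the nested F-test: F = ((SSR₀ − SSR₁)/4)/(SSR₁/(n − 5)). The recipe's
"GAM + parametric ANOVA" is realized as this fixed-df spline regression
because parametric ANOVA is exactly defined for nested linear models; empty
bins are dropped, not interpolated, and at least 10 non-empty bins are
required. A constant profile returns F = 0, p = 1 by convention. The
zonated call is strictly p < 0.05. Calibration on 1000 flat genes with
2000 nuclei gives a ~5% rejection rate and near-uniform null p-values;
power on 2-fold monotone gradients is ≈ 1. Note the calibration is cleanest
when unzonated genes dominate the panel — with a heavily zonated panel,
library-size normalization couples flat genes to the coordinate
(composition bias), as in real data.

Modules: zonated genes' concatenated control‖knockout 8-bin profiles are
z-scored per gene, distanced by 1 − Pearson correlation, clustered with
complete-linkage agglomeration and cut at k = 4 (exposed as a parameter),
labeled A, B, … in order of first appearance. Overlap with reference gene
sets uses the hypergeometric upper tail P(X ≥ overlap) with population =
universe, successes = set size, draws = module size; the overlap *fraction*
divides by the union of the two sets by default ("the number of genes in
both sets" is ambiguous between union, sum, and target; all three are
selectable). BH adjustment runs across all module × set tests.

## Differential expression and metabolites

Within a cluster, "expressed" means a nonzero count (the recipe does not
define it); genes expressed in strictly more than 10% of cells of both
genotypes are tested with the equal-variance two-sample t-test ("Student's
t-test" read literally, not Welch), identical samples yielding t = 0, p = 1;
BH runs over the tested genes and a gene passes at FDR < 0.05. The
ratio-slope statistic computes per gene and genotype
log2((mean HEP2 + ε)/(mean HEP1 + ε)) with ε = 10⁻⁹ (guarding empty genes
without distorting expressed ones) and regresses knockout on control ratios
by OLS with an intercept; slope < 1 indicates attenuation of the
pericentral/periportal distinction. The metabolite filter keeps rows with
−log10(p) > 1.3 and |log2FC| > 1.0, both strict (p = 0.05 itself passes the
first rule since −log10(0.05) ≈ 1.301), and reports per-category
proportions over the significant subset.

## smFISH quantification

Spot detection is scale-normalized Laplacian-of-Gaussian filtering at the
PSF scale with local-maximum extraction and per-axis quadratic sub-pixel
refinement — a deliberately simple stand-in for dedicated FISH spot callers,
sufficient at the simulated SNR. Distances are to the vein *boundary*;
spots inside vein lumens are masked with a warning (lumens are masked in the
real protocol too). r = d_CV/(d_CV + d_PV), bin = floor(10·r) with r = 1
clamped into bin 9. Bin areas are counted pixel-wise over the per-image
tissue mask (vein interiors excluded). Order of operations: densities
(count/area) first, then percentages of total density — this makes a
uniform field give a flat 10% profile, the natural null. Per-mouse profiles
are unweighted means over images. With multiple portal veins, each spot
would use its nearest; the generator emits one CV/PV pair per image.

## Association statistics

Genotype prevalences are reported at one decimal with a 2×3 χ² test of
independence; continuous characteristics can be tested by one-way ANOVA
reconstructed exactly from per-group n/mean/SD. The crude allelic odds
ratio collapses genotypes to dosage-weighted allele counts with a Woolf CI
and Haldane–Anscombe +0.5 correction for zero cells. Per-allele regression
is grouped logistic (GLM binomial on cases/non-cases vs dosage) for
aggregate tables — identical to individual-level logistic on the expanded
data — and covariate-adjusted logistic/linear ML/OLS fits with Wald
inference on individual-level data. Covariate adjustment is only possible
on individual-level data; aggregate-table estimates are labeled crude. The
biomarker scan applies the per-allele regression to each biomarker and
flags p strictly below the Bonferroni threshold α/m (0.05/168 ≈ 2.976e-4
for the full panel).

The synthetic cohort draws Hardy–Weinberg genotypes at T-allele frequency
q = 0.29, age ~ N(56.6, 8), sex ~ Bernoulli(0.46), ten standard-normal
ancestry PCs; disease follows a logistic model with intercept −3.3
(baseline prevalence near 4%), per-allele log-odds 0.30, and modest age/sex
effects; biomarkers are Gaussian with per-allele shifts (glucose +0.055,
glutamine −2.0 by default). Family-wise error of the Bonferroni-held null
scan is verified by simulation with an explicit Monte-Carlo error allowance.

## Problem sizes and numerical conventions

Tests run at 2 × 2000 nuclei × 1000 genes for embedding recovery, 2000
nuclei × 1050 genes for test calibration, 200 replicates × 400 individuals
× 168 biomarkers for the family-wise error check, and 50,000 individuals
for parameter recovery — sizes chosen as the smallest at which the
statistical properties under test are well resolved. Spline fits use
`numpy.linalg.lstsq`; eigendecompositions use dense/Lanczos symmetric
solvers on the conjugated kernel; disconnected kernel graphs raise with
advice to widen the bandwidth; DPD requires a non-constant DPT; degenerate
inputs (empty panels, zero-total nuclei, empty universes, zero-area bins
with counts) raise explicit errors rather than propagating NaNs.

## Known limitations

* The normalization is not a variance-stabilizing transform; heavily
  zonated panels induce composition bias in library-size scaling.
* The diffusion kernel uses one global bandwidth; strongly non-uniform
  nucleus densities would justify local scaling.
* The spline df is fixed at 4; the test targets smooth monotone or unimodal
  profiles and has reduced power against high-frequency spatial patterns.
* smFISH detection assumes isolated diffraction-limited spots; dense spot
  clusters are not decomposed.
* Aggregate-table association cannot adjust for covariates, so its odds
  ratio approximates, but does not equal, a covariate-adjusted estimate.
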