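# hepzone

Hepatic lobule **zonation** analysis for single-nucleus RNA-seq, with smFISH
radial quantification and genotype–phenotype association statistics.

The liver lobule is a radially organized tissue: hepatocytes near the central
vein (pericentral) and near the portal triad (periportal) run distinct
transcriptional programs, and many genes show smooth expression gradients
along the pericentral→periportal axis. `hepzone` provides a tested, reusable
implementation of a pipeline for quantifying that organization and how it
changes when a regulator (e.g. the Wnt effector TCF7L2) is knocked out:

1. **QC and normalization** — nuclei with < 500 detected genes or ≥ 2%
   mitochondrial reads are discarded; counts are log1p-normalized; nuclei are
   scored for pericentral/periportal marker expression and clustered
   (PCA → kNN graph → Louvain).
2. **Diffusion pseudodistance (DPD)** — a diffusion map is built on the top
   30 PCs; diffusion pseudotime from a periportal root nucleus,
   DPT(i) = ‖(ψᵢ − ψ_root) · λ/(1−λ)‖ over the diffusion components ψ, is
   min–max rescaled to [0, 1] and oriented with the pericentral marker score
   so that DPD = 0 is the central-vein end of the lobule.
3. **Zonation testing** — expression is averaged in 80 DPD bins; for each
   gene and genotype a cubic B-spline model (df = 4) of the bin means is
   compared with the intercept-only model by a weighted parametric F-test
   (weights = bin occupancy); a gene is zonated when p < 0.05 (strict).
   Genes are classified both / control-only / knockout-only / neither.
4. **Modules and overlaps** — zonated genes are clustered on their
   concatenated 8-bin control‖knockout profiles (1 − Pearson distance,
   complete linkage, tree cut at k = 4); modules are scored against reference
   gene sets (e.g. β-catenin-induced/suppressed) with the hypergeometric
   upper-tail test, P(X ≥ overlap), and Benjamini–Hochberg adjustment.
5. **Differential expression** — per-cluster genotype comparisons
   (equal-variance t-test on genes expressed in > 10% of cells of both
   genotypes, FDR < 0.05), the HEP2/HEP1 ratio-slope statistic (an OLS slope
   < 1 means the pericentral/periportal distinction is attenuated in the
   knockout), and a metabolite volcano filter (−log10 p > 1.3, |log2FC| > 1).
6. **smFISH quantification** — spots detected by Laplacian-of-Gaussian
   filtering are assigned to 10 lobular bins by r = d_CV/(d_CV + d_PV), the
   relative distance between central- and portal-vein outlines; per-bin
   counts are normalized by pixel area, converted to percentages and averaged
   per mouse.
7. **Association statistics** — genotype prevalences with a χ² test, the
   crude per-T-allele allelic odds ratio (Woolf CI, Haldane–Anscombe
   correction), per-allele logistic/linear regression with age/sex/ancestry-PC
   covariates, and a Bonferroni-thresholded (α/m) multi-biomarker scan.

Because the real snRNA-seq, smFISH and biobank data are large and access
controlled, the package ships first-class synthetic generators
(`hepzone.simulate`) with known ground truth: zonated negative-binomial count
matrices over a latent lobular coordinate u ∈ [0, 1] with knockout effects
(flatten / ablate / expand per gene program), inhomogeneous-Poisson smFISH
spot fields with intensity λ(r), and Hardy–Weinberg cohorts with logistic
disease risk and Gaussian biomarker shifts. Every pipeline stage is tested
against these generators' ground truth.

## Worked example

```python
import pandas as pd
from hepzone import (LobuleSimConfig, MarkerSets, generate_lobule_counts,
                     normalize_log, compute_dpd, test_zonation,
                     classify_zonation)
from scipy.stats import spearmanr

adata, truth = generate_lobule_counts(LobuleSimConfig(seed=1, ko_effect={}))
norm = normalize_log(adata)
markers = MarkerSets([f"PCg{i:03d}" for i in range(80)],
                     [f"PPg{i:03d}" for i in range(80)])
dpd = compute_dpd(norm, markers)
print(round(spearmanr(dpd.values, truth.u).statistic, 3))
# 0.906  -> the inferred lobular coordinate tracks the latent truth

res = test_zonation(norm, dpd.values, genotype="CON")
print(int(res["zonated"].sum()), "of", len(res), "genes zonated")
# 417 of 1000 genes zonated  (375 genes carry a planted gradient)
```

Association statistics work directly on aggregate genotype-by-outcome tables:

```python
from hepzone import genotype_prevalence, allelic_or
table = pd.DataFrame({"dosage": [0, 1, 2], "n": [54649, 44178, 9192],
                      "cases": [2353, 2508, 698]})
print(genotype_prevalence(table)[0]["percent"].tolist())  # [4.3, 5.7, 7.6]
print(round(allelic_or(table)[0], 3))                     # 1.349
```

A thin CLI mirrors the library:
`hepzone simulate counts|smfish|cohort`, `hepzone qc`, `hepzone dpd`,
`hepzone zonate`, `hepzone smfish-quant`, `hepzone assoc prevalence|or|scan`.

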