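# methyldriver

Finding the few genes whose DNA methylation actually drives a tumor — and
asking whether they are visible in blood.

Colorectal cancer develops through a staged progression (normal mucosa →
low-grade adenoma → high-grade adenoma → carcinoma stages I–IV) in which
aberrant CpG methylation appears early. `methyldriver` reimplements, as a
tested and reusable pipeline, the computational chain used to distill a
genome-wide methylation screen down to a minimal diagnostic panel:

1. **Methylation-driven gene (MDG) calling.** Probes are grouped into
   correlated *methylation clusters* per gene (average-linkage on
   1 − Pearson *r*); a univariate Gaussian mixture (K ∈ {1,2,3}, BIC) is
   fitted to each cluster's disease beta values. A cluster is *driven* when
   some component's differential methylation |DM| = |μₖ − μ_normal| ≥ 0.10
   with a rank-sum p < 0.01 **and** its methylation inversely predicts the
   gene's expression (Pearson r < −0.3, p < 0.01).
2. **Linear discriminant classification.** A two-class LDA with pooled
   covariance shrunk toward its diagonal, w = Σ̂_λ⁻¹(μ₊ − μ₋) with
   Σ̂_λ = (1−λ)Σ̂ + λ·diag(Σ̂); λ is chosen automatically
   (Schäfer–Strimmer-type estimate with a p/(p+n) conditioning floor), so the
   model stays usable when features rival samples. Performance is measured
   as ROC AUC by the rank method (ties ½).
3. **Iterated, stability-voted recursive feature elimination (iRFE).** One
   RFE run ranks features by standardized discriminant weight |wᵢ|·sd(xᵢ)
   and picks the subset size maximizing 5-fold cross-validated AUC (ties →
   smallest). The run is repeated 100 times under different resampling
   seeds; features appearing in ≥ 50 of the optimal subsets survive, and
   the procedure is iterated on the survivors until the panel stops
   shrinking.
4. **Statistical context.** Random same-size panels provide an AUC null
   (one-tailed one-sample t-test of the B null AUCs against the observed
   AUC); panel features are checked for mutual correlation against a
   100-repeat random-panel baseline; and a correlation-ranked single-gene
   GSEA (weighted-KS enrichment score, gene-set-permutation NES) asks which
   gene sets co-methylate with each panel member.
5. **cfDNA evaluation.** The tissue-trained model is applied *unchanged* to
   cell-free DNA modeled as a stage-dependent mixture
   β = f·β_tumor + (1−f)·β_leukocyte, asking at which tumor stage the panel
   becomes detectable in plasma.

Because the original cohorts (TCGA/GEO/CFEA) are not redistributable, the
package ships a first-class synthetic cohort generator
(`methyldriver.synthetic`) that emulates their statistical structure —
beta-distributed probe values, hyper/hypomethylated driver genes with
inversely coupled expression, effects beginning at adenoma and plateauing
across cancer stages, a planted minimal 4-cluster panel tied together by a
latent co-methylation factor, methylator-phenotype correlation among the
remaining drivers, and cfDNA as a tumor-fraction dilution series. Every
stage of the pipeline is validated against this generator's ground truth.

## Worked example

Run the whole pipeline on the default synthetic study conditions (2000
genes, 100 planted drivers, 260 tissue samples, 140 cfDNA samples):

```bash
methyldriver run --seed 1 --out run/
# pipeline ok: 8 stages -> run/
```

`run/manifest.json` then contains one report per stage. With master seed 1
the run prints (abridged):

```text
mdg           sensitivity 1.0   false_driver_rate 0.0   n_driver_clusters 100
discriminant  test_auc 1.0 (100-feature model, 140 train / 60 test)
irfe          history [100, 4, 4]  converged  panel = 4 clusters  holdout_auc 0.992
null_auc      observed 0.992 vs null mean 0.902  t = 22.2  one-tailed p = 1.7e-40
gsea          top set: PLANTED_COMETHYLATION  NES 1.96  p 0.0019
cfdna         AUC vs healthy: stages 0-III <= 0.62, stage IV = 1.0
```

Reading this: all 100 planted driver genes were recovered with no false
calls; iterated RFE shrank the 100 driver clusters to exactly the 4 planted
panel clusters in one generation and stopped; the 4-cluster model separates
held-out cancer from normal tissue nearly perfectly, far above random
4-cluster panels; the gene set built from the planted co-methylation factor
tops the single-gene GSEA ranking; and in simulated plasma the panel only
becomes detectable at stage IV, when the tumor fraction jumps from ≤ 5% to
40% — the dilution effect the cfDNA evaluation is designed to expose.

Each stage is also available as its own CLI verb (`simulate`, `call-mdg`,
`train-lda`, `evaluate`, `irfe`, `null-auc`, `correlate`, `sg-gsea`,
`cfdna-eval`) operating on plain TSV/CSV/GMT/JSON files, and as a library
API (`import methyldriver`).

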