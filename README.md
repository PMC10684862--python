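# oxim

Multi-cohort tumor subtyping for bulk expression data: cross-cohort
integration by per-cohort median binarization, consensus clustering into an
oxidative/proliferative (OX+) and an immune-infiltrated (IM+) subtype,
molecular/clinical/survival characterization of the subtypes, and a compact
gene-panel classifier selected by SVM-RFE and tuned by replicated
cross-validated grid search.

The package is aimed at analysts who want to pool many public expression
cohorts (different platforms, labs, normalizations) without a parametric
batch-correction model.  Its integration primitive is deliberately blunt:
within each cohort, every gene is thresholded at its own median, so a value
becomes "above (1) or below (0) the cohort-typical level of this gene".
Any monotone per-(gene, cohort) distortion — which is what location/scale
batch effects are — vanishes by construction.

## The method in brief

1. **Binarize & merge.** Per cohort, x_gs → 1{x_gs > median_g}; merge
   cohorts on their shared genes; split 50/50 into training/testing halves.
2. **Consensus clustering.** Repeatedly subsample 80% of samples, cluster
   with PAM (k-medoids, BUILD+SWAP, implemented here) under Pearson
   distance d = 1 − r, and accumulate the co-clustering frequency of every
   pair; cut an average-linkage tree on 1 − consensus at k = 2.
3. **Name the clusters.** Per-gene differential expression between clusters
   by two-sided Fisher exact tests on the 2×2 (cluster × {0,1}) tables,
   with log2FC = log2((p̂_A + ε)/(p̂_B + ε)), ε = 0.01, BH-adjusted; genes
   ranked by log2FC feed a preranked GSEA (weighted KS running sum,
   gene-set permutation null); the cluster enriched for oxidative marker
   sets is OX+, the other IM+.
4. **Characterize.** ssGSEA-style rank scores per sample (oxidative-stress
   sets, immune/stromal signatures with the cosine purity mapping,
   cell-population markers), checkpoint-gene comparisons on pre-binarization
   values per cohort, clinical covariate tests, Kaplan–Meier / log-rank
   survival by subtype and per gene.
5. **Classify.** Filter genes (log2FC > 0.5, adj. p < 0.05), rank by
   SVM-RFE, pick the panel size where CV accuracy plateaus, tune DT / SVM /
   ANN / RF grids by replicated stratified fivefold CV on mean AUC, and
   evaluate on the independently re-clustered testing half.

Because the public cohorts this design targets cannot be bundled, the
package includes a first-class synthetic generator (`oxim.syndata`) that
emulates a 12-cohort, 2154-sample compendium with planted subtypes, batch
effects, partially overlapping gene inventories and subtype-dependent
survival — with ground truth returned for recovery testing.  See
`docs/methods.md` for the model and its limits.

## Worked example

```python
from oxim.pipeline import PipelineConfig, run_pipeline
from oxim.syndata import SynthConfig

config = PipelineConfig(
    outdir="demo_out",
    synth=SynthConfig(cohort_sizes=[60] * 6, n_genes=300, n_shared_genes=250, seed=1),
    cc_reps=50, gsea_n_perm=300, cv_replicates=2,
)
manifest = run_pipeline(config)

sil = manifest["stages"]["integrate"]
print(f"batch silhouette: raw {sil['silhouette_before']:.2f} -> binary {sil['silhouette_after']:.2f}")
print(f"subtype recovery ARI (training): {manifest['recovery']['training_ari']:.2f}")
for row in manifest["stages"]["models"]["evaluation"]:
    print(f"{row['family']:>3}: test AUC {row['test_auc']:.3f}, accuracy {row['test_accuracy']:.3f}")
print("hub gene:", manifest["stages"]["survival"]["hub_gene"])
```

prints (seed 1):

```
batch silhouette: raw 0.77 -> binary -0.04
subtype recovery ARI (training): 0.98
 DT: test AUC 0.832, accuracy 0.817
SVM: test AUC 0.987, accuracy 0.950
ANN: test AUC 0.974, accuracy 0.878
 RF: test AUC 0.985, accuracy 0.933
hub gene: OXG022
```

Reading the numbers: the six simulated cohorts are fully separable in raw
PC space (silhouette 0.77) and indistinguishable after binarization
(−0.04); consensus clustering recovers the planted subtypes almost exactly
(ARI 0.98); all four classifier families transfer to the independently
re-clustered testing half, with the radial SVM strongest; the hub gene is
the panel gene whose values alone best separate the subtypes (folded
univariate AUC).

The same pipeline is available from a shell via a YAML config:

```sh
oxim simulate --outdir data/ --seed 1        # write a synthetic compendium
oxim all --config run.yaml --outdir out/     # run every stage
```

Every stage writes TSV/JSON outputs plus a run manifest; re-running an
identical config reproduces every output byte for byte (the manifest's
wall-clock timestamps aside).

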