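# scmoc — paired single-cell RNA + ATAC clustering

`scmoc` clusters single-cell multi-omics data in which gene expression
(scRNA-seq) and chromatin accessibility (scATAC-seq) are measured in the
*same* cells. It is aimed at analysts working with co-assay protocols
(sci-CAR, SNARE-seq, 10x Multiome), where the ATAC count matrix is
extremely sparse — often well below 1% nonzero — and unimodal ATAC
clustering collapses into noise.

## The method

The key idea is that cell–cell similarity can be estimated far more
robustly in the denser RNA modality, and, because the data are paired,
those similarities transfer to the ATAC modality cell-for-cell.

1. **Preprocessing.** Per modality: QC filtering; total-count
   normalization to 10⁴ per cell. RNA additionally: log(1+x), top-6000
   highly variable genes by the vst ranking (variance of clipped
   standardized counts under a loess mean–variance trend), per-gene
   z-scaling clipped at ±10, PCA to 20 components. ATAC is embedded with
   LSI: log-TF-IDF weighting followed by truncated SVD to 20 components.
2. **RNA-guided imputation.** For each cell *i*, find its k = 50 nearest
   neighbours **in RNA PCA space** (Euclidean), and replace the cell's
   normalized peak profile by the neighbourhood mean:
   x̂ᵢ = (1/k) Σ_{j∈N_RNA(i)} xⱼ. The imputed matrix is renormalized
   before embedding. (A *self-imputation* reference finds neighbours in
   the ATAC LSI space instead.)
3. **Unimodal clustering.** Each modality is clustered independently:
   symmetrized 50-NN graph, Louvain modularity optimization at
   resolution γ = 0.8, labels ordered by cluster size.
4. **Merge.** A contingency table of RNA × ATAC cluster overlaps is
   computed with rows normalized by RNA cluster size. An RNA cluster *r*
   is split when **two or more** ATAC clusters each cover strictly
   between 10% and 90% of *r*'s cells; each qualifying overlap becomes a
   sub-cluster, and *r*'s remaining cells are reattached to the nearest
   sub-cluster by mean Euclidean distance in RNA PCA space. The result
   always *refines* the RNA clustering — ATAC evidence can split RNA
   clusters, never merge them.

A seeded synthetic-data generator (`scmoc.simulate`) produces paired
count matrices with known nested structure and calibrated per-modality
densities spanning the 0.2%–7% regimes of the real protocols, so every
stage is testable without downloads.

## Worked example

`examples/01_full_pipeline.py` builds 2000 paired cells in four major
groups; group 0 is divided 40/60 into two subpopulations that differ
strongly in ATAC marker peaks but only weakly in expression — below the
threshold at which RNA-only Louvain separates them:

```
$ python examples/01_full_pipeline.py
ATAC density: raw 0.0100 -> imputed 0.3612
clusters: RNA 4, ATAC 5, merged 5
ARI vs fine ground truth: merged 0.960, RNA-only 0.899
```

Reading the numbers: imputation raises the ATAC matrix density from 1%
to 36%; the imputed-ATAC clustering finds five populations where RNA
finds four; the merge splits the corresponding RNA cluster, and the
merged labels agree with the true five-population structure (adjusted
Rand index 0.96) better than RNA-only clustering can (0.90, with the two
subpopulations fused).

The other examples show the imputation variants (`02`), the split rule
on a hand-built contingency table (`03`), and the downsampling benchmark
(`04`). The CLI mirrors the stages (`scmoc simulate | run | preprocess |
impute | cluster | merge | evaluate`); `scmoc run --help` shows the
file-level interface.

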