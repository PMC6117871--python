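# striacell

Analysis pipeline for classifying striatal interneurons from single-cell
RNA-seq UMI counts and for linking transcriptomes to intrinsic
electrophysiology (PatchSeq).

Single-cell surveys of the dorsolateral striatum resolve GABAergic
interneurons into discrete molecular classes (Pthlh-, Npy/Sst-, Th-,
Chodl-expressing, ...) that also harbor *continuous* gradients of
expression inside a class — most prominently a Pthlh/Pvalb continuum that
tracks fast-spiking physiology. This package implements the complete
computational chain such a study needs, with synthetic generators standing
in for raw recordings and sequencing data, so every stage can be verified
against known ground truth:

* **QC cascades** for a deep single-cell dataset (cells with more than
  1,500 molecules; genes with at least 25), a large UMI dataset (at least
  800 UMIs, total-UMI/genes ratio at least 1.2, zero tolerance for
  non-neuronal markers *Mog, Mbp, Aqp4, Gja1, C1qc, Aif1, Fn1, Cldn5*) and
  PatchSeq cells (more than 2,000 molecules **or** more than 1,000 genes,
  excluding mitochondrial/rRNA genes), plus normalization of every cell to
  2,000 counts.
* **Clustering scaffold** — log(CV) vs log(mean) variable-gene selection,
  a pluggable stand-in clustering stage (PCA-denoised agglomerative
  linkage with correlation distance plus nearest-centroid polish), cluster
  merging, a random-forest robustness report (80/20 split, per-cluster
  precision/recall and confusion probabilities), and a Ward/correlation
  cluster-mean dendrogram (cells normalized to 10,000 counts, log2(x+1)).
* **Marker scores** — for gene *i* and cluster *j*,

      enrich_ij  = mean_{k in j}(E_ik) / mean_k(E_ik)
      posfrac_ij = (1/|j|) * #{k in j : E_ik > 0}
      S_ij       = enrich_ij * posfrac_ij ^ power,   power in {0, 0.5, 1}

  ranked per cluster and unioned into marker panels; plus the gene-to-type
  **specificity** s_gj = cluster mean / sum of cluster means (rows sum
  to 1).
* **Within-cluster gradient** — a rank-1 negative-binomial latent factor
  log mu_ig = log s_i + a_g + c_g' f_i + w_g z_i with plate covariates,
  shared dispersion, monotone block-coordinate fitting; NB regression
  tests of factor-gene association; a projection-based factor-ephys
  association; and the Pearson screen of gene expression against 2-D
  embedding coordinates with the >10% in-cluster / <70% dataset detection
  filters.
* **Expression screens** — Spearman correlation against a target gene
  (called at rho > 0.15, BH q < 0.05) and Wilcoxon rank-sum differential
  expression (q < 0.05, fold change > 2), with exact small-sample
  p-values.
* **PatchSeq mapping** — specificity-weighted scores
  score_j = sum_g x_g s_gj over a marker panel (low-variance genes,
  SD < 1, dropped), compared with B = 10,000 bootstrap gene-lists;
  cells are assigned to the minimum-p cluster when p < 0.05, otherwise
  "undefined".
* **Intrinsic electrophysiology** — AP detection (dV/dt threshold,
  interpolated half-width), extraction of the intrinsic-parameter panel
  (RMP, Rin, tau_m, sag, rebound, AP threshold/amplitude/half-width,
  AHP and biphasic AHP, rheobase, latency, maximum/steady frequency,
  adaptation, IEI), the half-width > 2 ms / amplitude < 40 mV exclusion
  rule, PCA and BH-corrected Welch tests on signed-log features.
* **Synthetic data** — NB count matrices with planted clusters, markers,
  a rank-1 gradient and plate effects; PatchSeq queries with known type;
  and current-clamp sweep sets for five firing archetypes
  (fast-spiking, fast-spiking-like, late-spiking, bursting/low-threshold,
  regular-spiking) with exactly controllable ground-truth features.

## Worked example

```python
from striacell.synthetic_data import CountSimConfig, GradientSpec, simulate_counts
from striacell.cluster_scaffold import select_variable_genes, cluster_cells
from striacell.marker_score import enrichment_scores, top_markers
from sklearn.metrics import adjusted_rand_score

cfg = CountSimConfig(seed=20240501, n_plates=2, plate_effect_sd=0.1,
                     gradient=GradientSpec(cluster="C1"))
m, truth = simulate_counts(cfg)           # 500 genes x 700 cells, 7 clusters
fit = select_variable_genes(m, n=150)
clusters = cluster_cells(m, fit, k=7)
print(adjusted_rand_score(truth.assignment.labels_for(m.cell_ids),
                          clusters.labels_for(m.cell_ids)))
# 0.977
```

The numbered scripts under `analysis/` run the full narrative on this
reference and print what they find, e.g.:

```
$ python analysis/03_cluster_and_markers.py
Variable genes: top 150 by CV residual (fit slope -0.190)
Clustering at k=7: ARI vs planted clusters = 0.977
Robustness (held-out RF): mean precision 95.1%, mean recall 95.0%
Marker ranking (power 1): median 10/10 planted markers in each cluster's top-10

$ python analysis/06_patchseq_and_ephys.py
PatchSeq QC: 98/98 cells pass
Mapping (panel of 71 markers, 71 retained, B = 1000): 87 assigned / 11 undefined;
accuracy among assigned 100.0%
Ephys: 100 simulated cells, 0 excluded by the half-width/amplitude rule
PCA on 18 parameters: PC1 56%, PC2 14% of variance
Fast-spiking vs regular: 14/18 parameters differ at q < 0.05
```

The ARI of 0.977 says the stand-in clustering recovers the seven planted
classes nearly perfectly at 4-fold marker enrichment; the mapping line
says 87 of 98 synthetic PatchSeq cells reach a bootstrap p < 0.05 for
some cluster and every one of them lands on its true type; the ephys
lines say the five firing archetypes yield a feature table whose first
two principal components separate fast-spiking from regular-spiking
cells, with 14 of 18 intrinsic parameters differing significantly.
Result tables land in `results/`.

## Layout

```
src/striacell/    library: matrix_io, qc_normalize, cluster_scaffold,
                  marker_score, gradient_latent, diffexpr_corr,
                  patchseq_map, ephys_features, synthetic_data
analysis/         numbered narrative drivers (01 simulate ... 06 ephys)
tests/            pytest suite incl. end-to-end acceptance properties
scripts/          acceptance.py
docs/methods.md   models, parameters, numerical choices, limitations
```
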