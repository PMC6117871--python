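# Methods

This note documents the models and procedures implemented in striacell,
the parameters that matter, the numerical choices behind them, and what
the synthetic-data tests do and do not establish about real data.

## Quality control and normalization

Three cascades, with every inequality implemented exactly as its rule is
phrased (strict where the rule says "more than"/"less than"):

| scheme | cell rule | gene rule |
|---|---|---|
| deep dataset | total molecules > 1,500 | dataset-wide total ≥ 25 |
| UMI dataset | total ≥ 800 **and** total/genes-detected ≥ 1.2 **and** zero molecules of every non-neuronal marker | — |
| PatchSeq | molecules > 2,000 **or** distinct genes > 1,000, after removing mitochondrial/rRNA genes | — |

The default non-neuronal marker panel is *Mog, Mbp, Aqp4, Gja1, C1qc,
Aif1, Fn1, Cldn5* (oligodendrocyte, astrocyte, microglia, fibroblast,
endothelial). Activity-dependent and mito/rRNA gene lists are plain
configurable lists (`GeneListConfig`); they default to empty because no
canonical list ships with the package. The UMI-dataset genes-detected
denominator is computed on the full gene set, before any marker removal.
Manual doublet curation is not automated; an exclusion list can be
supplied.

Total-count normalization scales each cell to 2,000 counts (10,000 for
the dendrogram profile, see below). "Closest integer" rounding is
half-away-from-zero; half-integers are rare on this arithmetic and the
choice only matters at the third decimal of downstream statistics.

## Variable genes and the clustering stand-in

Variable genes are the `n` largest positive residuals of log10(CV) over
an ordinary-least-squares line in log10(mean), computed on genes with
positive mean, with an epsilon = 1e-8 floor protecting zero-variance
genes. The selection is invariant to globally rescaling the counts.

The discrete cluster discovery of the original study design used a
biclustering algorithm published elsewhere; it is deliberately not
reimplemented. The clustering stage here is a pluggable interface whose
default is: log2(x+1) on per-cell-normalized counts over the selected
genes → PCA to 20 components (exact SVD, deterministic) → agglomerative
Ward linkage on correlation distance cut at k → a nearest-centroid
reassignment loop run to its fixed point. The PCA denoising and the
centroid polish are what lift the partition from ARI ≈ 0.87 to ≈ 0.97 on
the 7-cluster / 4-fold-marker reference; pure linkage at these noise
levels chains badly under average linkage and plateaus under Ward.
Assignments can equally be loaded from a TSV — every downstream stage
consumes only a cell → label map.

Robustness is assessed with a random-forest classifier (200 trees,
seeded) on a stratified 80/20 split of the labelled cells; the report
carries per-cluster precision, recall and the row-normalized confusion
probabilities. One split by default; the hyperparameters are defaults,
not tuned. The cluster-mean dendrogram normalizes each cell to 10,000
molecules, takes log2(x+1), averages within clusters and applies Ward
linkage on correlation distance; it is emitted as Newick with merge
heights as branch lengths.

## Marker scores and specificity

For gene *i*, cluster *j* over N cells:
enrich_ij = (mean over k in j of E_ik) / (mean over all k), posfrac_ij =
fraction of cluster cells with E_ik > 0, and S_ij = enrich_ij ×
posfrac_ij^power with power ∈ {0, 0.5, 1}. Genes with zero global mean
define enrich = 0. Scores are computed on equal-total-normalized
expression by default (a flag switches to raw counts); ranking ties break
lexicographically by gene symbol so the panels are deterministic.

Specificity follows the expression-weighted cell-type enrichment
convention: s_gj = cluster-mean expression of g in j divided by the sum
of g's cluster means, so each in-universe row sums to one; genes with
all-zero cluster means are flagged out of the universe.

## Rank-1 negative-binomial latent factor

Model: y_ig ~ NB(mu_ig, theta) with Var = mu + mu²/theta and

    log mu_ig = log s_i + a_g + c_g' f_i + w_g z_i

where log s_i is an equal-total library-size offset, f_i the plate
indicator design (one 0/1 column per plate except a reference plate), and
z_i the per-cell factor score. Genes enter only if they show more than 3
reads in more than 8 cells (both strict).

Fitting is block coordinate ascent: one IRLS step per gene (shared design
[1, f, z]) and one damped Newton step per cell score, each backtracked by
step-halving until the likelihood does not decrease, so the recorded
log-likelihood trace is non-decreasing by construction. Three exact
reparameterizations keep the model identified without touching the
likelihood: (i) the component of z inside the span of [1, F] is projected
out and pushed into a_g and c_g — without this the factor is
unidentified against the plate coefficients and simply reproduces the
batch structure; (ii) z is standardized to mean 0, variance 1 with w and
a absorbing the shift; (iii) the global sign puts positive loading on the
gene with the largest |w|. The shared dispersion is re-estimated by
method of moments each outer iteration, guarded: the update is kept only
if it does not lower the likelihood (an unguarded moment update can).
Convergence: relative log-likelihood change < 1e-6 or 200 outer
iterations; initialization is the first principal component of the
log-normalized matrix, so the fit is deterministic given the seed. A
matrix whose cells are all identical short-circuits to w = 0 with a
degenerate flag.

Factor-gene association uses a statsmodels NB GLM of the gene's counts on
z (with the model's offsets and covariates, alpha fixed at 1/theta);
under a null gene its p-values are uniform (measured 4.5% below 0.05 over
200 replicates). Factor-ephys association projects query expression as
sum_g w_g log(x_ig + 1) (at least 10 shared genes required) and fits an
ordinary linear model.

The embedding-coordinate screen correlates each gene (Pearson, on
log2-normalized expression by default) with the x and y coordinates of a
supplied 2-D embedding, restricted to genes detected in more than 10% of
the cluster's cells and in less than 70% of all cells, both strict. The
pipeline treats embedding coordinates as input; it does not compute tSNE.

## Expression screens

Benjamini-Hochberg adjustment is implemented directly (step-up, capped at
one) and cross-checked in the tests against both a brute-force
transcription of the definition and statsmodels.

Spearman screen: average-rank rho of every gene against the target gene;
p by the t approximation for n > 9 and by exact enumeration of value
permutations for n ≤ 9; BH over all tested genes; calls at rho > 0.15
and q < 0.05 in either direction; the target itself is reported but never
classified. Computed on normalized expression by default — on raw counts
library-size variation correlates everything with everything (measured:
~105 false calls per null replicate raw vs 0.03 normalized), so the
normalized default is load-bearing.

Rank-sum differential expression: two-sided p by exhaustive enumeration
of group assignments when n_A + n_B ≤ 10 (ties handled by the
permutation null itself), otherwise a tie-corrected normal approximation
with continuity correction, vectorized across genes. Fold change is
(mean_A + eps)/(mean_B + eps) on normalized counts with eps = 0.01;
significance requires q < 0.05 and |log2FC| ≥ 1. The BH family is the
genes detected in at least one cell of either group.

## PatchSeq bootstrap mapping

A query cell's observed score for cluster j is sum over the retained
marker genes of count × specificity. Panel genes with SD < 1 across the
query dataset (raw counts; a flag switches to log scale) are dropped;
SD exactly 1 is kept. The null re-scores the same count vector (fixed
order) against B random gene-lists drawn without replacement; empirical
p_j = (1 + #{null ≥ observed}) / (B + 1), so p ∈ [1/(B+1), 1]. The cell
is assigned to the argmin-p cluster when that minimum is below alpha =
0.05, ties go to "undefined" with a flag, and no multiplicity correction
is applied to the minimum — the selection effect is documented here
instead, below.

**Null gene-list universe.** The default draws the lists from the
retained gene list itself, i.e. the null is a random re-pairing of the
cell's counts with the panel's own specificities. Under this choice the
per-cluster p-value of a count-permuted cell is uniform by symmetry
(measured: 4.9–5.4% below 0.05 on 500–1,000 null cells). Drawing instead
from the whole reference transcriptome (available as
`MappingConfig.background="universe"`) is strongly anticonservative
whenever the marker panel's specificities are more variable than typical
background genes — which is exactly what "most informative markers"
means — and drove the null assignment rate to 0.75–0.88 in our
measurements; it is therefore not the default.

**Selection effect of min-p.** With uniform per-cluster p-values and K
clusters, P(min_j p_j < alpha) is bracketed by 1 − (1 − alpha)^K from
below (the score-sum constraint makes the p_j negatively orthant
dependent) and K·alpha from above (union bound); for K = 7, alpha = 0.05
that is [0.302, 0.350]. The measured null assignment rate (0.34 at
n = 1,000) sits inside this band. This is the documented calibration of
the assignment rule as published — per-cluster p-values are honest, the
headline "assigned at p < 0.05" rate on pure noise is ≈ K·alpha, not
alpha.

`map_dataset` reuses one seeded set of B gene-lists across all query
cells; each cell's marginal p-distribution is unchanged and the whole run
is bit-reproducible. A standalone `map_cell` draws its own lists.

## Intrinsic electrophysiology

AP detection: the threshold is the first sample of the contiguous run of
dV/dt ≥ 10 mV/ms preceding a voltage peak (prominence ≥ 10 mV);
amplitude is peak minus threshold; half-width is measured at threshold +
amplitude/2 with linear interpolation between samples. AHP troughs are
local minima below threshold voltage between the peak and the next
event, searched on a 0.25 ms moving-average of the segment with 1 mV
prominence (raw-noise dips would otherwise masquerade as troughs); a
distinct second trough defines the biphasic AHP differences. The
10 mV/ms threshold criterion is a configuration knob.

Feature extraction: RMP is the pre-stimulus baseline of the first sweep.
Rin = ΔV_ss/ΔI and tau_m (least-squares single-exponential fit of the
onset) come from the smallest hyperpolarizing step; sag = (peak − steady
state)/peak deflection and rebound (post-stimulus peak minus baseline)
from the largest. The sag peak search runs on a 5 ms moving average with
segment edges excluded: the transient develops over tens of ms, and on a
15 mV deflection the raw minimum of ~10⁴ noisy samples is biased by the
noise floor alone (≈ +0.01 sag without smoothing, ≈ 0.001 with).
Rheobase is the smallest depolarizing current with ≥ 1 AP inside the
step; single-AP features come from that sweep's first AP. Maximum firing
frequency is the max over sweeps of AP count/stimulus duration; steady
frequency counts spikes in the last half of that sweep; adaptation =
(ISI_last − ISI_first)/(ISI_last + ISI_first); IEI is the mean ISI.
Undefined features are NaN with a reason flag.

Exclusion: half-width > 2 ms or amplitude < 40 mV (strict); cells where
both are NaN are kept with an "unevaluable" flag. PCA and the pairwise
Welch tests (BH across parameters) run on sign(v)·log(1+|v|)-transformed,
z-scored parameters — several parameters (RMP, rebound) are negative, so
a plain log is unavailable. Missing entries are median-imputed for PCA
only, never for tests; constant parameters are dropped with a warning.
Hierarchical clustering of cells uses Euclidean distance on the same
transformed features, average linkage.

## Synthetic generators

Counts: gene baseline means are log-normal(0, 1); each cluster gets
cluster-exclusive markers multiplied by a fold enrichment (default 10
markers at 4-fold for each of 7 clusters of 100 cells); an optional
gradient multiplies its genes by exp(w*_g z*_i) inside one cluster, with
|w*| ≥ 0.2 so every planted gradient gene carries recoverable signal;
optional per-plate log-normal perturbations model batch effects; expected
expression fractions are scaled by log-normal library sizes (mean 2,000,
sigma 0.3) and sampled NB with theta = 2 (gamma-Poisson). In addition to
the planted markers, nothing else separates the clusters — real data
differ genome-wide between types, so classifiers that exploit only
markers here may find real data easier, and screen calibration measured
here says nothing about biological confounding (e.g. activity-dependent
transcription) in real tissue.

PatchSeq queries are drawn NB around their true cluster's mean profile at
a configurable depth (default 5,000), which models transcriptomic
identity but not the RNA-degradation and cytoplasm-sampling artifacts of
real PatchSeq — QC failure modes are therefore under-represented.

Traces: a passive leaky-membrane envelope (R, tau per archetype) carries
scheduled spikes: when the injected current reaches the planted rheobase
the firing rate interpolates from f_rheo to f_max at the failure current
(above it the cell is silent, modelling depolarization block), the first
spike occurs at the planted latency, and the ISI sequence is a geometric
ramp whose first/last ratio realizes the planted adaptation index.
Spike waveforms are piecewise-linear (rise and fall spanning whole
samples, so interpolated measurements are exact), with the fall depth and
duration chosen so the realized half-width equals the configured value;
AHP recovery is slope-capped at 8 mV/ms so threshold back-walking stops
at the true onset. The sag conductance engages only on steps more
hyperpolarizing than the smallest one, keeping the Rin/tau sweep a clean
RC response; the protocol brackets rheobase at 1 pA resolution (so
rheobase recovery is exact by construction) and steps coarsely to
failure. Gaussian noise (0.2 mV SD) is added last. The truth vector
records configured values where the construction realizes them exactly
(R, tau, rheobase, amplitude, rate-derived frequencies) and values
computed from the clean waveform where discretization intervenes
(half-width on the sample grid, sag/rebound of the realized transient).
The simulator is phenomenological by design — ground truth must be
exactly controllable, which conductance-based models do not allow — so
its traces lack channel noise, subthreshold oscillations and spike-shape
drift; feature-recovery results bound algorithmic error only, not
biological robustness.

## Problem sizes in the verification suite

The acceptance properties run at: 100 random matrices for the
marker-score oracle; 20 seeded rank-1 fits of 200 cells × 100 genes for
latent recovery; 1,000 gene-permuted null cells and 100 true query cells
at B = 1,000 for the mapping; 100 pure-null replicates for each screen
plus one 1,050-gene power run; 100 seeded cells per firing archetype for
feature recovery; and a double end-to-end run for bit-reproducibility.
The whole suite completes in about a minute on one CPU.

## Known limitations

* The latent factor is strictly rank-1; multi-factor continua are out of
  scope, and the stand-in is a reimplementation of intent — its scores
  need not match any particular external implementation numerically.
* The clustering stand-in is not a biclustering algorithm; gene modules
  are recovered by the marker ranking, not by the partition itself.
* Exact rank-sum/Spearman enumeration is reserved for tiny samples; at
  moderate sizes the tie-corrected normal/t approximations apply.
* The min-p assignment rule is reported uncorrected (see above); users
  wanting family-wise control should Bonferroni-divide alpha by the
  number of clusters.
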