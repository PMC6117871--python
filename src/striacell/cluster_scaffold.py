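"""Variable-gene selection, stand-in clustering, robustness and dendrograms.

The discrete cluster discovery of the original study used a biclustering
algorithm published elsewhere; here the clustering stage is a pluggable
interface whose default is agglomerative linkage with correlation distance
on log-transformed normalized counts over the selected variable genes.
Cluster assignments can equally be loaded from file — every downstream
stage only consumes a :class:`~striacell.matrix_io.ClusterAssignment`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .matrix_io import ClusterAssignment, CountMatrix

__all__ = [
    "VariableGeneFit",
    "RobustnessReport",
    "select_variable_genes",
    "cluster_cells",
    "merge_clusters",
    "assess_robustness",
    "cluster_mean_dendrogram",
    "linkage_to_newick",
]

_CV_EPS = 1e-8  # guard for zero-variance genes


@dataclass
class VariableGeneFit:
    """Result of the log(CV) vs log(mean) variable-gene selection."""

    table: pd.DataFrame  # per-gene: mean, cv, log_mean, log_cv, residual
    slope: float
    intercept: float
    selected: list[str]  # the n largest-residual genes


def select_variable_genes(m: CountMatrix, n: int = 1000) -> VariableGeneFit:
    """Select the ``n`` genes with the largest positive residual of
    log10(CV) over the straight-line fit against log10(mean).

    Only genes with positive mean enter the fit; the selection is
    deterministic (ties broken by gene symbol) and invariant to a global
    rescaling of the counts.
    """
    if m.n_cells < 2:
        raise ValueError("need at least 2 cells")
    E = m.counts.astype(float)
    mean = E.mean(axis=1)
    sd = E.std(axis=1, ddof=0)
    eligible = mean > 0
    if n > int(eligible.sum()):
        raise ValueError(f"n={n} exceeds {int(eligible.sum())} genes with positive mean")
    cv = np.where(eligible, sd / np.where(eligible, mean, 1.0), 0.0)
    cv = np.maximum(cv, _CV_EPS)
    log_mean = np.where(eligible, np.log10(np.where(eligible, mean, 1.0)), np.nan)
    log_cv = np.where(eligible, np.log10(cv), np.nan)
    x = log_mean[eligible]
    y = log_cv[eligible]
    slope, intercept = np.polyfit(x, y, 1)
    residual = np.where(eligible, log_cv - (slope * log_mean + intercept), -np.inf)
    table = pd.DataFrame(
        {
            "mean": mean,
            "cv": cv,
            "log_mean": log_mean,
            "log_cv": log_cv,
            "residual": residual,
        },
        index=pd.Index(m.gene_ids, name="gene"),
    )
    order = sorted(
        (g for g, e in zip(m.gene_ids, eligible) if e),
        key=lambda g: (-table.at[g, "residual"], g),
    )
    return VariableGeneFit(
        table=table, slope=float(slope), intercept=float(intercept), selected=order[:n]
    )


def cluster_cells(
    m: CountMatrix,
    fit: VariableGeneFit | list[str],
    k: int,
    linkage_method: str = "ward",
    n_pcs: int | None = 20,
    refine: bool = True,
    norm_target: float = 2000,
    label_prefix: str = "C",
) -> ClusterAssignment:
    """Stand-in clustering stage.

    log2(x+1)-transformed normalized counts on the selected genes are
    denoised by PCA (``n_pcs`` components; ``None`` skips), cells are
    grouped by agglomerative linkage with correlation distance cut at
    ``k``, and (with ``refine``) the partition is polished by a
    deterministic nearest-centroid reassignment until fixed point.
    Fully deterministic; labels are assigned by order of first appearance
    so the partition is stable (up to renaming) under cell permutation.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > m.n_cells:
        raise ValueError(f"k={k} exceeds {m.n_cells} cells")
    genes = fit.selected if isinstance(fit, VariableGeneFit) else list(fit)
    sub = m.subset(genes=[g for g in genes if g in set(m.gene_ids)])
    from .qc_normalize import normalize_total

    X = np.log2(normalize_total(sub, target=norm_target, round_to_integer=False).to_numpy() + 1).T
    if k == 1:
        labels = np.zeros(m.n_cells, dtype=int)
    else:
        if n_pcs is not None and X.shape[1] > 2:
            d_eff = int(min(n_pcs, X.shape[0] - 1, X.shape[1]))
            Xc = X - X.mean(axis=0)
            U, S, _ = np.linalg.svd(Xc, full_matrices=False)
            X = U[:, :d_eff] * S[:d_eff]
        # correlation distance is undefined for constant rows
        X = X + 0.0
        const = X.std(axis=1) == 0
        if const.any():
            X[const, 0] += 1e-9
        d = ssd.pdist(X, metric="correlation")
        Z = sch.linkage(d, method=linkage_method)
        labels = sch.fcluster(Z, t=k, criterion="maxclust") - 1
        if refine:
            labels = _nearest_centroid_refine(X, labels)
    # rename by first appearance for permutation stability
    remap: dict[int, str] = {}
    out: dict[str, str] = {}
    for cid, lbl in zip(m.cell_ids, labels):
        if lbl not in remap:
            remap[lbl] = f"{label_prefix}{len(remap) + 1}"
        out[cid] = remap[lbl]
    return ClusterAssignment(labels=out)


def _nearest_centroid_refine(X: np.ndarray, labels: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Reassign each cell to its nearest cluster centroid until the
    partition stops changing; empty clusters keep their last centroid."""
    uniq = np.unique(labels)
    centroids = np.stack([X[labels == c].mean(axis=0) for c in uniq])
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centroids[None]) ** 2).sum(axis=-1)
        new = uniq[np.argmin(d2, axis=1)]
        if np.array_equal(new, labels):
            break
        labels = new
        for i, c in enumerate(uniq):
            mask = labels == c
            if mask.any():
                centroids[i] = X[mask].mean(axis=0)
    return labels


def merge_clusters(a: ClusterAssignment, mapping: dict[str, str]) -> ClusterAssignment:
    """Relabel fine clusters into coarse categories; recorded in hierarchy."""
    missing = sorted(set(a.labels.values()) - set(mapping))
    if missing:
        raise ValueError(f"mapping does not cover labels: {missing}")
    merged = {c: mapping[lbl] for c, lbl in a.labels.items()}
    return ClusterAssignment(labels=merged, hierarchy=[*a.hierarchy, dict(mapping)])


@dataclass
class RobustnessReport:
    """Held-out classifier performance per cluster plus confusion probabilities."""

    precision: pd.Series
    recall: pd.Series
    confusion: pd.DataFrame  # rows: true cluster; columns: predicted; rows sum to 1
    train_frac: float
    seed: int

    @property
    def mean_precision(self) -> float:
        return float(self.precision.mean())

    @property
    def mean_recall(self) -> float:
        return float(self.recall.mean())


def assess_robustness(
    m: CountMatrix,
    a: ClusterAssignment,
    genes: list[str] | None = None,
    train_frac: float = 0.8,
    seed: int = 0,
    n_estimators: int = 200,
    norm_target: float = 2000,
) -> RobustnessReport:
    """Train a random-forest classifier on a stratified train split of the
    labelled cells and report held-out precision/recall per cluster and the
    probability that cells of cluster j are classified as cluster j'.
    """
    labels = a.labels_for(m.cell_ids)
    names, counts = np.unique(labels, return_counts=True)
    singletons = [str(n) for n, c in zip(names, counts) if c < 2]
    if singletons:
        raise ValueError(f"clusters with fewer than 2 cells: {singletons}")
    sub = m if genes is None else m.subset(genes=genes)
    from .qc_normalize import normalize_total

    X = np.log2(normalize_total(sub, target=norm_target, round_to_integer=False).to_numpy() + 1).T
    idx_train, idx_test = train_test_split(
        np.arange(m.n_cells),
        train_size=train_frac,
        stratify=labels,
        random_state=seed,
    )
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    clf.fit(X[idx_train], labels[idx_train])
    pred = clf.predict(X[idx_test])
    true = labels[idx_test]
    cluster_names = list(names)
    conf = pd.DataFrame(0.0, index=cluster_names, columns=cluster_names)
    for t, p in zip(true, pred):
        conf.at[t, p] += 1
    row_tot = conf.sum(axis=1)
    precision = pd.Series(
        {
            c: (conf[c][c] / conf[c].sum()) if conf[c].sum() > 0 else np.nan
            for c in cluster_names
        }
    )
    recall = pd.Series({c: conf.at[c, c] / row_tot[c] if row_tot[c] > 0 else np.nan for c in cluster_names})
    confusion = conf.div(row_tot.replace(0, np.nan), axis=0)
    return RobustnessReport(
        precision=precision,
        recall=recall,
        confusion=confusion,
        train_frac=train_frac,
        seed=seed,
    )


def cluster_mean_dendrogram(
    m: CountMatrix,
    a: ClusterAssignment,
    norm_target: float = 10000,
    method: str = "ward",
):
    """Ward linkage on correlation distance between cluster-mean profiles.

    Each cell is normalized to ``norm_target`` total molecules, transformed
    log2(x+1), and averaged within clusters; returns ``(linkage matrix,
    cluster label order)``.
    """
    labels = a.labels_for(m.cell_ids)
    names = a.cluster_names
    if len(names) < 2:
        raise ValueError("need at least 2 clusters")
    from .qc_normalize import normalize_total

    X = np.log2(normalize_total(m, target=norm_target, round_to_integer=False).to_numpy() + 1)
    means = []
    for name in names:
        idx = np.flatnonzero(labels == name)
        if idx.size == 0:
            raise ValueError(f"cluster {name!r} has no cells")
        means.append(X[:, idx].mean(axis=1))
    M = np.stack(means)
    const = M.std(axis=1) == 0
    if const.any():
        M = M.copy()
        M[const, 0] += 1e-9
    d = ssd.pdist(M, metric="correlation")
    Z = sch.linkage(d, method=method)
    return Z, names


def linkage_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a SciPy linkage matrix as a Newick string with merge
    heights as branch lengths."""
    tree = sch.to_tree(Z)

    def rec(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.10g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"
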