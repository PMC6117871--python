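"""Cluster marker enrichment scoring and the gene-to-type specificity matrix.

For gene *i* and cluster *j* with cells ``k in j`` out of *N* cells total:

.. math::

    \\mathrm{enrich}_{i,j} = \\frac{\\frac{1}{|j|}\\sum_{k\\in j} E_{i,k}}
                                  {\\frac{1}{N}\\sum_k E_{i,k}},
    \\qquad
    \\mathrm{posfrac}_{i,j} = \\frac{1}{|j|}\\sum_{k\\in j} I(E_{i,k}>0),
    \\qquad
    S_{i,j} = \\mathrm{enrich}_{i,j}\\times\\mathrm{posfrac}_{i,j}^{power}

where ``power`` weights the fraction of positive cells (0: pure
enrichment; 1: full weight). Genes are ranked per cluster by S at each
power and the top-X lists unioned into a marker panel.

The specificity of gene *g* for cluster *j* is that cluster's mean
expression divided by the sum of the gene's cluster means, so it sums to
one across clusters (the convention used by expression-weighted cell-type
enrichment analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix_io import ClusterAssignment, CountMatrix

__all__ = [
    "MarkerScoreTable",
    "SpecificityMatrix",
    "enrichment_scores",
    "top_markers",
    "specificity",
]


def _cluster_groups(m: CountMatrix, a: ClusterAssignment) -> dict[str, np.ndarray]:
    labels = a.labels_for(m.cell_ids)
    groups: dict[str, np.ndarray] = {}
    for name in a.cluster_names:
        idx = np.flatnonzero(labels == name)
        if idx.size == 0:
            raise ValueError(f"cluster {name!r} has no cells in this matrix")
        groups[name] = idx
    return groups


def _values(m: CountMatrix, use_normalized: bool, target: float) -> np.ndarray:
    if not use_normalized:
        return m.counts.astype(float)
    from .qc_normalize import normalize_total

    return normalize_total(m, target=target, round_to_integer=False).to_numpy()


@dataclass
class MarkerScoreTable:
    """Per (gene, cluster) enrichment scores at each configured power."""

    enrich: pd.DataFrame  # genes x clusters
    posfrac: pd.DataFrame  # genes x clusters
    scores: dict[float, pd.DataFrame] = field(default_factory=dict)  # power -> genes x clusters

    @property
    def powers(self) -> list[float]:
        return list(self.scores)

    @property
    def clusters(self) -> list[str]:
        return list(self.enrich.columns)


def enrichment_scores(
    m: CountMatrix,
    a: ClusterAssignment,
    powers: list[float] = (0.0, 0.5, 1.0),
    use_normalized: bool = True,
    norm_target: float = 2000,
) -> MarkerScoreTable:
    """Compute enrich, posfrac and S = enrich * posfrac**power per cluster.

    Scores are computed on equal-total normalized expression by default
    (``use_normalized=False`` switches to raw counts). Genes with zero
    global mean get enrich = 0 in every cluster.
    """
    groups = _cluster_groups(m, a)
    E = _values(m, use_normalized, norm_target)
    global_mean = E.mean(axis=1)
    names = list(groups)
    enrich = np.zeros((m.n_genes, len(names)))
    posfrac = np.zeros_like(enrich)
    for jx, name in enumerate(names):
        idx = groups[name]
        cl_mean = E[:, idx].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            enrich[:, jx] = np.where(global_mean > 0, cl_mean / global_mean, 0.0)
        posfrac[:, jx] = (E[:, idx] > 0).mean(axis=1)
    gidx = pd.Index(m.gene_ids, name="gene")
    enrich_df = pd.DataFrame(enrich, index=gidx, columns=names)
    posfrac_df = pd.DataFrame(posfrac, index=gidx, columns=names)
    scores = {
        float(p): pd.DataFrame(enrich * posfrac**float(p), index=gidx, columns=names)
        for p in powers
    }
    return MarkerScoreTable(enrich=enrich_df, posfrac=posfrac_df, scores=scores)


def top_markers(t: MarkerScoreTable, x: int) -> dict[str, dict]:
    """Top-``x`` genes per cluster at every power, plus the tagged union.

    Returns ``{cluster: {"per_power": {power: [genes]}, "union":
    {gene: [powers that selected it]}}}``. Ties in S are broken
    lexicographically by gene symbol for determinism.
    """
    n_genes = len(t.enrich.index)
    if x > n_genes:
        raise ValueError(f"x={x} exceeds gene count {n_genes}")
    out: dict[str, dict] = {}
    for cluster in t.clusters:
        per_power: dict[float, list[str]] = {}
        union: dict[str, list[float]] = {}
        for p, df in t.scores.items():
            s = df[cluster]
            order = sorted(s.index, key=lambda g: (-s[g], g))
            top = order[:x]
            per_power[p] = top
            for g in top:
                union.setdefault(g, []).append(p)
        out[cluster] = {"per_power": per_power, "union": union}
    return out


@dataclass
class SpecificityMatrix:
    """Genes x clusters matrix of cluster-mean specificity values.

    Rows of in-universe genes sum to one; genes whose cluster means are all
    zero carry zeros and are excluded from the background universe.
    """

    values: pd.DataFrame  # genes x clusters
    universe: list[str]  # genes with a defined (nonzero) specificity row

    @property
    def clusters(self) -> list[str]:
        return list(self.values.columns)


def specificity(
    m: CountMatrix,
    a: ClusterAssignment,
    use_normalized: bool = True,
    norm_target: float = 2000,
) -> SpecificityMatrix:
    """s_{g,j} = cluster-mean expression / sum over clusters of the means."""
    groups = _cluster_groups(m, a)
    E = _values(m, use_normalized, norm_target)
    names = list(groups)
    means = np.stack([E[:, groups[n]].mean(axis=1) for n in names], axis=1)
    row_sum = means.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(row_sum[:, None] > 0, means / row_sum[:, None], 0.0)
    values = pd.DataFrame(s, index=pd.Index(m.gene_ids, name="gene"), columns=names)
    universe = [g for g, tot in zip(m.gene_ids, row_sum) if tot > 0]
    return SpecificityMatrix(values=values, universe=universe)
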