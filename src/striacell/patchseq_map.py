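"""Bootstrap assignment of PatchSeq transcriptomes to reference clusters.

Each query cell's observed score for cluster j is the sum over its
retained marker genes of (read count x specificity of the gene for j).
The null distribution comes from repeating the scoring B times with
random gene lists of equal size drawn without replacement from the
background universe; the empirical p-value uses the add-one convention

    p_j = (1 + #{b : score_j^(b) >= score_j^obs}) / (B + 1)

so p is never exactly zero. A cell is assigned to the cluster with the
smallest p when that p is below alpha, otherwise it is "undefined".
In the null draws, the cell's counts keep their order and the randomly
drawn genes contribute their specificities (i.e. gene identity is
randomized, the count vector is not).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

from .marker_score import SpecificityMatrix
from .matrix_io import CountMatrix

__all__ = [
    "MappingConfig",
    "MappingResult",
    "filter_query_genes",
    "map_cell",
    "map_dataset",
]


@dataclass
class MappingConfig:
    """Settings for specificity-weighted bootstrap mapping."""

    marker_panel: list[str]
    sd_min: float = 1.0
    n_bootstrap: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    #: gene universe the null gene-lists are drawn from. None (default)
    #: uses the retained query gene list itself, i.e. the null re-pairs the
    #: cell's counts with random permutations of the marker panel's
    #: specificities — the choice under which per-cluster p-values are
    #: uniform for a count-permuted cell. "universe" draws from all
    #: reference genes with defined specificity instead (anticonservative
    #: when marker specificities are more variable than background genes).
    background: list[str] | str | None = None

    def __post_init__(self) -> None:
        if self.n_bootstrap < 100:
            raise ValueError("need at least 100 bootstrap draws")


@dataclass
class MappingResult:
    """Per-cell mapping table plus the retained gene list and settings."""

    table: pd.DataFrame  # index cell: score_<j>..., p_<j>..., assigned, min_p, tie
    genes_used: list[str]
    clusters: list[str]
    n_bootstrap: int
    seed: int

    @property
    def n_assigned(self) -> int:
        return int((self.table["assigned"] != "undefined").sum())

    @property
    def n_undefined(self) -> int:
        return int((self.table["assigned"] == "undefined").sum())


def filter_query_genes(query: CountMatrix, panel, sd_min: float = 1.0, log_scale: bool = False) -> list[str]:
    """Keep panel genes whose standard deviation across the query dataset
    is at least ``sd_min`` (low-variance genes, SD < sd_min, are excluded).

    The SD is computed on raw read counts by default (``log_scale`` uses
    log2(x+1) values instead).
    """
    if query.n_cells < 2:
        raise ValueError("need at least 2 query cells")
    panel = [g for g in panel if g in set(query.gene_ids)]
    sub = query.subset(genes=panel)
    vals = sub.counts.astype(float)
    if log_scale:
        vals = np.log2(vals + 1)
    sd = vals.std(axis=1, ddof=0)
    kept = [g for g, s in zip(sub.gene_ids, sd) if s >= sd_min]
    if not kept:
        raise ValueError("no panel genes survive the variance filter")
    return kept


def _score_matrix(s: SpecificityMatrix, genes: list[str]) -> np.ndarray:
    missing = [g for g in genes if g not in s.values.index]
    if missing:
        raise KeyError(f"genes missing from specificity matrix: {missing[:5]}")
    return s.values.loc[genes].to_numpy()


def _resolve_background(cfg: MappingConfig, genes: list[str], s: SpecificityMatrix) -> list[str]:
    if cfg.background is None:
        return list(genes)
    if cfg.background == "universe":
        bg = list(s.universe)
    else:
        bg = list(cfg.background)
    if len(bg) < len(genes):
        raise ValueError("background universe smaller than the retained gene list")
    return bg


def _null_draws(rng: np.random.Generator, n_background: int, size: int, B: int) -> np.ndarray:
    """B gene-lists of the given size, drawn without replacement."""
    tiles = np.tile(np.arange(n_background), (B, 1))
    rng.permuted(tiles, axis=1, out=tiles)
    return tiles[:, :size]


def map_cell(
    x: pd.Series | np.ndarray,
    genes: list[str],
    s: SpecificityMatrix,
    cfg: MappingConfig,
    null_scores: np.ndarray | None = None,
) -> dict:
    """Map a single query cell given its counts on the retained genes.

    ``null_scores`` (B x clusters) may be supplied to reuse a precomputed
    null; otherwise the cell draws its own ``cfg.n_bootstrap`` gene lists
    seeded by ``cfg.seed``.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (len(genes),):
        raise ValueError("count vector does not match gene list")
    S = _score_matrix(s, genes)
    obs = x @ S
    clusters = s.clusters
    if null_scores is None:
        background = _resolve_background(cfg, genes, s)
        S_bg = _score_matrix(s, background)
        rng = np.random.default_rng(cfg.seed)
        draws = _null_draws(rng, len(background), len(genes), cfg.n_bootstrap)
        null_scores = np.einsum("g,bgk->bk", x, S_bg[draws])
    else:
        null_scores = np.asarray(null_scores)
        if null_scores.shape[1] != len(clusters):
            raise ValueError("null_scores cluster dimension mismatch")
    B = null_scores.shape[0]
    p = (1 + (null_scores >= obs[None, :] - 1e-12).sum(axis=0)) / (B + 1)
    min_p = p.min()
    ties = np.flatnonzero(p == min_p)
    if min_p < cfg.alpha and ties.size == 1:
        assigned = clusters[ties[0]]
        tie = False
    else:
        assigned = "undefined"
        tie = bool(min_p < cfg.alpha and ties.size > 1)
    return {
        "scores": dict(zip(clusters, obs)),
        "p": dict(zip(clusters, p)),
        "assigned": assigned,
        "min_p": float(min_p),
        "tie": tie,
    }


def enumerate_null_exactly(
    x: np.ndarray, background_specificity: np.ndarray, size: int
) -> np.ndarray:
    """Exhaustive null over all ordered draws of ``size`` genes from the
    background — the oracle for small universes (used in tests)."""
    n = background_specificity.shape[0]
    scores = []
    for idx in permutations(range(n), size):
        scores.append(x @ background_specificity[list(idx)])
    return np.asarray(scores)


def map_dataset(
    query: CountMatrix,
    s: SpecificityMatrix,
    cfg: MappingConfig,
) -> MappingResult:
    """Map every query cell with a shared gene filter and specificity matrix.

    The variance filter runs once across the query dataset; one shared set
    of B null gene-lists (seeded by ``cfg.seed``) is reused for all cells,
    which leaves each cell's marginal p-values unchanged in distribution.
    Deterministic given the seed.
    """
    clusters = s.clusters
    cols = (
        [f"score_{c}" for c in clusters]
        + [f"p_{c}" for c in clusters]
        + ["assigned", "min_p", "tie"]
    )
    if query.n_cells == 0:
        return MappingResult(
            table=pd.DataFrame(columns=cols),
            genes_used=[],
            clusters=clusters,
            n_bootstrap=cfg.n_bootstrap,
            seed=cfg.seed,
        )
    genes = filter_query_genes(query, cfg.marker_panel, sd_min=cfg.sd_min)
    background = _resolve_background(cfg, genes, s)
    S_bg = _score_matrix(s, background)
    rng = np.random.default_rng(cfg.seed)
    draws = _null_draws(rng, len(background), len(genes), cfg.n_bootstrap)
    X = query.subset(genes=genes).counts.T.astype(float)  # cells x genes
    rows = []
    # chunk the (B, genes, clusters) gather to bound memory
    chunk = max(1, int(2e7 // (len(genes) * len(clusters))))
    null_parts = []
    for start in range(0, cfg.n_bootstrap, chunk):
        null_parts.append(S_bg[draws[start : start + chunk]])
    for i, cid in enumerate(query.cell_ids):
        null_scores = np.concatenate(
            [np.einsum("g,bgk->bk", X[i], part) for part in null_parts]
        )
        res = map_cell(X[i], genes, s, cfg, null_scores=null_scores)
        rows.append(
            [res["scores"][c] for c in clusters]
            + [res["p"][c] for c in clusters]
            + [res["assigned"], res["min_p"], res["tie"]]
        )
    table = pd.DataFrame(rows, index=pd.Index(query.cell_ids, name="cell"), columns=cols)
    return MappingResult(
        table=table,
        genes_used=genes,
        clusters=clusters,
        n_bootstrap=cfg.n_bootstrap,
        seed=cfg.seed,
    )
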