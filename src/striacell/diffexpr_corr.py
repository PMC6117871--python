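"""Rank-based screens: Spearman correlation against a target gene within a
cluster, and Wilcoxon rank-sum differential expression between two cell
groups, both with Benjamini-Hochberg adjustment.

Significance conventions: a gene is called correlated when rho > 0.15 and
q < 0.05 (anti-correlated symmetric); differentially expressed when
q < 0.05 and |log2 fold change| >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import stats

from .matrix_io import CountMatrix

__all__ = [
    "CorrelationScreenResult",
    "DifferentialExpressionResult",
    "bh_adjust",
    "spearman_screen",
    "wilcoxon_de",
]


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min over the sorted tail of m * p_(j) / j, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Spearman screen
# ---------------------------------------------------------------------------

@dataclass
class CorrelationScreenResult:
    """Per-gene Spearman rho against the target gene, p, q and class."""

    table: pd.DataFrame  # index gene: rho, p, q, classification
    target_gene: str
    rho_thresh: float
    q_thresh: float

    def positive_genes(self) -> list[str]:
        return list(self.table.index[self.table["classification"] == "positive"])

    def negative_genes(self) -> list[str]:
        return list(self.table.index[self.table["classification"] == "negative"])


def _spearman_p_exact(target_ranks: np.ndarray, gene_vals: np.ndarray, rho_obs: float) -> float:
    """Exact permutation p for small n (permute the gene's values)."""
    n = target_ranks.size
    tr = target_ranks - target_ranks.mean()
    denom_t = np.sqrt((tr**2).sum())
    count = 0
    total = 0
    gr = stats.rankdata(gene_vals)
    for perm in permutations(gr):
        g = np.asarray(perm) - np.mean(perm)
        denom_g = np.sqrt((g**2).sum())
        r = 0.0 if denom_g == 0 or denom_t == 0 else float((tr * g).sum() / (denom_t * denom_g))
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman_screen(
    m: CountMatrix,
    cells,
    target_gene: str,
    rho_thresh: float = 0.15,
    q_thresh: float = 0.05,
    use_normalized: bool = True,
    norm_target: float = 2000,
) -> CorrelationScreenResult:
    """Spearman rho of every gene against ``target_gene`` over ``cells``.

    Average ranks handle ties; p-values use the t approximation (exact
    permutation for n <= 9). BH is applied over all tested genes; the
    target gene itself is reported but never classified.
    """
    sub = m.subset(cells=cells)
    if sub.n_cells < 5:
        raise ValueError("need at least 5 cells")
    if use_normalized:
        from .qc_normalize import normalize_total

        E = normalize_total(sub, target=norm_target, round_to_integer=False).to_numpy()
    else:
        E = sub.counts.astype(float)
    ti = sub.gene_index([target_gene])[0]
    target = E[ti]
    if np.all(target == target[0]):
        raise ValueError(f"target gene {target_gene!r} has zero variance")
    n = sub.n_cells
    tr = stats.rankdata(target)
    gr = stats.rankdata(E, axis=1)
    trc = tr - tr.mean()
    grc = gr - gr.mean(axis=1, keepdims=True)
    denom = np.sqrt((grc**2).sum(axis=1)) * np.sqrt((trc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(denom > 0, grc @ trc / denom, np.nan)
    rho = np.clip(rho, -1.0, 1.0)
    if n <= 9:
        p = np.array(
            [
                _spearman_p_exact(tr, E[g], rho[g]) if np.isfinite(rho[g]) else np.nan
                for g in range(sub.n_genes)
            ]
        )
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt((n - 2) / np.maximum(1 - rho**2, 1e-300))
        p = np.where(np.isfinite(rho), 2 * stats.t.sf(np.abs(t), df=n - 2), np.nan)
        p = np.minimum(p, 1.0)
    tested = np.isfinite(p)
    q = np.full_like(p, np.nan)
    q[tested] = bh_adjust(p[tested])
    classification = np.full(sub.n_genes, "ns", dtype=object)
    classification[(rho > rho_thresh) & (q < q_thresh)] = "positive"
    classification[(rho < -rho_thresh) & (q < q_thresh)] = "negative"
    classification[~tested] = "ns"
    classification[ti] = "target"
    table = pd.DataFrame(
        {"rho": rho, "p": p, "q": q, "classification": classification},
        index=pd.Index(sub.gene_ids, name="gene"),
    )
    return CorrelationScreenResult(
        table=table, target_gene=target_gene, rho_thresh=rho_thresh, q_thresh=q_thresh
    )


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum differential expression
# ---------------------------------------------------------------------------

@dataclass
class DifferentialExpressionResult:
    """Per-gene rank-sum p, q, log2 fold change and significance call."""

    table: pd.DataFrame  # index gene: p, q, log2fc, mean_a, mean_b, significant
    n_a: int
    n_b: int
    q_thresh: float
    fc_thresh: float
    pseudocount: float

    def significant_genes(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])

    def volcano_table(self) -> pd.DataFrame:
        t = self.table.copy()
        t["neg_log10_p"] = -np.log10(np.maximum(t["p"], 1e-300))
        return t[["log2fc", "neg_log10_p", "q", "significant"]]


def _ranksum_exact_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumerating group assignments.

    p = P(|U - n_a n_b / 2| >= |u_obs - n_a n_b / 2|) under the permutation
    null, which handles ties correctly.
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    na, nb = len(a), len(b)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    center = na * nb / 2
    stat_obs = abs(u_obs - center)
    n = na + nb
    count = 0
    total = 0
    for idx in combinations(range(n), na):
        u = ranks[list(idx)].sum() - na * (na + 1) / 2
        if abs(u - center) >= stat_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def _ranksum_normal_p(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Vectorized two-sided tie-corrected normal-approximation rank-sum p.

    A: (genes, n_a); B: (genes, n_b). Continuity correction of 0.5 applied.
    """
    na, nb = A.shape[1], B.shape[1]
    n = na + nb
    pooled = np.concatenate([A, B], axis=1)
    ranks = stats.rankdata(pooled, axis=1)
    u = ranks[:, :na].sum(axis=1) - na * (na + 1) / 2
    mu = na * nb / 2
    # tie correction to the variance
    var = np.empty(pooled.shape[0])
    for g in range(pooled.shape[0]):
        _, cnt = np.unique(pooled[g], return_counts=True)
        tie = (cnt**3 - cnt).sum()
        var[g] = na * nb / 12 * ((n + 1) - tie / (n * (n - 1)))
    z = np.zeros_like(var)
    nonzero = var > 0
    diff = np.abs(u - mu) - 0.5
    diff = np.maximum(diff, 0.0)
    z[nonzero] = diff[nonzero] / np.sqrt(var[nonzero])
    p = np.where(nonzero, 2 * stats.norm.sf(z), 1.0)
    return np.minimum(p, 1.0)


def wilcoxon_de(
    m: CountMatrix,
    group_a,
    group_b,
    q_thresh: float = 0.05,
    fc_thresh: float = 2.0,
    pseudocount: float = 0.01,
    use_normalized: bool = True,
    norm_target: float = 2000,
) -> DifferentialExpressionResult:
    """Per-gene two-sided Wilcoxon rank-sum test between two cell groups.

    Exact enumeration when n_a + n_b <= 10, tie-corrected normal
    approximation with continuity correction otherwise. Fold change is
    (mean_A + eps) / (mean_B + eps) on normalized expression; a gene is
    significant when q < ``q_thresh`` and |log2FC| >= log2(``fc_thresh``).
    Only genes detected in at least one cell of either group enter the BH
    family.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need at least 2 cells")
    sub = m.subset(cells=group_a + group_b)
    if use_normalized:
        from .qc_normalize import normalize_total

        E = normalize_total(sub, target=norm_target, round_to_integer=False).to_numpy()
    else:
        E = sub.counts.astype(float)
    na = len(group_a)
    A, B = E[:, :na], E[:, na:]
    detected = (E > 0).any(axis=1)
    if na + len(group_b) <= 10:
        p = np.array(
            [
                _ranksum_exact_p(A[g], B[g]) if detected[g] else np.nan
                for g in range(sub.n_genes)
            ]
        )
    else:
        p = np.full(sub.n_genes, np.nan)
        if detected.any():
            p[detected] = _ranksum_normal_p(A[detected], B[detected])
    q = np.full_like(p, np.nan)
    q[detected] = bh_adjust(p[detected])
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    lfc_min = np.log2(fc_thresh)
    significant = detected & (q < q_thresh) & (np.abs(log2fc) >= lfc_min)
    table = pd.DataFrame(
        {
            "p": p,
            "q": q,
            "log2fc": log2fc,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "significant": significant,
        },
        index=pd.Index(sub.gene_ids, name="gene"),
    )
    return DifferentialExpressionResult(
        table=table,
        n_a=na,
        n_b=len(group_b),
        q_thresh=q_thresh,
        fc_thresh=fc_thresh,
        pseudocount=pseudocount,
    )
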