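"""Within-cluster continuum analysis.

A rank-1 negative-binomial latent factor model captures the dominant
transcriptional gradient inside a cluster:

.. math::

    \\log \\mu_{ig} = \\log s_i + a_g + c_g^T f_i + w_g z_i,
    \\qquad y_{ig} \\sim \\mathrm{NB}(\\mu_{ig}, \\theta)

with library-size offsets ``log s_i`` (equal-total normalization), an
optional batch design ``f_i`` (one indicator column per plate except a
reference plate), per-gene intercepts/loadings and a shared dispersion
(variance = mu + mu^2/theta). The model is fit by block coordinate ascent
with step-halving, so the log-likelihood trace is non-decreasing; the cell
score z is standardized to mean 0 / variance 1 and its global sign is
chosen so the gene with the largest |w| loads positively.

The module also provides the gene-inclusion filter, negative-binomial
factor-gene association tests, the projection-based factor-ephys
association, and the Pearson screen of gene expression against 2-D
embedding coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special, stats

from .matrix_io import ClusterAssignment, CountMatrix, EmbeddingCoords

__all__ = [
    "CovariateDesign",
    "LatentFactorModel",
    "GradientScreenResult",
    "plate_design",
    "filter_genes_latent",
    "fit_latent_factor",
    "factor_gene_association",
    "factor_ephys_association",
    "gradient_tsne_screen",
]


@dataclass
class CovariateDesign:
    """Per-cell covariate matrix; plate indicators omit a reference plate."""

    matrix: np.ndarray  # cells x p (may be empty: p = 0)
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.size == 0:
            self.matrix = self.matrix.reshape(self.matrix.shape[0] if self.matrix.ndim else 0, 0)


def plate_design(plates, reference: str | None = None) -> CovariateDesign:
    """Build the batch design: one 0/1 column per plate except the reference
    (default: the first plate in sorted order)."""
    plates = np.asarray([str(p) for p in plates])
    levels = sorted(set(plates))
    if reference is None:
        reference = levels[0]
    cols = [lvl for lvl in levels if lvl != reference]
    mat = np.stack([(plates == lvl).astype(float) for lvl in cols], axis=1) if cols else np.zeros((len(plates), 0))
    return CovariateDesign(matrix=mat, names=[f"plate_{c}" for c in cols])


def filter_genes_latent(m: CountMatrix, min_reads: int = 3, min_cells: int = 8) -> list[str]:
    """Genes kept iff they have over ``min_reads`` reads in over
    ``min_cells`` cells (both strict)."""
    n_expressing = (m.counts > min_reads).sum(axis=1)
    return [g for g, n in zip(m.gene_ids, n_expressing) if n > min_cells]


# ---------------------------------------------------------------------------
# model fit
# ---------------------------------------------------------------------------

@dataclass
class LatentFactorModel:
    """Fitted rank-1 NB factor model."""

    z: pd.Series  # per-cell factor score, standardized
    w: pd.Series  # per-gene loading
    intercepts: pd.Series  # per-gene a_g
    covariate_coefs: pd.DataFrame  # genes x covariates
    theta: float
    offsets: pd.Series  # per-cell log s_i
    design: CovariateDesign
    loglik_trace: list[float]
    converged: bool
    degenerate: bool = False

    @property
    def cell_ids(self) -> list[str]:
        return list(self.z.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.w.index)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    mu = np.maximum(mu, 1e-12)
    return float(
        np.sum(
            special.gammaln(y + theta)
            - special.gammaln(theta)
            - special.gammaln(y + 1)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
    )


def fit_latent_factor(
    m: CountMatrix,
    design: CovariateDesign | None = None,
    theta_mode: str = "moment",
    tol: float = 1e-6,
    max_iter: int = 200,
    seed: int = 0,
) -> LatentFactorModel:
    """Fit the rank-1 NB latent factor by block coordinate ascent.

    Gene-wise IRLS steps (given z) alternate with per-cell Newton updates
    of z (given gene parameters); each step is backtracked until the
    log-likelihood does not decrease, so the trace is monotone. The shared
    dispersion is re-estimated by method of moments each outer iteration
    and the update is kept only if it does not lower the likelihood.
    Initialization is the first principal component of the log-normalized
    matrix; given the seed the fit is deterministic.
    """
    if m.n_genes < 2 or m.n_cells < 3:
        raise ValueError("need at least 2 genes and 3 cells")
    Y = m.counts.T.astype(float)  # cells x genes
    n, G = Y.shape
    F = design.matrix if design is not None else np.zeros((n, 0))
    if F.shape[0] != n:
        raise ValueError("design rows do not match cell count")
    p = F.shape[1]
    totals = Y.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("cells with zero counts; QC first")
    off = np.log(totals / totals.mean())  # equal-total normalization as offsets

    degenerate = bool(np.all(Y == Y[0]))

    # init: first PC of log-normalized expression
    L = np.log2(Y / totals[:, None] * totals.mean() + 1)
    Lc = L - L.mean(axis=0)
    if degenerate or np.allclose(Lc, 0):
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(n)
    else:
        _, _, vt = np.linalg.svd(Lc, full_matrices=False)
        z = Lc @ vt[0]
    z = (z - z.mean()) / max(z.std(), 1e-12)

    beta = np.zeros((G, 2 + p))  # columns: a_g, c_g..., w_g
    beta[:, 0] = np.log(np.maximum(Y.mean(axis=0), 1e-8))
    theta = 10.0

    def eta_of(beta_, z_):
        return off[:, None] + beta_[:, 0][None, :] + (F @ beta_[:, 1 : 1 + p].T if p else 0.0) + np.outer(z_, beta_[:, 1 + p])

    def ll_of(beta_, z_, theta_):
        return _nb_loglik(Y, np.exp(np.clip(eta_of(beta_, z_), -30, 30)), theta_)

    ll = ll_of(beta, z, theta)
    trace = [ll]
    converged = False

    if degenerate:
        beta[:, 1 + p] = 0.0
        return _pack_model(m, z, beta, p, theta, off, design, trace, True, True)

    X = np.empty((n, 2 + p))
    X[:, 0] = 1.0
    if p:
        X[:, 1 : 1 + p] = F

    for _ in range(max_iter):
        # ---- gene block: one IRLS step with backtracking -----------------
        X[:, 1 + p] = z
        eta = np.clip(eta_of(beta, z), -30, 30)
        mu = np.exp(eta)
        W = mu * theta / (theta + mu)  # cells x genes
        zwork = eta + (Y - mu) / np.maximum(mu, 1e-12)
        A = np.einsum("ni,ng,nj->gij", X, W, X)
        A += 1e-8 * np.eye(2 + p)[None]
        b = np.einsum("ni,ng->gi", X, W * zwork)
        beta_ls = np.linalg.solve(A, b[..., None])[..., 0]
        beta = _backtrack_genes(Y, X, off, beta, beta_ls, theta)

        # ---- cell block: one Newton step with backtracking ---------------
        w = beta[:, 1 + p]
        base = off[:, None] + beta[:, 0][None, :] + (F @ beta[:, 1 : 1 + p].T if p else 0.0)
        z = _backtrack_cells(Y, base, w, z, theta)

        # ---- identifiability: project the factor out of the covariate ----
        # span; the removed component is pushed into a_g / c_g, so the
        # likelihood is unchanged (exact reparameterization)
        if p:
            X0 = np.column_stack([np.ones(n), F])
            gamma, *_ = np.linalg.lstsq(X0, z, rcond=None)
            fitted = X0 @ gamma
            if np.abs(fitted).max() > 1e-12:
                w_cur = beta[:, 1 + p]
                beta[:, 0] += w_cur * gamma[0]
                beta[:, 1 : 1 + p] += np.outer(w_cur, gamma[1:])
                z = z - fitted

        # ---- rescale (exact reparameterization; likelihood unchanged) ----
        zm, zs = z.mean(), z.std()
        if zs > 1e-12:
            beta[:, 0] += beta[:, 1 + p] * zm
            beta[:, 1 + p] *= zs
            z = (z - zm) / zs

        # ---- dispersion: moment update with a likelihood guard -----------
        if theta_mode == "moment":
            mu = np.exp(np.clip(eta_of(beta, z), -30, 30))
            excess = np.sum((Y - mu) ** 2 - mu)
            if excess > 0:
                theta_new = float(np.sum(mu**2) / excess)
                theta_new = float(np.clip(theta_new, 1e-2, 1e6))
                if ll_of(beta, z, theta_new) >= ll_of(beta, z, theta):
                    theta = theta_new

        ll_new = ll_of(beta, z, theta)
        trace.append(max(ll_new, trace[-1]))
        if abs(ll_new - ll) <= tol * (abs(ll) + 1e-12):
            converged = True
            ll = ll_new
            break
        ll = ll_new

    # sign convention: the largest-|w| gene loads positively
    w = beta[:, 1 + p]
    if w.size and w[np.argmax(np.abs(w))] < 0:
        beta[:, 1 + p] = -w
        z = -z

    return _pack_model(m, z, beta, p, theta, off, design, trace, converged, False)


def _backtrack_genes(Y, X, off, beta, beta_target, theta) -> np.ndarray:
    """Move each gene's coefficients toward the IRLS solution, halving the
    step per gene until its likelihood does not decrease."""
    def gene_ll(bmat):
        eta = np.clip(off[:, None] + X @ bmat.T, -30, 30)
        mu = np.exp(eta)
        return (
            special.gammaln(Y + theta)
            - special.gammaln(theta)
            - special.gammaln(Y + 1)
            + theta * np.log(theta / (theta + mu))
            + Y * np.log(np.maximum(mu, 1e-12) / (theta + mu))
        ).sum(axis=0)

    ll0 = gene_ll(beta)
    step = np.ones(beta.shape[0])
    out = beta.copy()
    delta = beta_target - beta
    for _ in range(25):
        cand = beta + step[:, None] * delta
        llc = gene_ll(cand)
        ok = llc >= ll0 - 1e-10
        out[ok] = cand[ok]
        if ok.all():
            break
        step[~ok] *= 0.5
    else:
        pass
    # genes still failing keep their previous coefficients
    final_ok = gene_ll(out) >= ll0 - 1e-9
    out[~final_ok] = beta[~final_ok]
    return out


def _backtrack_cells(Y, base, w, z, theta) -> np.ndarray:
    """One damped Newton update of every cell score."""
    def cell_ll(z_):
        eta = np.clip(base + np.outer(z_, w), -30, 30)
        mu = np.exp(eta)
        return (theta * np.log(theta / (theta + mu)) + Y * np.log(np.maximum(mu, 1e-12) / (theta + mu))).sum(axis=1)

    ll0 = cell_ll(z)
    eta = np.clip(base + np.outer(z, w), -30, 30)
    mu = np.exp(eta)
    grad = ((Y - mu) * theta / (theta + mu)) @ w
    hess = -((mu * theta * (theta + Y)) / (theta + mu) ** 2) @ (w**2)
    step = np.where(hess < 0, -grad / hess, 0.0)
    step = np.clip(step, -3.0, 3.0)
    out = z.copy()
    t = np.ones_like(z)
    for _ in range(25):
        cand = z + t * step
        llc = cell_ll(cand)
        ok = llc >= ll0 - 1e-10
        out[ok] = cand[ok]
        if ok.all():
            break
        t[~ok] *= 0.5
    final_ok = cell_ll(out) >= ll0 - 1e-9
    out[~final_ok] = z[~final_ok]
    return out


def _pack_model(m, z, beta, p, theta, off, design, trace, converged, degenerate) -> LatentFactorModel:
    cov_names = design.names if design is not None and design.names else [f"cov{i}" for i in range(p)]
    return LatentFactorModel(
        z=pd.Series(z, index=pd.Index(m.cell_ids, name="cell")),
        w=pd.Series(beta[:, 1 + p], index=pd.Index(m.gene_ids, name="gene")),
        intercepts=pd.Series(beta[:, 0], index=m.gene_ids),
        covariate_coefs=pd.DataFrame(beta[:, 1 : 1 + p], index=m.gene_ids, columns=cov_names),
        theta=float(theta),
        offsets=pd.Series(off, index=m.cell_ids),
        design=design if design is not None else CovariateDesign(np.zeros((len(m.cell_ids), 0))),
        loglik_trace=list(trace),
        converged=converged,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# associations
# ---------------------------------------------------------------------------

def factor_gene_association(model: LatentFactorModel, gene_counts) -> dict:
    """NB regression of a gene's counts on the factor score z (with the
    model's offsets and batch covariates); returns the slope on the z
    scale, its standard error and p-value."""
    y = np.asarray(gene_counts, dtype=float)
    if y.shape != (len(model.cell_ids),):
        raise ValueError("gene counts must align with the model's cells")
    if np.all(y == 0):
        return {"coef": np.nan, "se": np.nan, "p": np.nan, "flag": "all_zero"}
    F = model.design.matrix
    X = np.column_stack([np.ones_like(y), *( [F] if F.shape[1] else [] ), model.z.to_numpy()])
    fam = sm.families.NegativeBinomial(alpha=1.0 / model.theta)
    try:
        res = sm.GLM(y, X, family=fam, offset=model.offsets.to_numpy()).fit()
    except Exception:
        return {"coef": np.nan, "se": np.nan, "p": np.nan, "flag": "fit_failed"}
    return {
        "coef": float(res.params[-1]),
        "se": float(res.bse[-1]),
        "p": float(res.pvalues[-1]),
        "flag": "",
    }


def factor_ephys_association(
    w: pd.Series,
    expression: pd.DataFrame,
    ephys_param,
    min_overlap: int = 10,
) -> dict:
    """Project query expression onto the factor gene weights and test a
    linear association with an electrophysiological parameter.

    projection_i = sum_g w_g * log(x_{ig} + 1); the parameter is regressed
    on the projection by ordinary least squares.
    """
    shared = [g for g in w.index if g in expression.index]
    if len(shared) < min_overlap:
        raise ValueError(f"gene overlap {len(shared)} below minimum {min_overlap}")
    X = np.log(expression.loc[shared].to_numpy().astype(float) + 1)
    proj = w.loc[shared].to_numpy() @ X
    y = np.asarray(ephys_param, dtype=float)
    if proj.std() == 0:
        return {"projection": proj, "slope": np.nan, "p": np.nan, "flag": "zero_variance"}
    lr = stats.linregress(proj, y)
    return {"projection": proj, "slope": float(lr.slope), "p": float(lr.pvalue), "flag": ""}


# ---------------------------------------------------------------------------
# embedding-coordinate gradient screen
# ---------------------------------------------------------------------------

@dataclass
class GradientScreenResult:
    """Per-gene Pearson r against embedding x and y, with inclusion flags."""

    table: pd.DataFrame  # index gene: included, r_x, r_y, cluster_posfrac, dataset_detfrac
    cluster: str


def gradient_tsne_screen(
    m: CountMatrix,
    a: ClusterAssignment,
    cluster: str,
    coords: EmbeddingCoords,
    min_cluster_frac: float = 0.1,
    max_dataset_frac: float = 0.7,
    log_transform: bool = True,
    use_normalized: bool = True,
    norm_target: float = 2000,
) -> GradientScreenResult:
    """Correlate each gene's expression with the embedding coordinates
    inside one cluster.

    Genes are screened only if detected (> 0) in more than
    ``min_cluster_frac`` of the cluster's cells and in less than
    ``max_dataset_frac`` of all cells (both strict).
    """
    cells = a.cells_of(cluster)
    if len(cells) < 3:
        raise ValueError(f"cluster {cluster!r} has fewer than 3 cells")
    xy = coords.array_for(cells)
    sub = m.subset(cells=cells)
    cluster_frac = (sub.counts > 0).mean(axis=1)
    dataset_frac = (m.counts > 0).mean(axis=1)
    included = (cluster_frac > min_cluster_frac) & (dataset_frac < max_dataset_frac)
    if use_normalized:
        from .qc_normalize import normalize_total

        E = normalize_total(sub, target=norm_target, round_to_integer=False).to_numpy()
    else:
        E = sub.counts.astype(float)
    if log_transform:
        E = np.log2(E + 1)
    r_x = np.full(m.n_genes, np.nan)
    r_y = np.full(m.n_genes, np.nan)
    idx = np.flatnonzero(included)
    if idx.size:
        Ec = E[idx] - E[idx].mean(axis=1, keepdims=True)
        sd = Ec.std(axis=1)
        for col, out in ((0, r_x), (1, r_y)):
            c = xy[:, col] - xy[:, col].mean()
            csd = c.std()
            with np.errstate(divide="ignore", invalid="ignore"):
                r = np.where(
                    (sd > 0) & (csd > 0),
                    (Ec @ c) / (len(cells) * sd * csd),
                    np.nan,
                )
            out[idx] = np.clip(r, -1, 1)
    table = pd.DataFrame(
        {
            "included": included,
            "r_x": r_x,
            "r_y": r_y,
            "cluster_posfrac": cluster_frac,
            "dataset_detfrac": dataset_frac,
        },
        index=pd.Index(m.gene_ids, name="gene"),
    )
    return GradientScreenResult(table=table, cluster=cluster)
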