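"""Cell/gene quality-control cascades and total-count normalization.

Three QC schemes are implemented, matching the three data sources of the
study design:

* ``qc_dataset_a`` — deep single-cell dataset: keep cells with more than
  1,500 molecules; drop genes with fewer than 25 molecules overall.
* ``qc_dataset_b`` — large UMI dataset: drop cells below 800 UMIs, with a
  total-UMI / genes-detected ratio below 1.2, or expressing any
  non-neuronal marker.
* ``qc_patchseq`` — PatchSeq transcriptomes: keep cells with more than
  2,000 molecules OR more than 1,000 distinct genes, counted after
  removing mitochondrial and rRNA genes.

All inequalities are implemented exactly as stated (strict where the rule
says "more than" / "less than"); the boundary semantics are pinned by the
test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .matrix_io import CountMatrix

__all__ = [
    "FailReason",
    "GeneListConfig",
    "QcReport",
    "qc_dataset_a",
    "qc_dataset_b",
    "qc_patchseq",
    "normalize_total",
    "drop_gene_lists",
    "apply_qc",
]

#: non-neuronal contamination markers (oligodendrocyte, astrocyte,
#: microglia, fibroblast and endothelial genes)
DEFAULT_NON_NEURONAL = ["Mog", "Mbp", "Aqp4", "Gja1", "C1qc", "Aif1", "Fn1", "Cldn5"]


class FailReason(str, Enum):
    LOW_MOLECULES = "low_molecules"
    LOW_RATIO = "low_ratio"
    NO_GENES = "no_genes_detected"
    NON_NEURONAL = "non_neuronal"
    LOW_GENE_TOTAL = "low_gene_total"


@dataclass
class GeneListConfig:
    """Configurable gene lists consumed by the QC and filtering steps."""

    non_neuronal_markers: list[str] = field(default_factory=lambda: list(DEFAULT_NON_NEURONAL))
    activity_genes: list[str] = field(default_factory=list)
    mito_genes: list[str] = field(default_factory=list)
    rrna_genes: list[str] = field(default_factory=list)
    exclude_cells: list[str] = field(default_factory=list)


@dataclass
class QcReport:
    """Per-cell and per-gene QC tables.

    ``cells`` has columns total, genes_detected, ratio, pass_qc and reasons
    (semicolon-joined reason codes); ``genes`` has columns total and
    pass_qc. A cell/gene passes iff it accrued no failing reason.
    """

    cells: pd.DataFrame
    genes: pd.DataFrame
    scheme: str

    def passing_cells(self) -> list[str]:
        return list(self.cells.index[self.cells["pass_qc"]])

    def passing_genes(self) -> list[str]:
        return list(self.genes.index[self.genes["pass_qc"]])


def _base_cell_table(m: CountMatrix) -> pd.DataFrame:
    totals = m.cell_totals()
    genes_detected = (m.counts > 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(genes_detected > 0, totals / np.maximum(genes_detected, 1), np.nan)
    return pd.DataFrame(
        {"total": totals, "genes_detected": genes_detected, "ratio": ratio},
        index=pd.Index(m.cell_ids, name="cell"),
    )


def _finish(cells: pd.DataFrame, reasons: list[list[str]], genes: pd.DataFrame, scheme: str) -> QcReport:
    cells = cells.copy()
    cells["reasons"] = [";".join(r) for r in reasons]
    cells["pass_qc"] = [len(r) == 0 for r in reasons]
    return QcReport(cells=cells, genes=genes, scheme=scheme)


def qc_dataset_a(m: CountMatrix, min_molecules: int = 1500, min_gene_total: int = 25) -> QcReport:
    """Deep-dataset QC: cell total strictly above ``min_molecules``; gene
    kept iff its dataset-wide total is at least ``min_gene_total``."""
    cells = _base_cell_table(m)
    reasons = [
        [] if t > min_molecules else [FailReason.LOW_MOLECULES.value]
        for t in cells["total"]
    ]
    gene_tot = m.gene_totals()
    genes = pd.DataFrame(
        {"total": gene_tot, "pass_qc": gene_tot >= min_gene_total},
        index=pd.Index(m.gene_ids, name="gene"),
    )
    return _finish(cells, reasons, genes, "dataset_a")


def qc_dataset_b(
    m: CountMatrix,
    cfg: GeneListConfig | None = None,
    min_umi: int = 800,
    min_ratio: float = 1.2,
) -> QcReport:
    """UMI-dataset QC: low total, low UMI/genes ratio, or any expression of
    a non-neuronal marker each fail the cell.

    The genes-detected denominator is computed on the full gene set, before
    any marker removal.
    """
    cfg = cfg or GeneListConfig()
    cells = _base_cell_table(m)
    present = [g for g in cfg.non_neuronal_markers if g in m.gene_ids]
    marker_pos = (
        (m.counts[m.gene_index(present)] > 0).any(axis=0)
        if present
        else np.zeros(m.n_cells, dtype=bool)
    )
    reasons: list[list[str]] = []
    for i, (t, g, r) in enumerate(zip(cells["total"], cells["genes_detected"], cells["ratio"])):
        rs = []
        if t < min_umi:
            rs.append(FailReason.LOW_MOLECULES.value)
        if g == 0:
            rs.append(FailReason.NO_GENES.value)
        elif r < min_ratio:
            rs.append(FailReason.LOW_RATIO.value)
        if marker_pos[i]:
            rs.append(FailReason.NON_NEURONAL.value)
        reasons.append(rs)
    genes = pd.DataFrame(
        {"total": m.gene_totals(), "pass_qc": True},
        index=pd.Index(m.gene_ids, name="gene"),
    )
    return _finish(cells, reasons, genes, "dataset_b")


def qc_patchseq(
    m: CountMatrix,
    cfg: GeneListConfig | None = None,
    min_molecules: int = 2000,
    min_genes: int = 1000,
) -> QcReport:
    """PatchSeq QC: pass iff molecules > 2,000 OR distinct genes > 1,000,
    both tallied after excluding mitochondrial and rRNA genes."""
    cfg = cfg or GeneListConfig()
    drop = set(cfg.mito_genes) | set(cfg.rrna_genes)
    keep_mask = np.asarray([g not in drop for g in m.gene_ids])
    counts = m.counts[keep_mask]
    totals = counts.sum(axis=0)
    genes_detected = (counts > 0).sum(axis=0)
    cells = pd.DataFrame(
        {
            "total": totals,
            "genes_detected": genes_detected,
            "ratio": np.where(genes_detected > 0, totals / np.maximum(genes_detected, 1), np.nan),
        },
        index=pd.Index(m.cell_ids, name="cell"),
    )
    reasons = [
        [] if (t > min_molecules or g > min_genes) else [FailReason.LOW_MOLECULES.value]
        for t, g in zip(totals, genes_detected)
    ]
    genes = pd.DataFrame(
        {"total": m.gene_totals(), "pass_qc": True},
        index=pd.Index(m.gene_ids, name="gene"),
    )
    return _finish(cells, reasons, genes, "patchseq")


def normalize_total(m: CountMatrix, target: float = 2000, round_to_integer: bool = True) -> pd.DataFrame:
    """Scale every cell to ``target`` total counts.

    Returns a genes x cells DataFrame of real values; with
    ``round_to_integer`` entries are rounded half-away-from-zero (the
    convention chosen for "closest integer" on this non-negative data).
    Cells with zero total are rejected — run QC first.
    """
    totals = m.cell_totals().astype(float)
    if np.any(totals == 0):
        bad = [m.cell_ids[i] for i in np.flatnonzero(totals == 0)][:5]
        raise ValueError(f"cells with zero total counts (QC first): {bad}")
    scaled = m.counts * (target / totals)[None, :]
    if round_to_integer:
        scaled = np.sign(scaled) * np.floor(np.abs(scaled) + 0.5)
    return pd.DataFrame(scaled, index=m.gene_ids, columns=m.cell_ids)


def drop_gene_lists(m: CountMatrix, genes_to_drop) -> CountMatrix:
    """Remove the given gene symbols; absent symbols are ignored with a warning."""
    drop = set(genes_to_drop)
    absent = sorted(drop - set(m.gene_ids))
    if absent:
        warnings.warn(f"{len(absent)} symbols not in matrix, ignored: {absent[:5]}", stacklevel=2)
    keep = np.asarray([g not in drop for g in m.gene_ids])
    return m.subset(genes=keep)


def apply_qc(m: CountMatrix, report: QcReport) -> CountMatrix:
    """Subset a matrix to the cells and genes passing a QC report."""
    return m.subset(cells=report.passing_cells(), genes=report.passing_genes())
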