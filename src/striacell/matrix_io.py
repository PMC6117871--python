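"""Count-matrix containers and tabular/sparse I/O.

The canonical in-memory object is :class:`CountMatrix`, a genes x cells
integer UMI matrix with gene symbols, cell identifiers and a free-form
per-cell metadata table. Readers accept either a dense TSV or a Matrix
Market coordinate file with ``genes.tsv`` / ``barcodes.tsv`` companions;
both produce identical matrices for the same data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "CountMatrix",
    "ClusterAssignment",
    "EmbeddingCoords",
    "FormatError",
    "read_count_matrix",
    "read_cluster_table",
    "read_coords",
    "write_count_matrix",
    "write_cluster_table",
    "write_coords",
    "write_table",
]

#: significant digits used when writing real-valued tables
_REAL_FMT = "%.12g"


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


@dataclass
class CountMatrix:
    """Genes x cells UMI count matrix with identifiers and cell metadata.

    Parameters
    ----------
    counts
        Non-negative integer array, shape ``(n_genes, n_cells)``.
    gene_ids
        Unique gene symbols, one per row.
    cell_ids
        Unique cell identifiers, one per column.
    cell_meta
        Optional per-cell table indexed by ``cell_ids`` (plate, dataset,
        age group, ...). Created empty when omitted.
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D genes x cells array")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell_ids")
        if np.issubdtype(self.counts.dtype, np.floating):
            if not np.all(np.isfinite(self.counts)):
                raise ValueError("non-finite counts")
            if not np.all(self.counts == np.round(self.counts)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell"))
        else:
            self.cell_meta = pd.DataFrame(self.cell_meta)
            if list(self.cell_meta.index) != self.cell_ids:
                self.cell_meta = self.cell_meta.reindex(self.cell_ids)
            self.cell_meta.index.name = "cell"

    # -- basic geometry ---------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        out = []
        for g in genes:
            if g not in lookup:
                raise KeyError(f"unknown gene id: {g!r}")
            out.append(lookup[g])
        return np.asarray(out, dtype=np.intp)

    def cell_index(self, cells: Iterable[str]) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        out = []
        for c in cells:
            if c not in lookup:
                raise KeyError(f"unknown cell id: {c!r}")
            out.append(lookup[c])
        return np.asarray(out, dtype=np.intp)

    def subset(self, cells=None, genes=None) -> "CountMatrix":
        """Return the submatrix restricted to the given cells and/or genes.

        Either argument may be a sequence of ids (order preserved as given)
        or a boolean mask over the current order; ``None`` keeps everything.
        """
        gi = _resolve_axis(genes, self.gene_ids, self.gene_index)
        ci = _resolve_axis(cells, self.cell_ids, self.cell_index)
        counts = self.counts[np.ix_(gi, ci)] if self.counts.size else self.counts[gi][:, ci]
        return CountMatrix(
            counts=counts,
            gene_ids=[self.gene_ids[i] for i in gi],
            cell_ids=[self.cell_ids[i] for i in ci],
            cell_meta=self.cell_meta.iloc[ci].copy(),
        )

    def cell_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def gene_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.cell_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.cell_ids == other.cell_ids
            and np.array_equal(self.counts, other.counts)
        )


def _resolve_axis(sel, ids: list[str], index_fn) -> np.ndarray:
    if sel is None:
        return np.arange(len(ids), dtype=np.intp)
    arr = np.asarray(sel)
    if arr.dtype == bool:
        if arr.shape != (len(ids),):
            raise ValueError("boolean mask length mismatch")
        return np.flatnonzero(arr)
    return index_fn(list(sel))


@dataclass
class ClusterAssignment:
    """cell id -> cluster label, with an optional merge history."""

    labels: dict[str, str]
    hierarchy: list[dict[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = {str(k): str(v) for k, v in self.labels.items()}

    @property
    def cluster_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self.labels.values():
            seen.setdefault(v, None)
        return list(seen)

    def cells_of(self, cluster: str) -> list[str]:
        return [c for c, lbl in self.labels.items() if lbl == cluster]

    def labels_for(self, cell_ids: Sequence[str]) -> np.ndarray:
        missing = [c for c in cell_ids if c not in self.labels]
        if missing:
            raise KeyError(f"cells without cluster label: {missing[:5]}")
        return np.asarray([self.labels[c] for c in cell_ids])

    def validate_against(self, m: CountMatrix) -> list[str]:
        """Return (and warn about) labelled cells absent from `m`."""
        cells = set(m.cell_ids)
        orphans = [c for c in self.labels if c not in cells]
        if orphans:
            warnings.warn(
                f"{len(orphans)} assigned cells absent from matrix: {orphans[:5]}",
                stacklevel=2,
            )
        return orphans


@dataclass
class EmbeddingCoords:
    """cell id -> (x, y) coordinates of a 2-D embedding (e.g. tSNE)."""

    coords: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        clean: dict[str, tuple[float, float]] = {}
        for cid, (x, y) in self.coords.items():
            x, y = float(x), float(y)
            if not (np.isfinite(x) and np.isfinite(y)):
                raise ValueError(f"non-finite coordinates for cell {cid!r}")
            clean[str(cid)] = (x, y)
        self.coords = clean

    def array_for(self, cell_ids: Sequence[str]) -> np.ndarray:
        missing = [c for c in cell_ids if c not in self.coords]
        if missing:
            raise KeyError(f"cells without coordinates: {missing[:5]}")
        return np.asarray([self.coords[c] for c in cell_ids], dtype=float)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_count_matrix(path, genes_in_rows: bool = True, meta_path=None) -> CountMatrix:
    """Read a count matrix from dense TSV or Matrix Market triplet format.

    ``path`` is either a ``.tsv`` file (first column gene ids, header row of
    cell ids) or a ``.mtx`` file whose directory holds ``genes.tsv`` and
    ``barcodes.tsv`` companion files (one id per line). Set
    ``genes_in_rows=False`` if the stored matrix is cells x genes.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        m = _read_mtx(path)
    else:
        m = _read_dense(path)
    if not genes_in_rows:
        m = CountMatrix(m.counts.T, gene_ids=m.cell_ids, cell_ids=m.gene_ids)
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype={0: str})
        meta.index = meta.index.astype(str)
        m.cell_meta = meta.reindex(m.cell_ids)
        m.cell_meta.index.name = "cell"
    return m


def _read_dense(path: Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = df.to_numpy()
    if arr.size and (not np.issubdtype(arr.dtype, np.number)):
        raise FormatError(f"{path}: non-numeric entries in dense matrix")
    return CountMatrix(arr, gene_ids=list(df.index.astype(str)), cell_ids=list(df.columns.astype(str)))


def _read_mtx(path: Path) -> CountMatrix:
    genes_file = path.parent / "genes.tsv"
    barcodes_file = path.parent / "barcodes.tsv"
    for f in (genes_file, barcodes_file):
        if not f.exists():
            raise FormatError(f"companion file missing: {f}")
    gene_ids = genes_file.read_text().split()
    cell_ids = barcodes_file.read_text().split()
    try:
        mat = scipy.io.mmread(path)
    except Exception as exc:  # malformed header/triplets
        raise FormatError(f"{path}: {exc}") from exc
    mat = scipy.sparse.coo_matrix(mat)
    if mat.shape != (len(gene_ids), len(cell_ids)):
        raise FormatError(
            f"{path}: matrix shape {mat.shape} does not match id files "
            f"({len(gene_ids)} genes, {len(cell_ids)} barcodes)"
        )
    return CountMatrix(mat.toarray(), gene_ids=gene_ids, cell_ids=cell_ids)


def write_count_matrix(m: CountMatrix, path, sparse: bool | None = None) -> None:
    """Write dense TSV (``.tsv``) or Matrix Market + companions (``.mtx``)."""
    path = Path(path)
    if sparse is None:
        sparse = path.suffix == ".mtx"
    if sparse:
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(m.counts))
        (path.parent / "genes.tsv").write_text("\n".join(m.gene_ids) + "\n")
        (path.parent / "barcodes.tsv").write_text("\n".join(m.cell_ids) + "\n")
    else:
        m.to_frame().to_csv(path, sep="\t", index_label="gene")


def read_cluster_table(path) -> ClusterAssignment:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need (cell, label) columns")
    return ClusterAssignment(labels=dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def write_cluster_table(a: ClusterAssignment, path) -> None:
    pd.DataFrame(
        {"cell": list(a.labels), "cluster": list(a.labels.values())}
    ).to_csv(path, sep="\t", index=False)


def read_coords(path) -> EmbeddingCoords:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: need (cell, x, y) columns")
    try:
        x = df.iloc[:, 1].astype(float)
        y = df.iloc[:, 2].astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric coordinates") from exc
    return EmbeddingCoords(
        coords={str(c): (xi, yi) for c, xi, yi in zip(df.iloc[:, 0], x, y)}
    )


def write_coords(e: EmbeddingCoords, path) -> None:
    rows = [(c, x, y) for c, (x, y) in e.coords.items()]
    pd.DataFrame(rows, columns=["cell", "x", "y"]).to_csv(
        path, sep="\t", index=False, float_format=_REAL_FMT
    )


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    """Write any result table as TSV at 12 significant digits."""
    pd.DataFrame(df).to_csv(path, sep="\t", index=index, float_format=_REAL_FMT)
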