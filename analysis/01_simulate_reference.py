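#!/usr/bin/env python
"""Generate the synthetic reference dataset used throughout the analysis.

Emulates a striatal-interneuron UMI dataset: 7 clusters x 100 cells, 500
genes, cluster-exclusive markers at 4-fold enrichment, a planted rank-1
expression gradient inside cluster C1 (the Pvalb/Pthlh-like continuum),
two plates with mild batch effects, and ~2,000-count libraries. Downstream
scripts re-create the identical dataset from the same seed; this script
records its shape and writes the ground-truth tables.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _common import RESULTS, SEED, get_reference  # noqa: E402

from striacell.matrix_io import write_cluster_table, write_table  # noqa: E402


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    m, truth = get_reference()
    totals = m.cell_totals()
    summary = {
        "seed": SEED,
        "n_genes": m.n_genes,
        "n_cells": m.n_cells,
        "clusters": {c: len(truth.assignment.cells_of(c)) for c in truth.assignment.cluster_names},
        "median_library_size": float(pd.Series(totals).median()),
        "gradient_cluster": "C1",
        "n_gradient_genes": int(len(truth.w_star)),
        "plates": sorted(set(truth.plate_labels)),
    }
    write_cluster_table(truth.assignment, RESULTS / "01_true_clusters.tsv")
    write_table(truth.w_star.rename("w_star").to_frame(), RESULTS / "01_gradient_loadings.tsv")
    (RESULTS / "01_reference_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print("Reference dataset:", summary["n_genes"], "genes x", summary["n_cells"], "cells")
    print("Cluster sizes:", summary["clusters"])
    print("Median library size:", summary["median_library_size"], "UMIs")
    print(f"Gradient: {summary['n_gradient_genes']} genes in cluster C1")


if __name__ == "__main__":
    main()
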