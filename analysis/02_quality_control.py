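#!/usr/bin/env python
"""Apply the UMI-dataset QC cascade to a degraded copy of the reference.

The clean reference passes the rules almost entirely; to show the filters
at work this script adds low-depth cells (library thinned to ~20%) and
glial contamination (non-neuronal marker molecules), which the cascade
flags and removes before total-count normalization.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
from _common import RESULTS, get_reference  # noqa: E402

from striacell.matrix_io import CountMatrix, write_table  # noqa: E402
from striacell.qc_normalize import GeneListConfig, normalize_total, qc_dataset_b  # noqa: E402


def main() -> None:
    m, _ = get_reference()
    rng = np.random.default_rng(7)

    counts = np.vstack([m.counts.copy(), np.zeros((2, m.n_cells), dtype=m.counts.dtype)])
    genes = list(m.gene_ids) + ["Mog", "Aqp4"]
    shallow = rng.choice(m.n_cells, 30, replace=False)
    counts[:, shallow] = rng.binomial(counts[:, shallow], 0.2)
    glial = rng.choice(np.setdiff1d(np.arange(m.n_cells), shallow), 20, replace=False)
    counts[-2, glial[:10]] = rng.poisson(3, 10) + 1
    counts[-1, glial[10:]] = rng.poisson(3, 10) + 1
    degraded = CountMatrix(counts, genes, m.cell_ids)

    rep = qc_dataset_b(degraded, GeneListConfig())
    failed = rep.cells[~rep.cells["pass_qc"]]
    reason_counts = failed["reasons"].str.split(";").explode().value_counts()

    write_table(rep.cells, RESULTS / "02_qc_cells.tsv")
    print(f"Degraded matrix: {degraded.n_cells} cells; {len(failed)} fail QC")
    print("Failure reasons:")
    for reason, k in reason_counts.items():
        print(f"  {reason}: {k}")
    kept = degraded.subset(cells=rep.passing_cells())
    norm = normalize_total(kept, target=2000)
    print(f"Kept {kept.n_cells} cells; rounded totals in "
          f"[{norm.sum(axis=0).min():.0f}, {norm.sum(axis=0).max():.0f}]")


if __name__ == "__main__":
    main()
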