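#!/usr/bin/env python
"""Cluster the reference, assess robustness, and derive marker panels.

Runs variable-gene selection (log CV vs log mean), the stand-in
agglomerative clustering at k = 7, the random-forest robustness
assessment (80/20 split), the cluster-mean dendrogram, and the marker
enrichment ranking (powers 0, 0.5, 1). Reports how well the pipeline
recovers the planted structure.
"""

import sys
from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score

sys.path.insert(0, str(Path(__file__).parent))
from _common import RESULTS, get_reference  # noqa: E402

from striacell.cluster_scaffold import (  # noqa: E402
    assess_robustness,
    cluster_cells,
    cluster_mean_dendrogram,
    linkage_to_newick,
    select_variable_genes,
)
from striacell.marker_score import enrichment_scores, top_markers  # noqa: E402
from striacell.matrix_io import write_cluster_table, write_table  # noqa: E402


def main() -> None:
    m, truth = get_reference()
    fit = select_variable_genes(m, n=150)
    assignment = cluster_cells(m, fit, k=7)
    ari = adjusted_rand_score(
        truth.assignment.labels_for(m.cell_ids), assignment.labels_for(m.cell_ids)
    )
    print(f"Variable genes: top {len(fit.selected)} by CV residual "
          f"(fit slope {fit.slope:.3f})")
    print(f"Clustering at k=7: ARI vs planted clusters = {ari:.3f}")

    rob = assess_robustness(m, assignment, seed=0)
    print(f"Robustness (held-out RF): mean precision {100 * rob.mean_precision:.1f}%, "
          f"mean recall {100 * rob.mean_recall:.1f}%")

    Z, names = cluster_mean_dendrogram(m, assignment)
    (RESULTS / "03_cluster_dendrogram.nwk").write_text(linkage_to_newick(Z, names) + "\n")

    scores = enrichment_scores(m, assignment)
    top = top_markers(scores, 10)
    # match each inferred cluster to the planted cluster holding the
    # majority of its cells, to score marker recovery
    true_labels = dict(truth.assignment.labels)
    match = {
        c: pd.Series([true_labels[cell] for cell in assignment.cells_of(c)]).mode()[0]
        for c in assignment.cluster_names
    }
    rows = []
    for cluster in top:
        planted = set(truth.marker_genes.get(match[cluster], []))
        for power, genes in top[cluster]["per_power"].items():
            rows.append({
                "cluster": cluster,
                "power": power,
                "top10": ",".join(genes),
                "planted_hits": sum(g in planted for g in genes) if planted else None,
            })
    table = pd.DataFrame(rows)
    write_table(table, RESULTS / "03_top_markers.tsv", index=False)
    write_cluster_table(assignment, RESULTS / "03_cluster_assignment.tsv")
    hits = table[table["power"] == 1.0]["planted_hits"]
    print(f"Marker ranking (power 1): median {hits.median():.0f}/10 planted markers "
          f"in each cluster's top-10")


if __name__ == "__main__":
    main()
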