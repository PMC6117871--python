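#!/usr/bin/env python
"""Map synthetic PatchSeq cells to the reference and analyze their
intrinsic electrophysiology.

PatchSeq transcriptomes (drawn from the reference cluster profiles at
5,000-count depth) go through the PatchSeq QC, the specificity-weighted
bootstrap assignment (B = 1,000), and the accuracy is scored against the
known labels. Current-clamp sweep sets for the five firing archetypes are
simulated, the intrinsic parameters extracted, low-quality cells excluded
by the half-width/amplitude rule, and the feature table summarized by PCA
and fast-spiking vs regular-spiking pairwise tests.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import RESULTS, get_reference  # noqa: E402

from striacell.ephys_features import (  # noqa: E402
    ephys_pca,
    exclude_low_quality,
    extract_feature_table,
    pairwise_compare,
)
from striacell.marker_score import enrichment_scores, specificity, top_markers  # noqa: E402
from striacell.matrix_io import write_table  # noqa: E402
from striacell.patchseq_map import MappingConfig, map_dataset  # noqa: E402
from striacell.qc_normalize import qc_patchseq  # noqa: E402
from striacell.synthetic_data import (  # noqa: E402
    ARCHETYPES,
    archetype_config,
    simulate_patchseq_cells,
    simulate_sweeps,
)


def main() -> None:
    m, truth = get_reference()
    s = specificity(m, truth.assignment)
    top = top_markers(enrichment_scores(m, truth.assignment), 10)
    panel = sorted({g for c in top for g in top[c]["union"]})

    query, qlab = simulate_patchseq_cells(m, truth.assignment, 98, depth=5000, seed=9)
    qc = qc_patchseq(query)
    query = query.subset(cells=qc.passing_cells())
    print(f"PatchSeq QC: {query.n_cells}/98 cells pass")
    res = map_dataset(query, s, MappingConfig(marker_panel=panel, n_bootstrap=1000, seed=10))
    assigned = res.table[res.table["assigned"] != "undefined"]
    acc = (assigned["assigned"] == qlab.loc[assigned.index]).mean()
    write_table(res.table, RESULTS / "06_patchseq_mapping.tsv")
    print(f"Mapping (panel of {len(panel)} markers, {len(res.genes_used)} retained, "
          f"B = 1000): {len(assigned)} assigned / {res.n_undefined} undefined; "
          f"accuracy among assigned {100 * acc:.1f}%")

    # intrinsic electrophysiology of the five archetypes, 20 cells each
    sets = []
    labels = {}
    for name in ARCHETYPES:
        for seed in range(20):
            ss, _ = simulate_sweeps(archetype_config(name, seed=seed))
            ss.cell_id = f"{name}_{seed}"
            labels[ss.cell_id] = name
            sets.append(ss)
    feats = extract_feature_table(sets)
    kept, report = exclude_low_quality(feats)
    print(f"Ephys: {len(feats)} simulated cells, {int(report['excluded'].sum())} "
          f"excluded by the half-width/amplitude rule")
    write_table(kept, RESULTS / "06_ephys_features.tsv")

    pca = ephys_pca(kept)
    ve = pca["variance_explained"]
    print(f"PCA on {pca['scores'].shape[1]} parameters: PC1 {100 * ve[0]:.0f}%, "
          f"PC2 {100 * ve[1]:.0f}% of variance")

    fs = [c for c in kept.index if labels[c] == "fast_spiking"]
    rs = [c for c in kept.index if labels[c] == "regular"]
    cmp_ = pairwise_compare(kept, fs, rs)
    sig = cmp_[cmp_["q"] < 0.05]
    write_table(cmp_, RESULTS / "06_fs_vs_regular_tests.tsv")
    print(f"Fast-spiking vs regular: {len(sig)}/{len(cmp_)} parameters differ at "
          f"q < 0.05 (most extreme: {cmp_['q'].astype(float).idxmin()})")


if __name__ == "__main__":
    main()
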