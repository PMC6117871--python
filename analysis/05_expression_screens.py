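#!/usr/bin/env python
"""Run the two expression screens on the reference.

Differential expression: Wilcoxon rank-sum between clusters C1 and C2
with BH adjustment, called at q < 0.05 and fold change > 2 — the planted
markers of the two clusters should dominate the significant set.
Correlation screen: Spearman rho of every gene against the strongest
planted gradient gene inside C1 (rho > 0.15, q < 0.05), mirroring a
Pvalb-style co-expression screen.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import RESULTS, get_reference  # noqa: E402

from striacell.diffexpr_corr import spearman_screen, wilcoxon_de  # noqa: E402
from striacell.matrix_io import write_table  # noqa: E402


def main() -> None:
    m, truth = get_reference()
    a = truth.assignment
    de = wilcoxon_de(m, a.cells_of("C1"), a.cells_of("C2"))
    sig = de.significant_genes()
    planted = set(truth.marker_genes["C1"]) | set(truth.marker_genes["C2"])
    write_table(de.volcano_table(), RESULTS / "05_volcano_C1_vs_C2.tsv")
    print(f"DE C1 vs C2: {len(sig)} genes at q<0.05 & |log2FC|>=1 "
          f"({len(set(sig) & planted)} of {len(planted)} planted markers)")
    up = (de.table.loc[sig, "log2fc"] > 0).sum()
    print(f"  {up} higher in C1, {len(sig) - up} higher in C2")

    target = truth.w_star.abs().idxmax()
    scr = spearman_screen(m, a.cells_of("C1"), target)
    pos, neg = scr.positive_genes(), scr.negative_genes()
    write_table(scr.table, RESULTS / "05_correlation_screen.tsv")
    grad_pos = truth.w_star[truth.w_star > 0].index if truth.w_star[target] > 0 else truth.w_star[truth.w_star < 0].index
    print(f"Correlation screen vs {target} (gradient gene, w* = {truth.w_star[target]:+.2f}):")
    print(f"  {len(pos)} correlated / {len(neg)} anti-correlated genes "
          f"(rho > 0.15, q < 0.05); {len(set(pos) & set(grad_pos))} of the "
          f"correlated are same-sign gradient genes")


if __name__ == "__main__":
    main()
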