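import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from striacell.cluster_scaffold import (
    assess_robustness,
    cluster_cells,
    cluster_mean_dendrogram,
    linkage_to_newick,
    merge_clusters,
    select_variable_genes,
)
from striacell.matrix_io import ClusterAssignment, CountMatrix
from striacell.synthetic_data import CountSimConfig, simulate_counts


class TestVariableGenes:
    def test_constant_genes_never_beat_variable_ones(self):
        rng = np.random.default_rng(0)
        counts = np.vstack([
            np.full((5, 40), 7),  # constant genes
            rng.poisson(7, size=(20, 40)),
        ])
        m = CountMatrix(counts, [f"g{i}" for i in range(25)], [f"c{i}" for i in range(40)])
        fit = select_variable_genes(m, n=10)
        assert not set(fit.selected) & {f"g{i}" for i in range(5)}

    def test_monotone_in_cv_at_equal_mean(self):
        # two genes with identical means but different spread
        lo = np.array([4, 4, 4, 4, 4, 4, 4, 4])
        hi = np.array([0, 8, 0, 8, 0, 8, 0, 8])
        filler = np.array([1, 2, 3, 4, 5, 4, 3, 2])
        m = CountMatrix(np.vstack([lo, hi, filler]), ["lo", "hi", "mid"], [f"c{i}" for i in range(8)])
        fit = select_variable_genes(m, n=1)
        assert fit.selected == ["hi"]

    def test_recovers_planted_high_dispersion_genes(self):
        rng = np.random.default_rng(11)
        n_cells = 200
        base = rng.uniform(2, 6, size=550)
        counts = rng.poisson(np.tile(base[:, None], (1, n_cells)))
        # 50 planted overdispersed genes: NB with small theta
        mu = base[:50, None]
        counts[:50] = rng.poisson(rng.gamma(0.3, mu / 0.3, size=(50, n_cells)))
        m = CountMatrix(counts, [f"g{i}" for i in range(550)], [f"c{i}" for i in range(n_cells)])
        fit = select_variable_genes(m, n=50)
        hits = len(set(fit.selected) & {f"g{i}" for i in range(50)})
        assert hits >= 45

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(5, size=(30, 20))
        m1 = CountMatrix(counts, [f"g{i}" for i in range(30)], [f"c{i}" for i in range(20)])
        m2 = CountMatrix(counts * 3, m1.gene_ids, m1.cell_ids)
        assert select_variable_genes(m1, n=10).selected == select_variable_genes(m2, n=10).selected

    def test_n_too_large(self, tiny_matrix):
        with pytest.raises(ValueError):
            select_variable_genes(tiny_matrix, n=100)


class TestClusterCells:
    def test_two_separated_clusters_recovered(self):
        cfg = CountSimConfig(n_clusters=2, cells_per_cluster=50, n_genes=200,
                             markers_per_cluster=20, marker_fold=8, seed=21)
        m, truth = simulate_counts(cfg)
        fit = select_variable_genes(m, n=60)
        a = cluster_cells(m, fit, k=2)
        ari = adjusted_rand_score(truth.assignment.labels_for(m.cell_ids), a.labels_for(m.cell_ids))
        assert ari == 1.0

    def test_seven_cluster_ari(self):
        m, truth = simulate_counts(CountSimConfig(seed=31))
        fit = select_variable_genes(m, n=150)
        a = cluster_cells(m, fit, k=7)
        ari = adjusted_rand_score(truth.assignment.labels_for(m.cell_ids), a.labels_for(m.cell_ids))
        assert ari > 0.9

    def test_k_one(self, small_reference):
        m, _ = small_reference
        a = cluster_cells(m, m.gene_ids[:50], k=1)
        assert len(set(a.labels.values())) == 1

    def test_k_exceeds_cells(self, tiny_matrix):
        with pytest.raises(ValueError):
            cluster_cells(tiny_matrix, ["g1"], k=5)

    def test_invariance_to_cell_duplication(self):
        cfg = CountSimConfig(n_clusters=2, cells_per_cluster=30, n_genes=100,
                             markers_per_cluster=15, marker_fold=8, seed=5)
        m, _ = simulate_counts(cfg)
        a1 = cluster_cells(m, m.gene_ids, k=2)
        dup = CountMatrix(
            np.concatenate([m.counts, m.counts], axis=1),
            m.gene_ids,
            m.cell_ids + [f"{c}_dup" for c in m.cell_ids],
        )
        a2 = cluster_cells(dup, dup.gene_ids, k=2)
        orig = [a2.labels[c] for c in m.cell_ids]
        copies = [a2.labels[f"{c}_dup"] for c in m.cell_ids]
        assert orig == copies
        assert adjusted_rand_score([a1.labels[c] for c in m.cell_ids], orig) == 1.0


class TestMerge:
    def test_identity_mapping(self):
        a = ClusterAssignment({"c1": "A", "c2": "B"})
        merged = merge_clusters(a, {"A": "A", "B": "B"})
        assert merged.labels == a.labels

    def test_sixteen_to_six(self):
        cells = {f"c{i}": f"F{i % 16}" for i in range(64)}
        a = ClusterAssignment(cells)
        mapping = {f"F{i}": f"M{i % 6}" for i in range(16)}
        merged = merge_clusters(a, mapping)
        assert len(set(merged.labels.values())) == 6
        assert merged.hierarchy[-1] == mapping

    def test_union_of_cell_sets(self):
        a = ClusterAssignment({"c1": "A", "c2": "B", "c3": "C"})
        merged = merge_clusters(a, {"A": "AB", "B": "AB", "C": "C"})
        assert set(merged.cells_of("AB")) == {"c1", "c2"}

    def test_unmapped_label_rejected(self):
        a = ClusterAssignment({"c1": "A", "c2": "B"})
        with pytest.raises(ValueError, match="B"):
            merge_clusters(a, {"A": "A"})


class TestRobustness:
    def test_perfectly_separable_blocks(self):
        # disjoint exclusive marker blocks per cluster
        rng = np.random.default_rng(2)
        K, C, G = 3, 30, 60
        counts = np.zeros((G, K * C), dtype=int)
        for k in range(K):
            block = slice(k * 20, (k + 1) * 20)
            cells = slice(k * C, (k + 1) * C)
            counts[block, cells] = rng.poisson(20, size=(20, C)) + 1
        m = CountMatrix(counts, [f"g{i}" for i in range(G)], [f"c{i}" for i in range(K * C)])
        a = ClusterAssignment({m.cell_ids[i]: f"K{i // C}" for i in range(K * C)})
        rep = assess_robustness(m, a, seed=0)
        assert (rep.precision == 1.0).all()
        assert (rep.recall == 1.0).all()

    def test_confusion_rows_sum_to_one(self, small_reference):
        m, truth = small_reference
        rep = assess_robustness(m, truth.assignment, seed=1)
        np.testing.assert_allclose(rep.confusion.sum(axis=1), 1.0)

    def test_shuffled_labels_recall_near_frequency(self, small_reference):
        m, truth = small_reference
        rng = np.random.default_rng(9)
        labels = truth.assignment.labels_for(m.cell_ids)
        shuffled = ClusterAssignment(dict(zip(m.cell_ids, rng.permutation(labels))))
        rep = assess_robustness(m, shuffled, seed=9)
        # 7 equal clusters: recall per cluster should be near 1/7
        freq = 1 / 7
        n_test = 0.2 * m.n_cells / 7
        sd = np.sqrt(freq * (1 - freq) / n_test)
        assert (np.abs(rep.recall - freq) < 3 * sd).all()

    def test_singleton_cluster_rejected(self, tiny_matrix):
        a = ClusterAssignment({"cA": "X", "cB": "Y"})
        with pytest.raises(ValueError, match="X|Y"):
            assess_robustness(tiny_matrix, a)


class TestDendrogram:
    def test_identical_profiles_merge_at_zero(self):
        counts = np.array([[5, 5, 5, 5], [2, 2, 2, 2], [9, 9, 9, 9]])
        m = CountMatrix(counts, ["a", "b", "c"], [f"c{i}" for i in range(4)])
        a = ClusterAssignment({"c0": "X", "c1": "X", "c2": "Y", "c3": "Y"})
        Z, names = cluster_mean_dendrogram(m, a)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-9)

    def test_correlated_pair_merges_first(self):
        rng = np.random.default_rng(1)
        prof = rng.poisson(10, size=20) + 1
        counts = np.stack([prof, prof * 3, prof[::-1]], axis=1)
        m = CountMatrix(counts, [f"g{i}" for i in range(20)], ["cA", "cB", "cC"])
        a = ClusterAssignment({"cA": "A", "cB": "B", "cC": "C"})
        Z, names = cluster_mean_dendrogram(m, a)
        first = {int(Z[0, 0]), int(Z[0, 1])}
        assert first == {names.index("A"), names.index("B")}

    def test_two_clusters_single_merge_and_newick(self):
        counts = np.array([[1, 9], [9, 1]])
        m = CountMatrix(counts, ["a", "b"], ["c0", "c1"])
        a = ClusterAssignment({"c0": "X", "c1": "Y"})
        Z, names = cluster_mean_dendrogram(m, a)
        assert Z.shape == (1, 4)
        nwk = linkage_to_newick(Z, names)
        assert nwk.startswith("(") and nwk.endswith(";")
        assert "X" in nwk and "Y" in nwk

    def test_empty_cluster_rejected(self, tiny_matrix):
        a = ClusterAssignment({"cA": "X", "cB": "X", "ghost": "Y"})
        with pytest.raises(ValueError, match="no cells"):
            cluster_mean_dendrogram(tiny_matrix, a)
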