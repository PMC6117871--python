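import numpy as np
import pandas as pd
import pytest

from striacell.gradient_latent import (
    CovariateDesign,
    factor_ephys_association,
    factor_gene_association,
    filter_genes_latent,
    fit_latent_factor,
    gradient_tsne_screen,
    plate_design,
)
from striacell.matrix_io import ClusterAssignment, CountMatrix, EmbeddingCoords


def rank1_nb_matrix(seed, n=200, G=100, theta=5.0, w_scale=0.5):
    """Generative rank-1 NB model; the construction is the oracle."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    z = (z - z.mean()) / z.std()
    w = rng.normal(0, w_scale, G)
    a = rng.normal(0.5, 1.0, G)
    s = rng.lognormal(0, 0.3, n)
    mu = s[:, None] * np.exp(a[None, :] + np.outer(z, w))
    y = rng.poisson(rng.gamma(theta, mu / theta))
    m = CountMatrix(y.T, [f"g{i}" for i in range(G)], [f"c{i}" for i in range(n)])
    return m, z, w


class TestGeneFilter:
    @pytest.mark.parametrize(
        "count,n_cells,kept",
        [
            (4, 9, True),   # over 3 reads in over 8 cells
            (4, 8, False),  # 8 cells is not over 8
            (3, 100, False),  # 3 reads is not over 3
        ],
    )
    def test_strict_boundaries(self, count, n_cells, kept):
        total = 120
        row = np.zeros(total, dtype=int)
        row[:n_cells] = count
        counts = np.vstack([row, np.full(total, 10)])
        m = CountMatrix(counts, ["probe", "always"], [f"c{i}" for i in range(total)])
        got = filter_genes_latent(m)
        assert ("probe" in got) == kept
        assert "always" in got


class TestFit:
    def test_identical_cells_degenerate(self):
        counts = np.tile(np.array([[4], [7], [2]]), (1, 10))
        m = CountMatrix(counts, ["a", "b", "c"], [f"c{i}" for i in range(10)])
        model = fit_latent_factor(m, seed=0)
        assert model.degenerate
        assert np.abs(model.w.to_numpy()).max() < 1e-6

    def test_rank1_recovery_and_sign_consistency(self):
        m, z_true, w_true = rank1_nb_matrix(seed=1)
        model = fit_latent_factor(m, seed=1)
        r = np.corrcoef(model.z.to_numpy(), z_true)[0, 1]
        assert abs(r) > 0.9
        # orient and compare loading signs for genes clearly above noise
        w_hat = model.w.to_numpy() * np.sign(r)
        strong = np.abs(w_true) > 0.3
        agree = np.mean(np.sign(w_hat[strong]) == np.sign(w_true[strong]))
        assert agree > 0.9

    def test_loglik_trace_monotone(self):
        for seed in (3, 4):
            m, _, _ = rank1_nb_matrix(seed=seed, n=80, G=40)
            model = fit_latent_factor(m, seed=seed)
            trace = np.asarray(model.loglik_trace)
            assert np.all(np.diff(trace) >= -1e-6 * np.abs(trace[:-1]))

    def test_z_standardized(self):
        m, _, _ = rank1_nb_matrix(seed=6, n=90, G=40)
        model = fit_latent_factor(m, seed=6)
        z = model.z.to_numpy()
        assert z.mean() == pytest.approx(0.0, abs=1e-8)
        assert z.std() == pytest.approx(1.0, abs=1e-6)

    def test_plate_confound_contrast(self):
        rng = np.random.default_rng(42)
        n, G = 200, 80
        plates = np.array(["P1"] * (n // 2) + ["P2"] * (n // 2))
        pe = rng.normal(0, 0.5, G)
        a = rng.normal(1.0, 0.8, G)
        mu = np.exp(a[None, :] + (plates == "P2")[:, None] * pe[None, :])
        y = rng.poisson(rng.gamma(5, mu / 5))
        m = CountMatrix(y.T, [f"g{i}" for i in range(G)], [f"c{i}" for i in range(n)])
        ind = (plates == "P2").astype(float)
        with_pl = fit_latent_factor(m, design=plate_design(plates), seed=0)
        without = fit_latent_factor(m, seed=0)
        assert abs(np.corrcoef(with_pl.z, ind)[0, 1]) < 0.2
        assert abs(np.corrcoef(without.z, ind)[0, 1]) > 0.5

    def test_too_small_rejected(self):
        m = CountMatrix(np.ones((1, 5), dtype=int), ["g"], [f"c{i}" for i in range(5)])
        with pytest.raises(ValueError):
            fit_latent_factor(m)


class TestPlateDesign:
    def test_reference_plate_omitted(self):
        d = plate_design(["A", "B", "B", "C"])
        assert d.matrix.shape == (4, 2)
        assert d.names == ["plate_B", "plate_C"]
        assert (d.matrix.sum(axis=1) <= 1).all()
        assert set(np.unique(d.matrix)) <= {0.0, 1.0}


class TestGeneAssociation:
    def test_strong_signal_gene(self):
        m, z_true, _ = rank1_nb_matrix(seed=9, n=300, G=50)
        model = fit_latent_factor(m, seed=9)
        rng = np.random.default_rng(10)
        orient = np.sign(np.corrcoef(model.z, z_true)[0, 1])
        y = rng.poisson(np.exp(1.0 + 1.5 * orient * model.z.to_numpy()))
        res = factor_gene_association(model, y)
        assert res["coef"] > 0
        assert res["p"] < 1e-6

    def test_null_calibration(self):
        m, _, _ = rank1_nb_matrix(seed=13, n=500, G=60)
        model = fit_latent_factor(m, seed=13)
        rng = np.random.default_rng(14)
        theta = model.theta
        off = np.exp(model.offsets.to_numpy())
        ps = []
        for _ in range(200):
            mu = np.exp(1.0) * off
            y = rng.poisson(rng.gamma(theta, mu / theta))
            ps.append(factor_gene_association(model, y)["p"])
        frac = np.mean(np.asarray(ps) < 0.05)
        assert 0.02 < frac < 0.09

    def test_constant_gene_flagged(self):
        m, _, _ = rank1_nb_matrix(seed=2, n=50, G=30)
        model = fit_latent_factor(m, seed=2)
        res = factor_gene_association(model, np.zeros(50))
        assert res["flag"] == "all_zero"


class TestEphysAssociation:
    def _setup(self, seed=0, n=50, G=20):
        rng = np.random.default_rng(seed)
        w = pd.Series(rng.normal(0, 1, G), index=[f"g{i}" for i in range(G)])
        expr = pd.DataFrame(
            rng.poisson(5, size=(G, n)),
            index=w.index,
            columns=[f"c{i}" for i in range(n)],
        )
        return w, expr, rng

    def test_constructed_positive_association(self):
        w, expr, rng = self._setup(seed=1)
        proj = w.to_numpy() @ np.log(expr.to_numpy() + 1)
        ephys = 2.0 * proj + rng.normal(0, 0.5 * proj.std(), proj.size)
        res = factor_ephys_association(w, expr, ephys)
        assert res["slope"] > 0
        assert res["p"] < 0.01

    def test_null_p_uniform(self):
        w, expr, rng = self._setup(seed=2)
        ps = [
            factor_ephys_association(w, expr, rng.normal(size=expr.shape[1]))["p"]
            for _ in range(100)
        ]
        assert 0.005 < np.mean(np.asarray(ps) < 0.05) < 0.12

    def test_single_gene_overlap_rejected(self):
        w, expr, _ = self._setup()
        with pytest.raises(ValueError, match="overlap"):
            factor_ephys_association(w.iloc[:1], expr.iloc[:1], np.zeros(expr.shape[1]))


class TestGradientScreen:
    def _cluster_setup(self, n_cluster=60, n_other=140, G=30, seed=0):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(3, size=(G, n_cluster + n_other))
        cells = [f"c{i}" for i in range(n_cluster + n_other)]
        m = CountMatrix(counts, [f"g{i}" for i in range(G)], cells)
        a = ClusterAssignment(
            {c: ("K" if i < n_cluster else "other") for i, c in enumerate(cells)}
        )
        xy = rng.normal(size=(n_cluster, 2))
        coords = EmbeddingCoords({cells[i]: tuple(xy[i]) for i in range(n_cluster)})
        return m, a, coords, rng

    def test_detection_filters_strict(self):
        m, a, coords, _ = self._cluster_setup()
        cluster_cells = a.cells_of("K")
        n = len(cluster_cells)
        counts = m.counts.copy()
        # gene 0: detected in exactly 10% of cluster cells -> excluded
        counts[0] = 0
        idx = m.cell_index(cluster_cells[: n // 10])
        counts[0, idx] = 5
        # gene 1: detected in 75% of ALL cells -> excluded (>= 70%)
        counts[1] = 0
        counts[1, : int(0.75 * m.n_cells)] = 2
        m2 = CountMatrix(counts, m.gene_ids, m.cell_ids)
        res = gradient_tsne_screen(m2, a, "K", coords)
        assert not res.table.loc["g0", "included"]
        assert not res.table.loc["g1", "included"]
        assert np.isnan(res.table.loc["g0", "r_x"])

    def test_gene_equal_to_x_coordinate(self):
        m, a, coords, _ = self._cluster_setup(seed=3)
        cluster_cells = a.cells_of("K")
        xy = coords.array_for(cluster_cells)
        counts = m.counts.copy().astype(float)
        gi = 5
        x = xy[:, 0]
        counts[gi] = 0  # keep the gene rare outside the cluster
        counts[gi, m.cell_index(cluster_cells)] = np.round(10 * (x - x.min() + 0.1)).astype(int)
        m2 = CountMatrix(counts.astype(int), m.gene_ids, m.cell_ids)
        res = gradient_tsne_screen(m2, a, "K", coords, log_transform=False, use_normalized=False)
        assert res.table.loc["g5", "r_x"] > 0.95

    def test_filters_match_brute_force(self):
        m, a, coords, _ = self._cluster_setup(seed=5)
        res = gradient_tsne_screen(m, a, "K", coords)
        sub = m.subset(cells=a.cells_of("K"))
        for g in m.gene_ids:
            cf = (sub.counts[sub.gene_index([g])[0]] > 0).mean()
            df = (m.counts[m.gene_index([g])[0]] > 0).mean()
            assert res.table.loc[g, "included"] == ((cf > 0.1) and (df < 0.7))

    def test_tiny_cluster_rejected(self):
        m, a, coords, _ = self._cluster_setup()
        tiny = ClusterAssignment({c: ("K" if i < 2 else "o") for i, c in enumerate(m.cell_ids)})
        with pytest.raises(ValueError):
            gradient_tsne_screen(m, tiny, "K", coords)
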