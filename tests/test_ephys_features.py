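import numpy as np
import pandas as pd
import pytest

from striacell.ephys_features import (
    Sweep,
    SweepSet,
    detect_aps,
    ephys_pca,
    exclude_low_quality,
    extract_features,
    hcluster_ephys,
    pairwise_compare,
    read_sweep_set,
    write_sweep_set,
)
from striacell.synthetic_data import archetype_config, simulate_sweeps

FS = 20_000.0
DT = 1.0 / FS


def triangular_spike_trace(baseline=-45.0, peak=35.0, slope_mv_per_ms=100.0):
    """Flat baseline, linear rise at the given slope to the peak, symmetric
    descent: closed-form amplitude and half-width."""
    rise_s = (peak - baseline) / slope_mv_per_ms * 1e-3
    n_rise = int(round(rise_s * FS))
    pre = np.full(400, baseline)
    up = np.linspace(baseline, peak, n_rise + 1)[1:]
    down = np.linspace(peak, baseline, n_rise + 1)[1:]
    post = np.full(400, baseline)
    return np.concatenate([pre, up, down, post])


class TestDetectAps:
    def test_flat_trace_empty(self):
        assert detect_aps(np.full(2000, -70.0), FS) == []

    def test_triangular_spike_closed_form(self):
        v = triangular_spike_trace()
        events = detect_aps(v, FS)
        assert len(events) == 1
        ev = events[0]
        assert ev.threshold_voltage_mv == pytest.approx(-45.0, abs=0.5)
        assert ev.amplitude_mv == pytest.approx(80.0, abs=0.5)
        # width at half amplitude (-5 mV): 0.4 ms up + 0.4 ms down
        assert ev.half_width_ms == pytest.approx(0.8, rel=0.02)

    def test_two_spikes_give_two_events_with_50ms_iei(self):
        single = triangular_spike_trace()
        gap = int(0.05 * FS) - len(single) // 2  # spacing so peaks sit 50 ms apart
        v = np.concatenate([single, np.full(gap, -45.0), single])
        events = detect_aps(v, FS)
        assert len(events) == 2
        iei_ms = (events[1].peak_time_s - events[0].peak_time_s) * 1e3
        assert iei_ms == pytest.approx(len(single) * DT * 1e3 + gap * DT * 1e3, abs=0.2)

    def test_time_axis_offset_invariance(self):
        # padding before the spike shifts times but not shape measurements
        v = triangular_spike_trace()
        padded = np.concatenate([np.full(1000, -45.0), v])
        e1 = detect_aps(v, FS)[0]
        e2 = detect_aps(padded, FS)[0]
        assert e2.amplitude_mv == pytest.approx(e1.amplitude_mv, abs=1e-9)
        assert e2.half_width_ms == pytest.approx(e1.half_width_ms, abs=1e-9)


class TestExtractFeatures:
    def test_passive_membrane_analytic(self):
        # R = 100 MOhm, tau = 20 ms, no sag; -50 pA and -20 pA steps
        cfg = archetype_config(
            "regular", seed=0, r_input=100.0, tau_m=20.0, sag_fraction=0.0,
            hyper_currents=(-50.0, -20.0), noise_sd=0.05,
        )
        ss, truth = simulate_sweeps(cfg)
        f, _ = extract_features(ss)
        assert f["input_resistance"] == pytest.approx(100.0, abs=2.0)
        assert f["tau_m"] == pytest.approx(20.0, abs=2.0)
        assert abs(f["sag_ratio"]) <= 0.02

    def test_planted_rheobase_exact(self):
        cfg = archetype_config("regular", seed=1, rheobase=120.0)
        ss, _ = simulate_sweeps(cfg)
        f, _ = extract_features(ss)
        assert f["rheobase"] == 120.0

    def test_fast_spiking_half_width_within_5pct(self):
        cfg = archetype_config("fast_spiking", seed=2)
        ss, truth = simulate_sweeps(cfg)
        f, _ = extract_features(ss)
        assert f["ap_half_width"] == pytest.approx(truth["ap_half_width"], rel=0.05)

    def test_late_spiking_latency(self):
        cfg = archetype_config("late_spiking", seed=3)
        ss, truth = simulate_sweeps(cfg)
        f, _ = extract_features(ss)
        assert truth["latency_first_spike"] == pytest.approx(150.0, abs=1.0)
        assert f["latency_first_spike"] == pytest.approx(truth["latency_first_spike"], abs=10.0)

    def test_no_hyperpolarizing_sweeps_flagged(self):
        cfg = archetype_config("regular", seed=4)
        ss, _ = simulate_sweeps(cfg)
        depol_only = SweepSet(cell_id="x", sweeps=[s for s in ss.sweeps if s.current_pa > 0])
        f, flags = extract_features(depol_only)
        assert np.isnan(f["input_resistance"])
        assert flags["input_resistance"] == "no_hyperpolarizing_sweeps"

    def test_no_spikes_flagged(self):
        cfg = archetype_config("regular", seed=5)
        ss, _ = simulate_sweeps(cfg)
        passive_only = SweepSet(cell_id="x", sweeps=[s for s in ss.sweeps if s.current_pa < 0])
        f, flags = extract_features(passive_only)
        assert np.isnan(f["rheobase"])
        assert flags["rheobase"] == "no_action_potentials"


class TestExclusion:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["ap_half_width", "ap_amplitude"],
                            index=[f"c{i}" for i in range(len(rows))])

    def test_boundary_semantics(self):
        t = self._table([
            (2.0, 60.0),   # half-width exactly 2 ms: kept (strict >)
            (2.01, 60.0),  # excluded
            (1.0, 39.9),   # amplitude below 40: excluded
            (1.0, 40.0),   # exactly 40: kept
        ])
        kept, report = exclude_low_quality(t)
        assert list(kept.index) == ["c0", "c3"]
        assert report.loc["c1", "reason"] == "half_width"
        assert report.loc["c2", "reason"] == "amplitude"

    def test_unevaluable_cell_kept_with_flag(self):
        t = self._table([(np.nan, np.nan)])
        kept, report = exclude_low_quality(t)
        assert list(kept.index) == ["c0"]
        assert report.loc["c0", "reason"] == "unevaluable"


class TestStats:
    def _features(self, seed=0, n=40, p=6):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(10, 3, size=(n, p)),
            index=[f"c{i}" for i in range(n)],
            columns=[f"f{i}" for i in range(p)],
        )

    def test_pca_correlated_parameters_equal_loadings(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=50)
        # plant perfect correlation on the analysis (signed-log) scale
        u = 3 * np.sign(base) * np.log1p(np.abs(base)) + 5
        b = np.sign(u) * (np.expm1(np.abs(u)))
        X = pd.DataFrame({"a": base, "b": b, "c": rng.normal(size=50)},
                         index=[f"c{i}" for i in range(50)])
        out = ephys_pca(X)
        la, lb = out["loadings"].loc["a", "PC1"], out["loadings"].loc["b", "PC1"]
        assert abs(la) == pytest.approx(abs(lb), abs=1e-6)

    def test_pca_rank1_variance(self):
        base = np.linspace(1, 5, 30)
        X = pd.DataFrame({"a": base, "b": 2 * base, "c": 0.5 * base},
                         index=[f"c{i}" for i in range(30)])
        out = ephys_pca(X)
        assert out["variance_explained"][0] > 0.999

    def test_pca_order_invariance_up_to_sign(self):
        X = self._features()
        s1 = ephys_pca(X)["scores"]
        s2 = ephys_pca(X[list(X.columns[::-1])])["scores"]
        for pc in ("PC1", "PC2"):
            r = np.corrcoef(s1[pc], s2[pc])[0, 1]
            assert abs(r) == pytest.approx(1.0, abs=1e-8)

    def test_pairwise_identical_groups_t_zero(self):
        X = self._features(seed=2)
        dup = pd.concat([X, X.set_index(X.index + "_b")])
        res = pairwise_compare(dup, list(X.index), list(X.index + "_b"))
        np.testing.assert_allclose(res["t"].astype(float), 0.0, atol=1e-12)
        np.testing.assert_allclose(res["p"].astype(float), 1.0, atol=1e-12)

    def test_pairwise_planted_shift_detected(self):
        rng = np.random.default_rng(3)
        a = pd.DataFrame(rng.normal(10, 1, size=(20, 5)), columns=[f"f{i}" for i in range(5)],
                         index=[f"a{i}" for i in range(20)])
        b = pd.DataFrame(rng.normal(10, 1, size=(25, 5)), columns=a.columns,
                         index=[f"b{i}" for i in range(25)])
        b["f0"] += 3 * 1.0  # 3 pooled SDs in one parameter
        feats = pd.concat([a, b])
        res = pairwise_compare(feats, list(a.index), list(b.index))
        assert res.loc["f0", "q"] < 0.05
        assert (res.drop(index="f0")["q"] > 0.05).all()

    def test_hcluster_twin_merges_at_zero(self):
        X = self._features(seed=4, n=10)
        X.loc["c1"] = X.loc["c0"]
        link, order = hcluster_ephys(X)
        assert link[0, 2] == pytest.approx(0.0, abs=1e-9)
        assert {order[int(link[0, 0])], order[int(link[0, 1])]} == {"c0", "c1"}


class TestSweepIO:
    def test_round_trip(self, tmp_path):
        cfg = archetype_config("regular", seed=6, hyper_currents=(-40.0, -20.0))
        ss, _ = simulate_sweeps(cfg)
        write_sweep_set(ss, tmp_path / "cell0")
        back = read_sweep_set(tmp_path / "cell0", cell_id="cell0")
        assert len(back.sweeps) == len(ss.sweeps)
        for a, b in zip(ss.sweeps, back.sweeps):
            assert a.current_pa == b.current_pa
            np.testing.assert_allclose(a.voltage_mv, b.voltage_mv, atol=1e-5)
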