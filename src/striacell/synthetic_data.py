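"""Synthetic fixtures with exact ground truth.

Two generator families make every stage of the pipeline testable without
any download:

* negative-binomial UMI count matrices with planted cluster structure
  (cluster-exclusive marker enrichment), an optional within-cluster rank-1
  expression gradient ``exp(w*_g z*_i)``, plate batch effects and
  log-normal library sizes — emulating discrete interneuron classes that
  carry continuous gradients inside them;
* phenomenological current-clamp sweep sets for five firing archetypes
  (fast-spiking, fast-spiking-like, late-spiking, bursting/low-threshold,
  regular-spiking). Spike times are scheduled from the planted
  rate/adaptation rules and stereotyped piecewise-linear waveforms are
  inserted on a passive envelope, so the ground-truth feature vector is
  exactly controllable — which a conductance-based model would not allow.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ephys_features import FULL_FEATURE_SET, Sweep, SweepSet
from .matrix_io import ClusterAssignment, CountMatrix

__all__ = [
    "CountSimConfig",
    "GradientSpec",
    "TraceSimConfig",
    "ARCHETYPES",
    "simulate_counts",
    "simulate_patchseq_cells",
    "simulate_sweeps",
]


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

@dataclass
class GradientSpec:
    """A planted rank-1 gradient inside one cluster."""

    cluster: str
    n_genes: int = 20
    w_scale: float = 0.8  # spread of the per-gene loading w*
    w_min: float = 0.2  # minimum |w*|: every gradient gene carries signal
    positive_frac: float = 0.7  # fraction of gradient genes with w* > 0


@dataclass
class CountSimConfig:
    """Study-shaped NB count simulation settings.

    Defaults emulate the analysis conditions: 7 interneuron-like clusters
    of 100 cells, cluster-exclusive markers at 4-fold enrichment, UMI-like
    overdispersion (theta = 2) and ~2,000-count log-normal libraries.
    """

    n_clusters: int = 7
    cells_per_cluster: int = 100
    n_genes: int = 500
    markers_per_cluster: int = 10
    marker_fold: float = 4.0
    base_mean_log_mu: float = 0.0  # log-normal baseline expression
    base_mean_log_sigma: float = 1.0
    theta: float = 2.0  # NB dispersion: var = mu + mu^2/theta
    mean_depth: float = 2000.0
    depth_log_sigma: float = 0.3
    n_plates: int = 1
    plate_effect_sd: float = 0.0  # per-gene log-fold perturbation SD
    gradient: GradientSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_clusters, self.cells_per_cluster, self.n_genes) < 1:
            raise ValueError("sizes must be positive")
        if self.marker_fold < 1:
            raise ValueError("marker fold enrichment must be >= 1")
        if self.markers_per_cluster * self.n_clusters > self.n_genes:
            raise ValueError("more marker genes requested than genes available")


@dataclass
class CountSimTruth:
    """Everything needed to score downstream modules."""

    assignment: ClusterAssignment
    marker_genes: dict[str, list[str]]
    plate_labels: pd.Series
    z_star: pd.Series | None
    w_star: pd.Series | None
    cell_rates: np.ndarray  # genes x cells expected fractions (pre-depth)


def simulate_counts(cfg: CountSimConfig) -> tuple[CountMatrix, CountSimTruth]:
    """Draw an NB count matrix with planted clusters, markers, gradient and
    plate effects; fully reproducible given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    G, K, C = cfg.n_genes, cfg.n_clusters, cfg.cells_per_cluster
    n_cells = K * C
    gene_ids = [f"Gene{g:04d}" for g in range(G)]
    cell_ids = [f"cell{c:04d}" for c in range(n_cells)]
    cluster_names = [f"C{k+1}" for k in range(K)]
    labels = np.repeat(np.arange(K), C)

    base = rng.lognormal(cfg.base_mean_log_mu, cfg.base_mean_log_sigma, size=G)
    marker_sets: dict[str, list[str]] = {}
    mult = np.ones((G, n_cells))
    perm = rng.permutation(G)
    for k in range(K):
        idx = perm[k * cfg.markers_per_cluster : (k + 1) * cfg.markers_per_cluster]
        marker_sets[cluster_names[k]] = [gene_ids[i] for i in sorted(idx)]
        mult[np.ix_(idx, np.flatnonzero(labels == k))] *= cfg.marker_fold

    z_star = w_star = None
    if cfg.gradient is not None:
        gs = cfg.gradient
        k = cluster_names.index(gs.cluster)
        cells_k = np.flatnonzero(labels == k)
        free = [i for i in range(G) if gene_ids[i] not in
                {g for v in marker_sets.values() for g in v}]
        gidx = rng.choice(free, size=gs.n_genes, replace=False)
        sign = np.where(rng.random(gs.n_genes) < gs.positive_frac, 1.0, -1.0)
        w = (gs.w_min + np.abs(rng.normal(0, gs.w_scale, gs.n_genes))) * sign
        z = rng.standard_normal(cells_k.size)
        z = (z - z.mean()) / z.std()
        mult[np.ix_(gidx, cells_k)] *= np.exp(np.outer(w, z))
        z_star = pd.Series(z, index=[cell_ids[i] for i in cells_k])
        w_star = pd.Series(w, index=[gene_ids[i] for i in gidx])

    plates = rng.integers(0, cfg.n_plates, size=n_cells)
    if cfg.n_plates > 1 and cfg.plate_effect_sd > 0:
        plate_fx = rng.normal(0, cfg.plate_effect_sd, size=(G, cfg.n_plates))
        mult *= np.exp(plate_fx[:, plates])

    rates = base[:, None] * mult
    rates = rates / rates.sum(axis=0, keepdims=True)  # expression fractions
    depth = rng.lognormal(np.log(cfg.mean_depth) - cfg.depth_log_sigma**2 / 2,
                          cfg.depth_log_sigma, size=n_cells)
    mu = rates * depth[None, :]
    lam = rng.gamma(shape=cfg.theta, scale=mu / cfg.theta)
    counts = rng.poisson(lam)

    meta = pd.DataFrame(
        {"plate": [f"P{p+1}" for p in plates], "dataset": "synthetic"},
        index=pd.Index(cell_ids, name="cell"),
    )
    m = CountMatrix(counts=counts, gene_ids=gene_ids, cell_ids=cell_ids, cell_meta=meta)
    assignment = ClusterAssignment(
        labels={cid: cluster_names[k] for cid, k in zip(cell_ids, labels)}
    )
    truth = CountSimTruth(
        assignment=assignment,
        marker_genes=marker_sets,
        plate_labels=meta["plate"],
        z_star=z_star,
        w_star=w_star,
        cell_rates=rates,
    )
    return m, truth


def simulate_patchseq_cells(
    reference: CountMatrix,
    assignment: ClusterAssignment,
    n_cells: int,
    depth: float = 5000.0,
    theta: float = 2.0,
    seed: int = 0,
) -> tuple[CountMatrix, pd.Series]:
    """Sample query cells from their true cluster's mean expression profile
    with NB noise at the given sequencing depth."""
    rng = np.random.default_rng(seed)
    clusters = assignment.cluster_names
    labels_ref = assignment.labels_for(reference.cell_ids)
    profiles = {}
    for c in clusters:
        idx = np.flatnonzero(labels_ref == c)
        prof = reference.counts[:, idx].mean(axis=1).astype(float)
        tot = prof.sum()
        profiles[c] = prof / tot if tot > 0 else np.full(reference.n_genes, 1 / reference.n_genes)
    if n_cells == 0:
        empty = CountMatrix(
            counts=np.zeros((reference.n_genes, 0), dtype=int),
            gene_ids=reference.gene_ids,
            cell_ids=[],
        )
        return empty, pd.Series(dtype=object)
    true = [clusters[i] for i in rng.integers(0, len(clusters), size=n_cells)]
    counts = np.empty((reference.n_genes, n_cells), dtype=np.int64)
    for i, c in enumerate(true):
        mu = profiles[c] * depth
        lam = rng.gamma(shape=theta, scale=np.maximum(mu, 1e-12) / theta)
        counts[:, i] = rng.poisson(lam)
    cell_ids = [f"ps{i:04d}" for i in range(n_cells)]
    query = CountMatrix(counts=counts, gene_ids=reference.gene_ids, cell_ids=cell_ids)
    return query, pd.Series(true, index=cell_ids, name="true_cluster")


# ---------------------------------------------------------------------------
# current-clamp traces
# ---------------------------------------------------------------------------

@dataclass
class TraceSimConfig:
    """Archetype-level settings for the phenomenological trace simulator.

    Units: resistance MOhm, time constants ms, voltages mV, currents pA,
    frequencies Hz, sampling Hz.
    """

    archetype: str = "regular"
    r_input: float = 250.0
    tau_m: float = 15.0
    e_rest: float = -75.0
    v_threshold: float = -42.0
    ap_amplitude: float = 70.0
    ap_half_width: float = 1.0
    ahp_depth: float = 12.0
    biphasic: bool = False
    ahp2_depth: float = 6.0
    ahp2_latency_ms: float = 12.0
    adaptation: float = 0.2  # target adaptation index
    sag_fraction: float = 0.02
    rebound_mv: float = 0.0
    rheobase: float = 80.0
    f_rheo: float = 8.0
    f_max: float = 60.0
    latency_rheo_ms: float = 30.0
    fail_current_offset: float = 120.0  # firing fails above rheobase + offset
    hyper_currents: tuple = (-100.0, -50.0, -20.0)
    depol_step: float = 20.0
    step_duration_s: float = 0.5
    onset_s: float = 0.1
    post_s: float = 0.3
    fs_hz: float = 20_000.0
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_hz < 10_000:
            raise ValueError("sampling rate must be >= 10 kHz")
        if not any(i < 0 for i in self.hyper_currents):
            raise ValueError("protocol must include hyperpolarizing steps")


#: preset parameterizations of the five firing archetypes
ARCHETYPES: dict[str, dict] = {
    "fast_spiking": dict(
        r_input=150.0, tau_m=8.0, v_threshold=-40.0, ap_amplitude=75.0,
        ap_half_width=0.35, ahp_depth=18.0, adaptation=0.05, sag_fraction=0.02,
        rheobase=200.0, f_rheo=60.0, f_max=200.0, latency_rheo_ms=25.0,
    ),
    "fast_spiking_like": dict(
        r_input=200.0, tau_m=10.0, v_threshold=-41.0, ap_amplitude=72.0,
        ap_half_width=0.5, ahp_depth=15.0, adaptation=0.1, sag_fraction=0.05,
        rheobase=150.0, f_rheo=40.0, f_max=120.0, latency_rheo_ms=30.0,
    ),
    "late_spiking": dict(
        r_input=300.0, tau_m=20.0, v_threshold=-44.0, ap_amplitude=65.0,
        ap_half_width=0.8, ahp_depth=10.0, adaptation=0.15, sag_fraction=0.05,
        rheobase=100.0, f_rheo=10.0, f_max=80.0, latency_rheo_ms=150.0,
    ),
    "bursting_low_threshold": dict(
        r_input=400.0, tau_m=25.0, v_threshold=-45.0, ap_amplitude=68.0,
        ap_half_width=0.9, ahp_depth=8.0, biphasic=True, adaptation=0.5,
        sag_fraction=0.25, rebound_mv=4.0, rheobase=40.0, f_rheo=15.0,
        f_max=90.0, latency_rheo_ms=20.0,
    ),
    "regular": dict(
        r_input=250.0, tau_m=15.0, v_threshold=-42.0, ap_amplitude=70.0,
        ap_half_width=1.0, ahp_depth=12.0, adaptation=0.2, sag_fraction=0.02,
        rheobase=80.0, f_rheo=8.0, f_max=60.0, latency_rheo_ms=40.0,
    ),
}


def archetype_config(name: str, seed: int = 0, **overrides) -> TraceSimConfig:
    if name not in ARCHETYPES:
        raise KeyError(f"unknown archetype {name!r}; options: {sorted(ARCHETYPES)}")
    params = {**ARCHETYPES[name], **overrides}
    return TraceSimConfig(archetype=name, seed=seed, **params)


def _grid(t: float, fs: float) -> int:
    return int(round(t * fs))


def simulate_sweeps(cfg: TraceSimConfig) -> tuple[SweepSet, pd.Series]:
    """Generate a sweep set plus the planted feature truth vector.

    The protocol contains the configured hyperpolarizing steps, 1 pA steps
    bracketing rheobase, coarser depolarizing steps up to firing failure,
    and one suprathreshold sweep past failure (no spikes). The sag
    conductance engages only on steps more hyperpolarizing than the
    smallest one, keeping the Rin / tau_m sweep a clean RC response.
    """
    rng = np.random.default_rng(cfg.seed)
    fs, dt = cfg.fs_hz, 1.0 / cfg.fs_hz
    n_total = _grid(cfg.onset_s + cfg.step_duration_s + cfg.post_s, fs)
    i_on, i_off = _grid(cfg.onset_s, fs), _grid(cfg.onset_s + cfg.step_duration_s, fs)
    t_step = np.arange(i_off - i_on) * dt

    truth = pd.Series(np.nan, index=FULL_FEATURE_SET, dtype=float)
    truth["rmp"] = cfg.e_rest
    truth["input_resistance"] = cfg.r_input
    truth["tau_m"] = cfg.tau_m
    truth["rheobase"] = cfg.rheobase
    truth["ap_threshold"] = cfg.v_threshold
    truth["ap_amplitude"] = cfg.ap_amplitude

    sweeps: list[Sweep] = []
    tau_s = cfg.tau_m * 1e-3

    smallest_hyper = max(cfg.hyper_currents)
    for i_pa in sorted(cfg.hyper_currents):
        d_inf = i_pa * cfg.r_input * 1e-3  # mV
        defl = d_inf * (1 - np.exp(-t_step / tau_s))
        use_sag = cfg.sag_fraction > 0 and i_pa < smallest_hyper
        if use_sag:
            t_x = min(5 * tau_s, cfg.step_duration_s * 0.4)
            ix = _grid(t_x, fs)
            d_peak = d_inf * (1 - np.exp(-t_x / tau_s))
            d_ss = d_peak * (1 - cfg.sag_fraction)
            tau_sag = (cfg.step_duration_s - t_x) / 5
            tt = t_step[ix:] - t_x
            defl = defl.copy()
            defl[ix:] = d_ss + (d_peak - d_ss) * np.exp(-tt / tau_sag)
        v = np.full(n_total, cfg.e_rest)
        v[i_on:i_off] += defl
        end_defl = defl[-1]
        post = np.arange(n_total - i_off) * dt
        v[i_off:] = cfg.e_rest + end_defl * np.exp(-post / tau_s)
        if use_sag and cfg.rebound_mv > 0:
            tau_reb = 0.02
            v[i_off:] += cfg.rebound_mv * (post / tau_reb) * np.exp(1 - post / tau_reb)
        sweeps.append(_finish_sweep(v, i_pa, cfg, rng))
        if i_pa == min(cfg.hyper_currents):
            # realized truth from the clean waveform, by the same definitions
            seg = v[i_on:i_off]
            peak_d = seg.min() - cfg.e_rest
            ss_d = seg[i_off - i_on - max(1, (i_off - i_on) // 5):].mean() - cfg.e_rest
            truth["sag_ratio"] = (peak_d - ss_d) / peak_d if peak_d < 0 else np.nan
            truth["rebound"] = v[i_off:].max() - cfg.e_rest

    # depolarizing protocol: 1 pA resolution around rheobase, then coarse
    i_fail = cfg.rheobase + cfg.fail_current_offset
    currents = [cfg.rheobase - 2, cfg.rheobase - 1, cfg.rheobase]
    c = cfg.rheobase + cfg.depol_step
    while c < i_fail:
        currents.append(c)
        c += cfg.depol_step
    currents.append(i_fail)  # the last sweep that still fires
    currents.append(i_fail + cfg.depol_step)  # depolarization block: silent

    best = None  # (freq, schedule, sweep)
    rheo_schedule = None
    for i_pa in currents:
        fires = cfg.rheobase <= i_pa <= i_fail
        schedule = _spike_schedule(cfg, i_pa) if fires else []
        v = _depol_waveform(cfg, i_pa, schedule, n_total, i_on, i_off)
        sweeps.append(_finish_sweep(v, i_pa, cfg, rng))
        if fires and i_pa == cfg.rheobase:
            rheo_schedule = schedule
        if fires:
            freq = len(schedule) / cfg.step_duration_s
            if best is None or freq > best[0]:
                best = (freq, schedule)

    if rheo_schedule:
        truth["latency_first_spike"] = rheo_schedule[0] * 1e3 - cfg.onset_s * 1e3
    truth["ap_half_width"] = _realized_half_width(cfg, fs)
    truth["ahp_amplitude"] = cfg.ahp_depth
    truth["ahp_latency"] = _fall_samples(cfg, fs) * dt * 1e3
    if cfg.biphasic:
        truth["ahp2_amp_diff"] = cfg.ahp2_depth - cfg.ahp_depth
        truth["ahp2_lat_diff"] = cfg.ahp2_latency_ms - truth["ahp_latency"]
    if best is not None:
        freq, sched = best
        truth["max_firing_freq"] = freq
        peaks = np.array(sched) + _rise_samples(cfg, fs) * dt
        half_start = cfg.onset_s + cfg.step_duration_s / 2
        truth["steady_freq"] = (peaks >= half_start).sum() / (cfg.step_duration_s / 2)
        if len(peaks) >= 3:
            isi = np.diff(peaks)
            truth["adaptation_index"] = (isi[-1] - isi[0]) / (isi[-1] + isi[0])
            truth["mean_iei"] = float(isi.mean() * 1e3)

    return SweepSet(cell_id=f"{cfg.archetype}_{cfg.seed}", sweeps=sweeps), truth


def _rise_samples(cfg: TraceSimConfig, fs: float) -> int:
    return max(2, _grid(cfg.ap_half_width * 1e-3, fs))


def _fall_samples(cfg: TraceSimConfig, fs: float) -> int:
    # fall from peak to the fast AHP trough; chosen so that the half-level
    # crossing puts the realized half-width at the configured value
    t_fall = cfg.ap_half_width * 1e-3 * (cfg.ap_amplitude + cfg.ahp_depth) / cfg.ap_amplitude
    return max(2, _grid(t_fall, fs))


def _realized_half_width(cfg: TraceSimConfig, fs: float) -> float:
    dt = 1.0 / fs
    n_rise, n_fall = _rise_samples(cfg, fs), _fall_samples(cfg, fs)
    rise_part = n_rise * dt / 2
    fall_part = n_fall * dt * (cfg.ap_amplitude / 2) / (cfg.ap_amplitude + cfg.ahp_depth)
    return (rise_part + fall_part) * 1e3


def _spike_schedule(cfg: TraceSimConfig, i_pa: float) -> list[float]:
    """Threshold-crossing times (s) for a sweep at current ``i_pa``."""
    i_fail = cfg.rheobase + cfg.fail_current_offset
    x = (i_pa - cfg.rheobase) / max(i_fail - cfg.rheobase, 1.0)
    freq = cfg.f_rheo + (cfg.f_max - cfg.f_rheo) * min(x, 1.0)
    n = max(1, int(round(freq * cfg.step_duration_s)))
    latency = cfg.latency_rheo_ms * 1e-3 * cfg.rheobase / max(i_pa, 1.0)
    latency = min(latency, cfg.step_duration_s * 0.4)
    first = cfg.onset_s + latency
    if n == 1:
        return [first]
    a = min(cfg.adaptation, 0.9)
    ratio = (1 + a) / (1 - a)  # ISI_last / ISI_first
    k = np.arange(n - 1)
    isis = ratio ** (k / max(n - 2, 1))
    span = cfg.onset_s + cfg.step_duration_s - first - 0.004  # leave room for the last spike
    isis = isis / isis.sum() * span
    times = first + np.concatenate([[0.0], np.cumsum(isis)])
    fs = cfg.fs_hz
    return [round(t * fs) / fs for t in times]


def _depol_waveform(
    cfg: TraceSimConfig, i_pa: float, schedule: list[float], n_total: int, i_on: int, i_off: int
) -> np.ndarray:
    fs, dt = cfg.fs_hz, 1.0 / cfg.fs_hz
    tau_s = cfg.tau_m * 1e-3
    v = np.full(n_total, cfg.e_rest)
    t_step = np.arange(i_off - i_on) * dt
    if not schedule:
        d_inf = i_pa * cfg.r_input * 1e-3
        # subthreshold sweeps stay below threshold by construction
        ceiling = (cfg.v_threshold - 1.0) - cfg.e_rest
        d_inf = min(d_inf, ceiling)
        v[i_on:i_off] += d_inf * (1 - np.exp(-t_step / tau_s))
        post = np.arange(n_total - i_off) * dt
        v[i_off:] = cfg.e_rest + d_inf * (1 - np.exp(-cfg.step_duration_s / tau_s)) * np.exp(
            -post / tau_s
        )
        return v
    # spiking sweep: envelope rises to threshold by the first spike
    latency = max(schedule[0] - cfg.onset_s, 5 * dt)
    tau_eff = latency / 6
    env = cfg.e_rest + (cfg.v_threshold - cfg.e_rest) * (1 - np.exp(-t_step / tau_eff))
    v[i_on:i_off] = env
    post = np.arange(n_total - i_off) * dt
    v[i_off:] = cfg.e_rest + (v[i_off - 1] - cfg.e_rest) * np.exp(-post / tau_s)

    n_rise, n_fall = _rise_samples(cfg, fs), _fall_samples(cfg, fs)
    for s_idx, t_thr in enumerate(schedule):
        i_thr = _grid(t_thr, fs)
        if i_thr + n_rise + n_fall + 2 >= i_off:
            continue
        v_thr = v[i_thr]
        peak = v_thr + cfg.ap_amplitude
        trough = v_thr - cfg.ahp_depth
        ramp_up = np.linspace(v_thr, peak, n_rise + 1)
        ramp_dn = np.linspace(peak, trough, n_fall + 1)[1:]
        i_peak = i_thr + n_rise
        i_trough = i_peak + n_fall
        v[i_thr : i_peak + 1] = ramp_up
        v[i_peak + 1 : i_trough + 1] = ramp_dn
        # recovery toward threshold until the next spike (slope < detection
        # threshold so the back-walk stops at the true AP onset)
        next_thr = (
            _grid(schedule[s_idx + 1], fs) if s_idx + 1 < len(schedule) else min(i_off, i_trough + _grid(0.05, fs))
        )
        if cfg.biphasic and s_idx == 0:
            i_ahp2 = i_thr + n_rise + _grid(cfg.ahp2_latency_ms * 1e-3, fs)
            i_ahp2 = min(i_ahp2, next_thr - 2)
            if i_ahp2 > i_trough + 2:
                mid = i_trough + (i_ahp2 - i_trough) // 2
                v_mid = v_thr - 0.3 * cfg.ahp_depth
                trough2 = v_thr - cfg.ahp2_depth
                v[i_trough + 1 : mid + 1] = np.linspace(trough, v_mid, mid - i_trough + 1)[1:]
                v[mid + 1 : i_ahp2 + 1] = np.linspace(v_mid, trough2, i_ahp2 - mid + 1)[1:]
                i_trough, trough = i_ahp2, trough2
        if next_thr > i_trough + 1:
            n_rec = next_thr - i_trough
            rec = np.linspace(trough, cfg.v_threshold, n_rec + 1)[1:]
            # cap the recovery slope below the dV/dt detection threshold
            max_step = 8.0 * dt * 1e3  # 8 mV/ms
            rec = trough + np.minimum(rec - trough, np.arange(1, n_rec + 1) * max_step)
            v[i_trough + 1 : next_thr + 1] = rec
    return v


def _finish_sweep(v: np.ndarray, i_pa: float, cfg: TraceSimConfig, rng) -> Sweep:
    noisy = v + rng.normal(0, cfg.noise_sd, size=v.size) if cfg.noise_sd > 0 else v.copy()
    return Sweep(
        current_pa=float(i_pa),
        voltage_mv=noisy,
        fs_hz=cfg.fs_hz,
        onset_s=cfg.onset_s,
        offset_s=cfg.onset_s + cfg.step_duration_s,
    )
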