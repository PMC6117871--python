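"""Intrinsic electrophysiology: AP detection, feature extraction from
current-clamp step protocols, quality exclusion, PCA and group tests.

Features extracted per cell (units in brackets): resting membrane
potential RMP [mV], input resistance Rin [MOhm], membrane time constant
tau_m [ms], sag ratio [-], rebound [mV], AP voltage threshold [mV],
rheobase (AP current threshold) [pA], AP amplitude [mV], AP half-width
[ms], AHP latency [ms] and amplitude [mV], biphasic AHP amplitude/latency
differences, latency to first spike at rheobase [ms], maximum firing
frequency [Hz], steady frequency [Hz], adaptation index [-] and mean
inter-event interval IEI [ms]. Features undefined for a cell (e.g. no
biphasic AHP) are NaN and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.signal
from scipy import stats
from scipy.optimize import curve_fit

from .diffexpr_corr import bh_adjust

__all__ = [
    "Sweep",
    "SweepSet",
    "APEvent",
    "FULL_FEATURE_SET",
    "CORE_FEATURE_SET",
    "detect_aps",
    "extract_features",
    "extract_feature_table",
    "exclude_low_quality",
    "ephys_pca",
    "pairwise_compare",
    "hcluster_ephys",
    "read_sweep_set",
    "write_sweep_set",
]

#: the full intrinsic-parameter panel
FULL_FEATURE_SET = [
    "rmp",
    "input_resistance",
    "tau_m",
    "sag_ratio",
    "rebound",
    "ap_threshold",
    "rheobase",
    "ap_amplitude",
    "ap_half_width",
    "ahp_latency",
    "ahp_amplitude",
    "ahp2_amp_diff",
    "ahp2_lat_diff",
    "latency_first_spike",
    "max_firing_freq",
    "steady_freq",
    "adaptation_index",
    "mean_iei",
]

#: reduced panel without the biphasic-AHP pair and rebound
CORE_FEATURE_SET = [
    f for f in FULL_FEATURE_SET if f not in ("ahp2_amp_diff", "ahp2_lat_diff", "rebound")
]


@dataclass
class Sweep:
    """One current-clamp sweep: injected current and sampled voltage."""

    current_pa: float
    voltage_mv: np.ndarray
    fs_hz: float
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        self.voltage_mv = np.asarray(self.voltage_mv, dtype=float)

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.voltage_mv.size) / self.fs_hz

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class SweepSet:
    cell_id: str
    sweeps: list[Sweep]

    def hyperpolarizing(self) -> list[Sweep]:
        return sorted((s for s in self.sweeps if s.current_pa < 0), key=lambda s: s.current_pa)

    def depolarizing(self) -> list[Sweep]:
        return sorted((s for s in self.sweeps if s.current_pa > 0), key=lambda s: s.current_pa)


@dataclass
class APEvent:
    """One detected action potential with its derived quantities."""

    peak_time_s: float
    peak_voltage_mv: float
    threshold_time_s: float
    threshold_voltage_mv: float
    amplitude_mv: float
    half_width_ms: float
    ahp_latency_ms: float = np.nan
    ahp_amplitude_mv: float = np.nan
    ahp2_latency_ms: float = np.nan
    ahp2_amplitude_mv: float = np.nan


def _smooth(v: np.ndarray, fs_hz: float, window_ms: float = 0.25) -> np.ndarray:
    """Moving-average smoothing used for extremum measurements on noisy
    traces (peak hyperpolarization, AHP troughs)."""
    n = max(1, int(round(window_ms * 1e-3 * fs_hz)))
    if n <= 1 or v.size < n:
        return v
    kernel = np.ones(n) / n
    out = np.convolve(v, kernel, mode="same")
    # edges of 'same' convolution are biased; fall back to raw samples
    half = n // 2 + 1
    out[:half] = v[:half]
    out[-half:] = v[-half:]
    return out


def _interp_crossing(t0, v0, t1, v1, level) -> float:
    if v1 == v0:
        return t0
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def detect_aps(
    voltage_mv: np.ndarray,
    fs_hz: float,
    dvdt_thresh: float = 10.0,
    min_amplitude: float = 10.0,
    search_window_s: float = 0.1,
) -> list[APEvent]:
    """Detect action potentials on a voltage trace.

    The AP threshold is the first sample of the run of dV/dt >=
    ``dvdt_thresh`` (mV/ms) preceding each peak; peaks must rise at least
    ``min_amplitude`` mV above their threshold. Half-width is measured at
    threshold + amplitude/2 with linear interpolation between samples. AHP
    troughs (below threshold voltage, before the next event) give latency
    from the peak and amplitude below threshold; a distinct second trough
    is reported when present.
    """
    v = np.asarray(voltage_mv, dtype=float)
    if v.size < 3:
        return []
    dt = 1.0 / fs_hz
    dvdt = np.diff(v) / (dt * 1e3)  # mV/ms
    peaks, _ = scipy.signal.find_peaks(v, prominence=min_amplitude)
    events: list[APEvent] = []
    for px in peaks:
        # walk back to the start of the fast-depolarization run
        i = px - 1
        while i > 0 and dvdt[i - 1] >= dvdt_thresh:
            i -= 1
        if i >= px or dvdt[min(i, dvdt.size - 1)] < dvdt_thresh:
            continue
        thr_idx = i
        v_thr = v[thr_idx]
        amp = v[px] - v_thr
        if amp < min_amplitude:
            continue
        half = v_thr + amp / 2
        # rising crossing
        j = px
        while j > thr_idx and v[j - 1] > half:
            j -= 1
        t_rise = _interp_crossing((j - 1) * dt, v[j - 1], j * dt, v[j], half) if j > 0 else j * dt
        # falling crossing
        end = min(v.size - 1, px + int(search_window_s * fs_hz))
        k = px
        while k < end and v[k + 1] > half:
            k += 1
        if k >= end:
            continue  # never falls below half level: not a resolvable AP
        t_fall = _interp_crossing(k * dt, v[k], (k + 1) * dt, v[k + 1], half)
        events.append(
            APEvent(
                peak_time_s=px * dt,
                peak_voltage_mv=v[px],
                threshold_time_s=thr_idx * dt,
                threshold_voltage_mv=v_thr,
                amplitude_mv=amp,
                half_width_ms=(t_fall - t_rise) * 1e3,
            )
        )
    # AHP measurement between consecutive events
    for n, ev in enumerate(events):
        px = int(round(ev.peak_time_s * fs_hz))
        stop = (
            int(round(events[n + 1].threshold_time_s * fs_hz))
            if n + 1 < len(events)
            else min(v.size, px + int(search_window_s * fs_hz))
        )
        seg = v[px:stop]
        if seg.size < 3:
            continue
        seg_s = _smooth(seg, fs_hz)
        minima, _ = scipy.signal.find_peaks(-seg_s, prominence=1.0)
        troughs = [ix for ix in minima if seg_s[ix] < ev.threshold_voltage_mv]
        if not troughs and seg.size:
            gmin = int(np.argmin(seg_s))
            if 0 < gmin < seg.size - 1 and seg_s[gmin] < ev.threshold_voltage_mv:
                troughs = [gmin]
        if troughs:
            t1 = troughs[0]
            ev.ahp_latency_ms = t1 * 1e3 / fs_hz
            ev.ahp_amplitude_mv = ev.threshold_voltage_mv - seg_s[t1]
            if len(troughs) > 1:
                t2 = troughs[1]
                ev.ahp2_latency_ms = t2 * 1e3 / fs_hz
                ev.ahp2_amplitude_mv = ev.threshold_voltage_mv - seg_s[t2]
    return events


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def _baseline(sweep: Sweep) -> float:
    n = max(1, int(sweep.onset_s * sweep.fs_hz) - 2)
    return float(sweep.voltage_mv[:n].mean())


def _steady_state(sweep: Sweep, frac: float = 0.2) -> float:
    i0 = int(sweep.onset_s * sweep.fs_hz)
    i1 = int(sweep.offset_s * sweep.fs_hz)
    start = i1 - max(1, int((i1 - i0) * frac))
    return float(sweep.voltage_mv[start:i1].mean())


def extract_features(s: SweepSet, dvdt_thresh: float = 10.0) -> tuple[pd.Series, dict[str, str]]:
    """Extract the intrinsic-parameter vector from a sweep set.

    Returns ``(features, flags)`` where flags maps feature names to the
    reason they are undefined. Passive features come from hyperpolarizing
    steps (Rin and tau_m from the smallest, sag and rebound from the
    largest); spike features from the rheobase sweep; firing-pattern
    features from the maximum-frequency sweep.
    """
    f = pd.Series(np.nan, index=FULL_FEATURE_SET, dtype=float)
    flags: dict[str, str] = {}
    if not s.sweeps:
        return f, {k: "no_sweeps" for k in FULL_FEATURE_SET}
    first = s.sweeps[0]
    f["rmp"] = _baseline(first)

    hyper = s.hyperpolarizing()
    if not hyper:
        for k in ("input_resistance", "tau_m", "sag_ratio", "rebound"):
            flags[k] = "no_hyperpolarizing_sweeps"
    else:
        small = hyper[-1]  # least negative current
        base = _baseline(small)
        dv = _steady_state(small) - base
        f["input_resistance"] = dv / small.current_pa * 1e3  # mV/pA -> MOhm
        f["tau_m"] = _fit_tau(small)
        large = hyper[0]  # most negative current
        base_l = _baseline(large)
        i0 = int(large.onset_s * large.fs_hz)
        i1 = int(large.offset_s * large.fs_hz)
        # sag develops over tens of ms, so a 5 ms window suppresses the
        # noise-floor bias of the min search without flattening the
        # transient; edges are excluded (smoothing falls back to raw there)
        raw = large.voltage_mv[i0:i1]
        w = int(0.005 * large.fs_hz)
        seg = _smooth(raw, large.fs_hz, window_ms=5.0)
        interior = seg[w : -w] if raw.size > 3 * w else seg
        peak_defl = interior.min() - base_l
        ss_defl = _steady_state(large) - base_l
        f["sag_ratio"] = (peak_defl - ss_defl) / peak_defl if peak_defl < 0 else np.nan
        post = large.voltage_mv[i1 : i1 + int(0.3 * large.fs_hz)]
        if post.size:
            f["rebound"] = _smooth(post, large.fs_hz, window_ms=1.0).max() - base_l

    # rheobase: smallest depolarizing current with >= 1 AP inside the step
    depol = s.depolarizing()
    spikes_by_sweep: dict[int, list[APEvent]] = {}
    rheo_sweep = None
    for ix, sw in enumerate(depol):
        evs = [
            e
            for e in detect_aps(sw.voltage_mv, sw.fs_hz, dvdt_thresh)
            if sw.onset_s <= e.peak_time_s <= sw.offset_s
        ]
        spikes_by_sweep[ix] = evs
        if evs and rheo_sweep is None:
            rheo_sweep = ix
    if rheo_sweep is None:
        for k in (
            "rheobase",
            "ap_threshold",
            "ap_amplitude",
            "ap_half_width",
            "ahp_latency",
            "ahp_amplitude",
            "latency_first_spike",
            "max_firing_freq",
            "steady_freq",
            "adaptation_index",
            "mean_iei",
            "ahp2_amp_diff",
            "ahp2_lat_diff",
        ):
            flags[k] = "no_action_potentials"
        return f, flags

    sw = depol[rheo_sweep]
    ap = spikes_by_sweep[rheo_sweep][0]
    f["rheobase"] = sw.current_pa
    f["ap_threshold"] = ap.threshold_voltage_mv
    f["ap_amplitude"] = ap.amplitude_mv
    f["ap_half_width"] = ap.half_width_ms
    f["ahp_latency"] = ap.ahp_latency_ms
    f["ahp_amplitude"] = ap.ahp_amplitude_mv
    f["latency_first_spike"] = (ap.threshold_time_s - sw.onset_s) * 1e3
    if np.isfinite(ap.ahp2_amplitude_mv):
        f["ahp2_amp_diff"] = ap.ahp2_amplitude_mv - ap.ahp_amplitude_mv
        f["ahp2_lat_diff"] = ap.ahp2_latency_ms - ap.ahp_latency_ms
    else:
        flags["ahp2_amp_diff"] = flags["ahp2_lat_diff"] = "monophasic_ahp"

    # firing-pattern features from the maximum-frequency sweep
    freqs = {
        ix: len(evs) / depol[ix].duration_s for ix, evs in spikes_by_sweep.items() if evs
    }
    best = max(freqs, key=lambda ix: (freqs[ix], -ix))
    f["max_firing_freq"] = freqs[best]
    sw_max = depol[best]
    evs = spikes_by_sweep[best]
    times = np.array([e.peak_time_s for e in evs])
    half_start = sw_max.onset_s + sw_max.duration_s / 2
    n_late = int((times >= half_start).sum())
    f["steady_freq"] = n_late / (sw_max.duration_s / 2)
    if len(times) >= 3:
        isi = np.diff(times)
        f["adaptation_index"] = (isi[-1] - isi[0]) / (isi[-1] + isi[0])
        f["mean_iei"] = float(isi.mean() * 1e3)
    else:
        flags["adaptation_index"] = flags["mean_iei"] = "too_few_spikes"
    return f, flags


def _fit_tau(sweep: Sweep) -> float:
    """Single-exponential least-squares fit to the onset decay of a
    hyperpolarizing response; returns tau in ms."""
    i0 = int(sweep.onset_s * sweep.fs_hz)
    i1 = int(sweep.offset_s * sweep.fs_hz)
    seg = sweep.voltage_mv[i0:i1]
    t = np.arange(seg.size) / sweep.fs_hz
    v0, vss = seg[0], _steady_state(sweep)
    if not np.isfinite(vss) or seg.size < 10:
        return np.nan

    def model(tt, tau, a, b):
        return b + a * np.exp(-tt / max(tau, 1e-6))

    try:
        popt, _ = curve_fit(
            model, t, seg, p0=[0.02, v0 - vss, vss], maxfev=5000
        )
        return float(abs(popt[0]) * 1e3)
    except Exception:
        return np.nan


def extract_feature_table(sweep_sets: list[SweepSet], dvdt_thresh: float = 10.0) -> pd.DataFrame:
    rows, flags = {}, {}
    for ss in sweep_sets:
        f, fl = extract_features(ss, dvdt_thresh)
        rows[ss.cell_id] = f
        flags[ss.cell_id] = fl
    table = pd.DataFrame(rows).T
    table.index.name = "cell"
    table.attrs["flags"] = flags
    return table


def exclude_low_quality(
    features: pd.DataFrame, hw_max: float = 2.0, amp_min: float = 40.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude cells with AP half-width larger than ``hw_max`` ms or AP
    amplitude lower than ``amp_min`` mV (both strict, as stated); cells
    where both features are NaN are kept with a warning flag.

    Returns ``(kept, report)`` where report lists every cell with its
    excluded flag and reason.
    """
    hw = features["ap_half_width"]
    amp = features["ap_amplitude"]
    reasons = []
    for c in features.index:
        r = []
        if np.isfinite(hw[c]) and hw[c] > hw_max:
            r.append("half_width")
        if np.isfinite(amp[c]) and amp[c] < amp_min:
            r.append("amplitude")
        if not np.isfinite(hw[c]) and not np.isfinite(amp[c]):
            r.append("unevaluable")
        reasons.append(r)
    excluded = ["half_width" in r or "amplitude" in r for r in reasons]
    report = pd.DataFrame(
        {"excluded": excluded, "reason": [";".join(r) for r in reasons]},
        index=features.index,
    )
    return features.loc[~np.asarray(excluded)], report


# ---------------------------------------------------------------------------
# statistics over the feature table
# ---------------------------------------------------------------------------

def _signed_log_z(features: pd.DataFrame, subset: list[str] | None) -> pd.DataFrame:
    cols = subset if subset is not None else list(features.columns)
    X = features[cols].astype(float)
    X = np.sign(X) * np.log1p(np.abs(X))
    return X


def ephys_pca(
    features: pd.DataFrame,
    subset: list[str] | None = None,
    impute: bool = True,
) -> dict:
    """PCA on signed-log, z-scored parameters.

    Missing entries are imputed with the parameter median (PCA only; the
    imputed mask is reported). Constant parameters are dropped with a
    warning entry. Returns scores, loadings and variance_explained.
    """
    if len(features) < 3:
        raise ValueError("need at least 3 cells")
    X = _signed_log_z(features, subset)
    imputed = X.isna()
    if impute:
        X = X.fillna(X.median())
    dropped = [c for c in X.columns if X[c].std(ddof=0) == 0 or X[c].isna().any()]
    X = X.drop(columns=dropped)
    Z = (X - X.mean()) / X.std(ddof=0)
    U, S, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    var = S**2 / (len(Z) - 1)
    scores = pd.DataFrame(
        U * S, index=X.index, columns=[f"PC{i+1}" for i in range(S.size)]
    )
    loadings = pd.DataFrame(
        Vt.T, index=X.columns, columns=[f"PC{i+1}" for i in range(S.size)]
    )
    return {
        "scores": scores,
        "loadings": loadings,
        "variance_explained": var / var.sum(),
        "dropped": dropped,
        "imputed_mask": imputed,
    }


def pairwise_compare(
    features: pd.DataFrame, group_a: list[str], group_b: list[str], subset: list[str] | None = None
) -> pd.DataFrame:
    """Welch two-sided t-test per parameter on signed-log data, BH across
    parameters. Missing values are dropped per parameter, never imputed."""
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("both groups need at least 3 cells")
    X = _signed_log_z(features, subset)
    rows = []
    for c in X.columns:
        a = X.loc[group_a, c].dropna()
        b = X.loc[group_b, c].dropna()
        if len(a) < 3 or len(b) < 3:
            rows.append((c, np.nan, np.nan, "insufficient_data"))
            continue
        if a.std(ddof=0) == 0 and b.std(ddof=0) == 0:
            if a.mean() == b.mean():
                rows.append((c, 0.0, 1.0, "zero_variance"))
            else:
                # groups are internally constant but differ exactly
                rows.append((c, np.inf if a.mean() > b.mean() else -np.inf, 0.0, "exact_separation"))
            continue
        import warnings as _warnings

        with _warnings.catch_warnings():
            # near-constant parameters (e.g. exactly recovered rheobase plus
            # one deviating cell) trip scipy's precision-loss warning; the
            # resulting tiny p-value is the correct answer here
            _warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append((c, float(t), float(p), ""))
    out = pd.DataFrame(rows, columns=["parameter", "t", "p", "flag"]).set_index("parameter")
    ok = out["p"].notna()
    out["q"] = np.nan
    out.loc[ok, "q"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out


def hcluster_ephys(features: pd.DataFrame, subset: list[str] | None = None, method: str = "average"):
    """Hierarchical clustering of cells on Euclidean distance over the
    signed-log z-scored features; returns (linkage, cell order)."""
    if len(features) < 2:
        raise ValueError("need at least 2 cells")
    X = _signed_log_z(features, subset)
    X = X.fillna(X.median())
    X = X.loc[:, X.std(ddof=0) > 0]
    Z = (X - X.mean()) / X.std(ddof=0)
    link = sch.linkage(Z.to_numpy(), method=method, metric="euclidean")
    return link, list(X.index)


# ---------------------------------------------------------------------------
# sweep I/O (per-cell CSV traces + manifest)
# ---------------------------------------------------------------------------

def write_sweep_set(s: SweepSet, directory) -> None:
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, sw in enumerate(s.sweeps):
        fname = f"sweep_{i:03d}.csv"
        pd.DataFrame({"time_s": sw.time_s, "voltage_mV": sw.voltage_mv}).to_csv(
            d / fname, index=False, float_format="%.6f"
        )
        rows.append((fname, sw.current_pa, sw.onset_s, sw.offset_s, sw.fs_hz))
    pd.DataFrame(
        rows, columns=["file", "current_pA", "onset_s", "offset_s", "fs_Hz"]
    ).to_csv(d / "manifest.tsv", sep="\t", index=False)


def read_sweep_set(directory, cell_id: str | None = None) -> SweepSet:
    from pathlib import Path

    d = Path(directory)
    manifest = pd.read_csv(d / "manifest.tsv", sep="\t")
    sweeps = []
    for _, row in manifest.iterrows():
        tr = pd.read_csv(d / row["file"])
        sweeps.append(
            Sweep(
                current_pa=float(row["current_pA"]),
                voltage_mv=tr["voltage_mV"].to_numpy(),
                fs_hz=float(row["fs_Hz"]),
                onset_s=float(row["onset_s"]),
                offset_s=float(row["offset_s"]),
            )
        )
    return SweepSet(cell_id=cell_id or d.name, sweeps=sweeps)
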