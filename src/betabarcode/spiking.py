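"""Spike-phase statistics, population decoding, optotagging and waveform clustering.

Spike-phase coherence is the mean resultant length R = |mean(e^{i p})| of the
unit phasors at spike-sampled phases; its null distribution comes from
circular rotations of the beta-bout window pattern (preserving all bout
durations and inter-bout gaps).  The Rayleigh p is computed from R and n as
Z = n R^2, p = e^{-Z} (1 + (2Z - Z^2)/(4n)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .betadyn import morlet_spectrogram


def rayleigh_p(R: float, n: int) -> float:
    """Rayleigh uniformity test p-value from resultant length and sample size."""
    Z = n * R * R
    p = np.exp(-Z) * (1.0 + (2.0 * Z - Z * Z) / (4.0 * n))
    return float(np.clip(p, 0.0, 1.0))


def circular_mean(phases: np.ndarray) -> float:
    return float(np.angle(np.mean(np.exp(1j * np.asarray(phases)))))


def resultant_length(phases: np.ndarray) -> float:
    return float(np.abs(np.mean(np.exp(1j * np.asarray(phases)))))


@dataclass
class SpikePhaseStats:
    unit_id: int
    n_spikes: int
    R: float
    preferred_phase: float
    rayleigh_p: float
    null_R: np.ndarray | None = None
    significant: bool | None = None
    scored: bool = True


def _spikes_in_windows(spike_times: np.ndarray, windows: np.ndarray) -> np.ndarray:
    """Spike times falling in any [start, end) window (windows sorted, disjoint)."""
    if len(windows) == 0:
        return np.array([])
    st = np.asarray(spike_times)
    starts, ends = windows[:, 0], windows[:, 1]
    k = np.searchsorted(starts, st, side="right") - 1
    ok = (k >= 0) & (st < ends[np.clip(k, 0, len(ends) - 1)])
    return st[ok]


def phases_at(phase_series: np.ndarray, rate: float, times: np.ndarray) -> np.ndarray:
    """Phase samples at the nearest LFP sample to each spike time."""
    idx = np.clip(np.round(np.asarray(times) * rate).astype(int), 0, len(phase_series) - 1)
    return phase_series[idx]


def spike_phase_coherence(
    spike_times: np.ndarray,
    phase_series: np.ndarray,
    rate: float,
    windows: np.ndarray | None = None,
    unit_id: int = -1,
    min_spikes: int = 20,
) -> SpikePhaseStats:
    """Mean resultant length, circular mean phase and Rayleigh p of a unit.

    ``windows`` restricts spikes to (n, 2) [start, end) intervals (e.g. beta
    bouts); units with fewer than ``min_spikes`` inside are flagged unscored.
    """
    st = np.asarray(spike_times, dtype=float)
    if windows is not None:
        st = _spikes_in_windows(st, np.asarray(windows, dtype=float))
    if len(st) < min_spikes:
        return SpikePhaseStats(unit_id, len(st), np.nan, np.nan, np.nan, scored=False)
    p = phases_at(phase_series, rate, st)
    R = resultant_length(p)
    return SpikePhaseStats(
        unit_id=unit_id,
        n_spikes=len(st),
        R=R,
        preferred_phase=circular_mean(p),
        rayleigh_p=rayleigh_p(R, len(st)),
    )


def rotate_windows(windows: np.ndarray, offset: float, t_total: float) -> np.ndarray:
    """Circularly shift a window pattern by ``offset`` modulo the recording.

    Windows that wrap around the end are split; durations and inter-window
    gaps are preserved exactly (up to the single wrap cut).
    """
    out = []
    for a, b in windows:
        dur = b - a
        a2 = (a + offset) % t_total
        b2 = a2 + dur
        if b2 <= t_total:
            out.append((a2, b2))
        else:  # wraps past the end: split into two pieces
            out.append((a2, t_total))
            out.append((0.0, b2 - t_total))
    return np.array(sorted(out))


def bout_shuffle_null(
    windows: np.ndarray,
    phase_series: np.ndarray,
    rate: float,
    spike_times: np.ndarray,
    t_total: float,
    n_shuffles: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Null R distribution from circular rotations of the bout-window pattern."""
    windows = np.asarray(windows, dtype=float)
    if len(windows) < 2:
        raise ValueError("need at least 2 bout windows")
    if np.sum(windows[:, 1] - windows[:, 0]) >= t_total:
        raise ValueError("total bout time exceeds recording time")
    rng = np.random.default_rng(seed)
    st = np.asarray(spike_times, dtype=float)
    null = np.empty(n_shuffles)
    for k in range(n_shuffles):
        shifted = rotate_windows(windows, rng.uniform(0, t_total), t_total)
        sel = _spikes_in_windows(st, shifted)
        if len(sel) == 0:
            null[k] = 0.0
            continue
        null[k] = resultant_length(phases_at(phase_series, rate, sel))
    return null


def coherence_with_null(
    spike_times,
    phase_series,
    rate,
    windows,
    t_total,
    n_shuffles: int = 200,
    seed: int = 0,
    unit_id: int = -1,
    min_spikes: int = 20,
) -> SpikePhaseStats:
    """Observed coherence plus bout-shuffle null and the 95th-percentile flag."""
    stats = spike_phase_coherence(
        spike_times, phase_series, rate, windows, unit_id, min_spikes
    )
    if not stats.scored:
        return stats
    null = bout_shuffle_null(
        windows, phase_series, rate, spike_times, t_total, n_shuffles, seed
    )
    stats.null_R = null
    stats.significant = bool(stats.R > np.percentile(null, 95))
    return stats


# --------------------------------------------------------------------------
# population coherence percentile curves


@dataclass
class PercentileCurves:
    percentiles: np.ndarray
    curves: dict                      # group -> fraction above each threshold
    null_low: dict
    null_high: dict
    significant: dict                 # group -> boolean mask over percentiles


def population_percentile_curve(
    R_values: np.ndarray,
    groups: np.ndarray,
    percentiles: np.ndarray | None = None,
    n_shuffles: int = 1000,
    ci: float = 99.0,
    seed: int = 0,
) -> PercentileCurves:
    """Fraction of each group above whole-population coherence percentiles.

    The null band comes from ``n_shuffles`` group-label shuffles; spans where
    a curve exits the two-sided ``ci``% band are flagged significant.
    """
    R_values = np.asarray(R_values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    for g in labels:
        if np.sum(groups == g) < 5:
            warnings.warn(f"group {g!r} has fewer than 5 units", stacklevel=2)
    if percentiles is None:
        percentiles = np.arange(0.0, 101.0, 1.0)
    thresholds = np.percentile(R_values, percentiles)

    def curves_for(lab_arr):
        return {
            g: np.array([(R_values[lab_arr == g] >= th).mean() for th in thresholds])
            for g in labels
        }

    obs = curves_for(groups)
    rng = np.random.default_rng(seed)
    null = {g: np.empty((n_shuffles, len(percentiles))) for g in labels}
    for k in range(n_shuffles):
        perm = rng.permutation(groups)
        for g in labels:
            null[g][k] = np.array([(R_values[perm == g] >= th).mean() for th in thresholds])
    lo_q, hi_q = (100 - ci) / 2, 100 - (100 - ci) / 2
    null_low = {g: np.percentile(null[g], lo_q, axis=0) for g in labels}
    null_high = {g: np.percentile(null[g], hi_q, axis=0) for g in labels}
    significant = {
        g: (obs[g] < null_low[g]) | (obs[g] > null_high[g]) for g in labels
    }
    return PercentileCurves(percentiles, obs, null_low, null_high, significant)


# --------------------------------------------------------------------------
# triggered firing


def trough_triggered_rate(
    spike_times: np.ndarray,
    trough_times: np.ndarray,
    bin_s: float = 0.0015,
    window_s: tuple = (-0.125, 0.125),
    zscore: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Peri-trough spike-count histogram (counts per trough per bin).

    Returns (bin centres, rate per bin); optionally z-scored against the
    window mean/SD.
    """
    troughs = np.atleast_1d(np.asarray(trough_times, dtype=float))
    if len(troughs) == 0:
        raise ValueError("no reference troughs")
    st = np.asarray(spike_times, dtype=float)
    edges = np.arange(window_s[0], window_s[1] + bin_s / 2, bin_s)
    counts = np.zeros(len(edges) - 1)
    for t in troughs:
        rel = st[(st >= t + window_s[0]) & (st < t + window_s[1])] - t
        counts += np.histogram(rel, bins=edges)[0]
    rate = counts / len(troughs)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if zscore:
        sd = rate.std()
        rate = (rate - rate.mean()) / sd if sd > 0 else rate - rate.mean()
    return centers, rate


# --------------------------------------------------------------------------
# place-LED decoding


@dataclass
class DecoderModel:
    estimator: LinearDiscriminantAnalysis
    cv_accuracy: float
    contributions: np.ndarray         # |coefficient| per unit
    training_stage: str = "recall"
    bin_s: float = 0.1


def fit_place_led_decoder(
    counts: np.ndarray,
    labels: np.ndarray,
    n_splits: int = 5,
    seed: int = 0,
    training_stage: str = "recall",
) -> DecoderModel:
    """LDA on 100-ms population spike-count vectors; stratified 5-fold CV.

    Returns the decoder refit on all training bins plus the mean held-out
    accuracy and per-unit contributions |coefficient|.
    """
    counts = np.asarray(counts, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training data contains a single class")
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    lda = LinearDiscriminantAnalysis()
    acc = cross_val_score(lda, counts, labels, cv=cv, scoring="accuracy").mean()
    lda.fit(counts, labels)
    return DecoderModel(
        estimator=lda,
        cv_accuracy=float(acc),
        contributions=np.abs(lda.coef_[0]),
        training_stage=training_stage,
    )


def apply_decoder(model: DecoderModel, counts: np.ndarray, labels: np.ndarray) -> float:
    """Accuracy of the (frozen) recall-trained decoder on another stage."""
    return float(model.estimator.score(np.asarray(counts, dtype=float), np.asarray(labels)))


def contribution_vs_coherence(
    contributions: np.ndarray, coherences: np.ndarray
) -> tuple[float, float]:
    """Pearson r (and p) between decoder |weight| and spike-phase coherence R."""
    from scipy.stats import pearsonr

    c = np.asarray(contributions, dtype=float)
    R = np.asarray(coherences, dtype=float)
    if len(c) != len(R):
        raise ValueError("mismatched unit sets")
    if len(c) < 10:
        warnings.warn("fewer than 10 units; correlation unstable", stacklevel=2)
    r, p = pearsonr(c, R)
    return float(r), float(p)


def spike_count_matrix(
    spike_times_by_unit: dict,
    t_start: float,
    t_end: float,
    bin_s: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """(n_bins, n_units) disjoint spike-count matrix plus bin start times."""
    edges = np.arange(t_start, t_end + bin_s / 2, bin_s)
    units = sorted(spike_times_by_unit)
    X = np.empty((len(edges) - 1, len(units)))
    for j, uid in enumerate(units):
        X[:, j] = np.histogram(spike_times_by_unit[uid], bins=edges)[0]
    return X, edges[:-1]


# --------------------------------------------------------------------------
# optotagging / entrainment


def _split_half_psth(
    spike_times: np.ndarray,
    pulse_times: np.ndarray,
    rng: np.random.Generator,
    bin_s: float = 0.002,
    window_s: tuple = (-1.0, 0.05),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pulses = rng.permutation(np.asarray(pulse_times, dtype=float))
    half1, half2 = pulses[: len(pulses) // 2], pulses[len(pulses) // 2 :]
    edges = np.arange(window_s[0], window_s[1] + bin_s / 2, bin_s)
    st = np.asarray(spike_times, dtype=float)

    def psth(p):
        c = np.zeros(len(edges) - 1)
        for t in p:
            rel = st[(st >= t + window_s[0]) & (st < t + window_s[1])] - t
            c += np.histogram(rel, bins=edges)[0]
        return c / max(len(p), 1)

    return psth(half1), psth(half2), 0.5 * (edges[:-1] + edges[1:])


def optotag_classify(
    spike_times: np.ndarray,
    pulse_times: np.ndarray,
    seed: int = 0,
    bin_s: float = 0.002,
    latency_cap_s: float = 0.006,
    min_pulses: int = 20,
) -> bool | None:
    """Split-half optotag test with 2-ms bins.

    Pulses are randomly split in two; the half-1 peak (post-onset) bin
    samples the half-2 response.  Tagged requires both halves' responses
    above the 99th percentile of their own -1000..-500 ms baseline bins AND
    the half-2 maximum response within 6 ms of laser onset.  Returns None
    (unscored) below ``min_pulses``.
    """
    if len(pulse_times) < min_pulses:
        return None
    rng = np.random.default_rng(seed)
    h1, h2, centers = _split_half_psth(spike_times, pulse_times, rng, bin_s)
    base = (centers >= -1.0) & (centers < -0.5)
    post = centers >= 0.0
    if not post.any():
        return False
    thr1 = np.percentile(h1[base], 99)
    thr2 = np.percentile(h2[base], 99)
    peak_bin = np.where(post)[0][int(np.argmax(h1[post]))]
    resp1 = h1[peak_bin]
    resp2 = h2[peak_bin]
    latency = centers[np.where(post)[0][int(np.argmax(h2[post]))]]
    return bool(resp1 > thr1 and resp2 > thr2 and latency <= latency_cap_s)


def entrainment_classify(
    spike_times: np.ndarray,
    pulse_times: np.ndarray,
    seed: int = 0,
    bin_s: float = 0.002,
    min_pulses: int = 20,
    window_s: tuple = (-1.0, 0.1),
) -> bool | None:
    """As the optotag test but 95th percentile of -1000..-50 ms, no latency cap."""
    if len(pulse_times) < min_pulses:
        return None
    if len(spike_times) == 0:
        return None
    rng = np.random.default_rng(seed)
    h1, h2, centers = _split_half_psth(spike_times, pulse_times, rng, bin_s, window_s)
    base = (centers >= -1.0) & (centers < -0.05)
    post = centers >= 0.0
    thr = np.percentile(h2[base], 95)
    peak_bin = np.where(post)[0][int(np.argmax(h1[post]))]
    return bool(h2[peak_bin] > thr)


# --------------------------------------------------------------------------
# spike-triggered spectrograms with speed control


def select_trigger_spikes(spike_times: np.ndarray, burst_isi_s: float = 0.010) -> np.ndarray:
    """Isolated spikes plus the first spike of each burst (ISI < 10 ms starts a burst)."""
    st = np.asarray(spike_times, dtype=float)
    if len(st) <= 1:
        return st
    prev_gap = np.diff(st, prepend=st[0] - 1.0)
    return st[prev_gap >= burst_isi_s]


def spike_triggered_spectrogram(
    lfp: np.ndarray,
    rate: float,
    spike_times: np.ndarray,
    speed: np.ndarray,
    speed_rate: float,
    freqs: np.ndarray,
    seed: int = 0,
    window_s: tuple = (-0.5, 0.5),
    n_speed_bins: int = 100,
    min_spikes: int = 20,
    n_cycles: float = 6.0,
):
    """Spike-triggered mean spectrogram minus a speed-matched control.

    Each qualifying spike (isolated or burst-first) is assigned a random
    control time drawn from the same speed-percentile bin (excluding real
    spike times); real and control responses are z-scored per frequency over
    both and subtracted.  Returns (difference grid, lags) or None when fewer
    than ``min_spikes`` qualify.
    """
    trig = select_trigger_spikes(spike_times)
    t_max = len(lfp) / rate
    i0 = int(round(window_s[0] * rate))
    i1 = int(round(window_s[1] * rate))
    trig = trig[(trig * rate + i0 >= 0) & (trig * rate + i1 <= len(lfp))]
    if len(trig) < min_spikes:
        return None
    rng = np.random.default_rng(seed)
    # percentile-bin the speed trace; map each spike to its bin
    sp_t = np.arange(len(speed)) / speed_rate
    edges = np.percentile(speed, np.linspace(0, 100, n_speed_bins + 1))
    sample_bins = np.clip(np.searchsorted(edges, speed, side="right") - 1, 0, n_speed_bins - 1)
    spike_bins = sample_bins[
        np.clip((trig * speed_rate).astype(int), 0, len(speed) - 1)
    ]
    spike_idx_set = set(np.round(trig * rate).astype(int))
    ctrl = np.empty_like(trig)
    for k, b in enumerate(spike_bins):
        cand_t = sp_t[sample_bins == b]
        cand_t = cand_t[(cand_t * rate + i0 >= 0) & (cand_t * rate + i1 <= len(lfp))]
        cand_t = np.array(
            [t for t in cand_t if int(round(t * rate)) not in spike_idx_set]
        )
        ctrl[k] = rng.choice(cand_t) if len(cand_t) else rng.uniform(
            -window_s[0], t_max + window_s[0]
        )
    spec = morlet_spectrogram(lfp, rate, freqs, n_cycles)

    def mean_windows(times):
        acc = np.zeros((spec.shape[0], i1 - i0))
        for t in times:
            c = int(round(t * rate))
            acc += spec[:, c + i0 : c + i1]
        return acc / len(times)

    real = mean_windows(trig)
    control = mean_windows(ctrl)
    both = np.concatenate([real, control], axis=1)
    mu = both.mean(axis=1, keepdims=True)
    sd = both.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    diff = (real - mu) / sd - (control - mu) / sd
    lags = np.arange(i0, i1) / rate
    return diff, lags


# --------------------------------------------------------------------------
# VTA waveform clustering


@dataclass
class WaveformClusterModel:
    waveforms: np.ndarray             # normalised (max-abs = 1) mean waveforms
    pc_scores: np.ndarray
    n_pcs: int
    embedding: np.ndarray             # (n_units, 2)
    labels: np.ndarray
    k: int


def cluster_vta_waveforms(
    waveforms: np.ndarray,
    k: int = 3,
    var_target: float = 0.95,
    seed: int = 0,
) -> WaveformClusterModel:
    """Normalise -> PCA (to >= 95% variance) -> 2-D UMAP -> seeded k-means.

    Each mean waveform is divided by its maximum absolute value; principal
    components are retained until ``var_target`` explained variance; k-means
    (k = 3 by default) labels the 2-D embedding.
    """
    import umap

    W = np.atleast_2d(np.asarray(waveforms, dtype=float))
    if W.shape[0] < k:
        raise ValueError(f"need at least {k} units for k={k} clusters")
    peak = np.abs(W).max(axis=1, keepdims=True)
    peak[peak == 0] = 1.0
    Wn = W / peak
    n_comp = min(W.shape[0], W.shape[1])
    pca = PCA(n_components=n_comp, random_state=seed)
    scores = pca.fit_transform(Wn)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_pcs = int(np.searchsorted(cum, var_target) + 1)
    n_pcs = min(n_pcs, scores.shape[1])
    reducer = umap.UMAP(
        n_components=2, random_state=seed, n_neighbors=min(15, W.shape[0] - 1)
    )
    emb = reducer.fit_transform(scores[:, :n_pcs])
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(emb)
    return WaveformClusterModel(
        waveforms=Wn, pc_scores=scores[:, :n_pcs], n_pcs=n_pcs,
        embedding=np.asarray(emb), labels=labels, k=k,
    )
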