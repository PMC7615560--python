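"""Beta cycle/bout detection, 4-Hz phase modulation, and wavelet spectrograms.

A beta cycle runs trough-to-trough and must contain, in order, an ascending
zero-crossing, a positive peak and a descending zero-crossing; the cycle is
only accepted if another ascending zero-crossing follows its end trough (so
the end trough genuinely starts the next cycle).  A beta bout is a chain of
at least 5 consecutive cycles whose mean amplitudes all exceed the session's
50th percentile of cycle amplitudes; the bout spans the first cycle's start
trough to the last cycle's end trough.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve


@dataclass
class BetaCycle:
    trough_start: int
    asc_zero: int
    peak: int
    desc_zero: int
    trough_end: int
    mean_amplitude: float


@dataclass
class BetaBout:
    start_s: float
    end_s: float
    cycles: list
    region: str = ""

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)


# --------------------------------------------------------------------------
# cycles and bouts


def detect_cycles(beta_imf: np.ndarray, amplitude: np.ndarray) -> list[BetaCycle]:
    """Trough-delimited cycles with the required internal structure.

    Malformed trough-to-trough spans (no positive peak, missing crossing)
    are skipped.  ``mean_amplitude`` is the mean instantaneous amplitude
    over the span.
    """
    x = np.asarray(beta_imf, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if len(x) != len(amplitude):
        raise ValueError("amplitude/IMF length mismatch")
    d = np.diff(x)
    minima = np.where((d[:-1] < 0) & (d[1:] >= 0))[0] + 1
    troughs = minima[x[minima] < 0]
    asc = np.where((x[:-1] < 0) & (x[1:] >= 0))[0]
    desc = np.where((x[:-1] >= 0) & (x[1:] < 0))[0]
    cycles: list[BetaCycle] = []
    if len(troughs) < 2:
        return cycles
    # a trough only delimits a cycle when the enclosed span has the full
    # asc-crossing -> positive peak -> desc-crossing structure; troughs that
    # fail (noise wiggles) are absorbed into the current span rather than
    # breaking the trough-to-trough tiling
    a = troughs[0]
    for b in troughs[1:]:
        asc_in = asc[(asc > a) & (asc < b)]
        if len(asc_in) == 0:
            continue
        seg = x[a:b]
        pk = a + int(np.argmax(seg))
        if x[pk] <= 0 or pk <= asc_in[0]:
            continue
        desc_in = desc[(desc > pk) & (desc < b)]
        if len(desc_in) == 0:
            continue
        # the end trough must itself be followed by an ascending crossing
        # (i.e. genuinely start the next cycle)
        if not len(asc[asc >= b]):
            continue
        cycles.append(
            BetaCycle(
                trough_start=int(a),
                asc_zero=int(asc_in[0]),
                peak=int(pk),
                desc_zero=int(desc_in[0]),
                trough_end=int(b),
                mean_amplitude=float(amplitude[a:b].mean()),
            )
        )
        a = b
    return cycles


def detect_bouts(
    cycles: list[BetaCycle],
    rate: float,
    min_cycles: int = 5,
    amp_percentile: float = 50.0,
    region: str = "",
) -> list[BetaBout]:
    """Maximal runs of >= ``min_cycles`` consecutive above-threshold cycles.

    The amplitude threshold is the session-level ``amp_percentile`` of all
    cycle mean amplitudes.  Consecutive means each cycle's end trough is the
    next cycle's start trough.
    """
    if not cycles:
        return []
    amps = np.array([c.mean_amplitude for c in cycles])
    thresh = np.percentile(amps, amp_percentile)
    bouts: list[BetaBout] = []
    run: list[BetaCycle] = []

    def flush(run):
        if len(run) >= min_cycles:
            bouts.append(
                BetaBout(
                    start_s=run[0].trough_start / rate,
                    end_s=run[-1].trough_end / rate,
                    cycles=list(run),
                    region=region,
                )
            )

    for c in cycles:
        above = c.mean_amplitude > thresh
        if run and (not above or c.trough_start != run[-1].trough_end):
            flush(run)
            run = []
        if above:
            run.append(c)
    flush(run)
    return bouts


def bout_reference_troughs(
    bouts: list[BetaBout], rate: float, min_separation_s: float = 0.25
) -> np.ndarray:
    """One reference trough per bout: the trough of its highest-amplitude cycle.

    Troughs closer than ``min_separation_s`` are thinned greedily, keeping
    the earliest of each conflicting pair.
    """
    times = []
    for b in bouts:
        best = max(b.cycles, key=lambda c: c.mean_amplitude)
        times.append(best.trough_start / rate)
    times = np.sort(np.asarray(times))
    kept = []
    for t in times:
        if not kept or t - kept[-1] >= min_separation_s:
            kept.append(t)
    return np.asarray(kept)


# --------------------------------------------------------------------------
# phase-amplitude modulation


def phase_modulation(
    amplitude: np.ndarray, phase_4hz: np.ndarray, n_bins: int = 32
) -> tuple[float, float]:
    """Modulation strength and preferred phase of an amplitude by a phase.

    The amplitude is z-scored, averaged within ``n_bins`` equal phase bins;
    strength = max bin mean - min bin mean, preferred phase = centre of the
    max bin.  A constant amplitude returns strength 0 (with a warning); an
    empty phase bin raises.
    """
    amplitude = np.asarray(amplitude, dtype=float)
    phase_4hz = np.asarray(phase_4hz, dtype=float)
    if len(amplitude) != len(phase_4hz):
        raise ValueError("series length mismatch")
    sd = amplitude.std()
    if sd == 0:
        warnings.warn("constant amplitude: modulation strength 0 by convention", stacklevel=2)
        return 0.0, float("nan")
    z = (amplitude - amplitude.mean()) / sd
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    idx = np.clip(np.digitize(phase_4hz, edges) - 1, 0, n_bins - 1)
    means = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            raise ValueError(f"empty phase bin {b}; need longer data")
        means[b] = z[sel].mean()
    centers = 0.5 * (edges[:-1] + edges[1:])
    strength = float(means.max() - means.min())
    preferred = float(centers[int(np.argmax(means))])
    return strength, preferred


# --------------------------------------------------------------------------
# Morlet spectrograms


def default_freq_grid() -> np.ndarray:
    """2-100 Hz in 1-Hz steps plus 105-200 Hz in 5-Hz steps (119 frequencies)."""
    return np.concatenate([np.arange(2.0, 101.0, 1.0), np.arange(105.0, 201.0, 5.0)])


def morlet_spectrogram(
    lfp: np.ndarray, rate: float, freqs: np.ndarray | None = None, n_cycles: float = 6.0
) -> np.ndarray:
    """Time x frequency power via complex Morlet convolution of the z-scored LFP.

    Returns an (n_freqs, n_samples) array of squared moduli; wavelets are
    L2-normalised, width ``n_cycles`` cycles.
    """
    x = np.asarray(lfp, dtype=float)
    if freqs is None:
        freqs = default_freq_grid()
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs > rate / 2):
        raise ValueError("frequency above Nyquist")
    sd = x.std()
    z = (x - x.mean()) / sd if sd > 0 else x - x.mean()
    out = np.empty((len(freqs), len(z)))
    for k, f in enumerate(freqs):
        sigma_t = n_cycles / (2 * np.pi * f)
        half = int(np.ceil(4 * sigma_t * rate))
        t = np.arange(-half, half + 1) / rate
        wav = np.exp(2j * np.pi * f * t) * np.exp(-(t ** 2) / (2 * sigma_t ** 2))
        wav /= np.linalg.norm(wav)
        conv = fftconvolve(z, wav, mode="same")
        out[k] = np.abs(conv) ** 2
    return out


@dataclass
class TriggeredSpectralResponse:
    mean_by_condition: dict          # condition -> (n_freqs, n_window) z-scored grid
    freqs: np.ndarray
    lags_s: np.ndarray
    beta_summary: dict               # condition -> per-frequency z-power at reference time
    beta_reference_lag_s: float


def triggered_spectrogram(
    lfp: np.ndarray,
    rate: float,
    triggers_by_condition: dict,
    window_s: tuple = (-0.5, 0.5),
    freqs: np.ndarray | None = None,
    n_cycles: float = 6.0,
    beta_band: tuple = (15.0, 25.0),
) -> TriggeredSpectralResponse:
    """Trigger-averaged spectrograms per condition with joint z-scoring.

    Window-averaged responses are z-scored per frequency using the mean and
    SD pooled over all condition averages (the two LED zones).  The beta
    summary samples each condition's z-scored 15-25 Hz power at the
    cross-condition median lag of maximal beta power.
    """
    spec = morlet_spectrogram(lfp, rate, freqs, n_cycles)
    freqs = default_freq_grid() if freqs is None else np.asarray(freqs, dtype=float)
    i0 = int(round(window_s[0] * rate))
    i1 = int(round(window_s[1] * rate))
    lags = np.arange(i0, i1) / rate
    n = spec.shape[1]
    means = {}
    for cond, trig in triggers_by_condition.items():
        wins = []
        for t in np.atleast_1d(trig):
            c = int(round(t * rate))
            if c + i0 < 0 or c + i1 > n:
                continue
            wins.append(spec[:, c + i0 : c + i1])
        if not wins:
            raise ValueError(f"no valid triggers for condition {cond!r}")
        means[cond] = np.mean(wins, axis=0)
    # joint per-frequency z-scoring over all condition averages
    stacked = np.concatenate(list(means.values()), axis=1)
    mu = stacked.mean(axis=1, keepdims=True)
    sd = stacked.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    zmeans = {c: (m - mu) / sd for c, m in means.items()}
    # beta quantification at the cross-condition median time of beta maximum
    brows = (freqs >= beta_band[0]) & (freqs <= beta_band[1])
    peak_lags = [lags[int(np.argmax(m[brows].mean(axis=0)))] for m in zmeans.values()]
    ref_lag = float(np.median(peak_lags))
    ref_idx = int(np.argmin(np.abs(lags - ref_lag)))
    summary = {c: m[brows, ref_idx].copy() for c, m in zmeans.items()}
    return TriggeredSpectralResponse(
        mean_by_condition=zmeans,
        freqs=freqs,
        lags_s=lags,
        beta_summary=summary,
        beta_reference_lag_s=ref_lag,
    )


# --------------------------------------------------------------------------
# pulse-locked amplitude change


def pulse_locked_amplitude_change(
    beta_amplitude_z: np.ndarray,
    rate: float,
    pulse_onsets_s: np.ndarray,
    window_ms: float = 125.0,
) -> float:
    """Mean pulse-on (0..125 ms) minus pulse-off (-125..0 ms) z-amplitude.

    Averaged over all pulses with full context on both sides.
    """
    z = np.asarray(beta_amplitude_z, dtype=float)
    w = int(round(window_ms / 1000.0 * rate))
    diffs = []
    for t in np.atleast_1d(pulse_onsets_s):
        c = int(round(t * rate))
        if c - w < 0 or c + w > len(z):
            continue
        diffs.append(z[c : c + w].mean() - z[c - w : c].mean())
    if not diffs:
        raise ValueError("no pulses with full +/- window context")
    return float(np.mean(diffs))
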