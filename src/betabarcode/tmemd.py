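"""Masked empirical mode decomposition and the tailored mask-frequency search.

Standard EMD sifts a signal into intrinsic mode functions (IMFs) by repeatedly
subtracting the mean of its cubic-spline extrema envelopes.  With intermittent
oscillations (short beta bursts riding on slower rhythms) plain sifting mixes
modes; the masked variant adds a helper sinusoid at each sift level so the
first extracted IMF is pinned near the mask frequency, then averages over
several mask phases and subtracts the mask back out.

The "tailored" search (tmEMD) chooses mask frequencies by random search: at
each iteration a batch of candidate mask sets is drawn uniformly from the
current per-level frequency ranges, each candidate is scored by a mode-mixing
score (the absolute maximum of all pairwise IMF correlations, lower is
better), and the ranges are narrowed to the span of the best candidates.
When several subjects are decomposed at once a between-subject consistency
score is also computed, and the final mask set minimises the mean of its
mixing and consistency ranks.

Phase convention throughout the package: the analytic-signal phase of a
cosine, i.e. phase 0 at the oscillation peak and +/- pi at the trough.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert, welch


# --------------------------------------------------------------------------
# containers


@dataclass
class IMFSet:
    """Ordered IMFs (highest frequency first) plus the final residual.

    ``sum(imfs) + residual`` reconstructs the input to floating-point
    accuracy because each IMF is literally subtracted from the working
    signal during decomposition.
    """

    imfs: np.ndarray          # (n_imfs, n_samples)
    residual: np.ndarray      # (n_samples,)
    mask_freqs: np.ndarray    # Hz, one per sift level
    rate: float               # samples/s

    def __post_init__(self) -> None:
        self.imfs = np.atleast_2d(np.asarray(self.imfs, dtype=float))
        self.residual = np.asarray(self.residual, dtype=float)

    @property
    def n_imfs(self) -> int:
        return self.imfs.shape[0]

    def reconstruct(self) -> np.ndarray:
        return self.imfs.sum(axis=0) + self.residual

    def amplitude(self, k: int) -> np.ndarray:
        return analytic_amplitude_phase(self.imfs[k])[0]

    def phase(self, k: int) -> np.ndarray:
        return analytic_amplitude_phase(self.imfs[k])[1]


@dataclass
class MaskSearchState:
    """Bookkeeping for one iteration of the tailored mask search."""

    iteration: int
    candidates: np.ndarray             # (n_candidates, n_levels) Hz
    mixing_scores: np.ndarray          # (n_candidates,)
    consistency_scores: np.ndarray | None
    ranges: list[tuple[float, float]] = field(default_factory=list)


# --------------------------------------------------------------------------
# sifting


def _extrema_indices(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima (plateau-safe simple comparison)."""
    dx = np.diff(x)
    # sign of slope; treat zeros by carrying the previous sign forward
    s = np.sign(dx)
    nz = s != 0
    if not nz.any():
        return np.array([], dtype=int), np.array([], dtype=int)
    # forward-fill zero slopes
    idx = np.where(nz, np.arange(len(s)), 0)
    np.maximum.accumulate(idx, out=idx)
    s = s[idx]
    turn = np.diff(s)
    maxima = np.where(turn < 0)[0] + 1
    minima = np.where(turn > 0)[0] + 1
    return maxima, minima


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through ``x[idx]`` with mirrored edge knots."""
    n = len(x)
    t = idx.astype(float)
    v = x[idx]
    # mirror the two outermost extrema about the signal edges so the spline
    # does not diverge near the boundaries
    t_ext = np.concatenate(([-t[1], -t[0]], t, [2 * (n - 1) - t[-1], 2 * (n - 1) - t[-2]])) \
        if len(t) >= 2 else t
    v_ext = np.concatenate(([v[1], v[0]], v, [v[-1], v[-2]])) if len(v) >= 2 else v
    order = np.argsort(t_ext)
    t_ext, v_ext = t_ext[order], v_ext[order]
    # drop duplicate knots (can occur when an extremum sits on an edge)
    keep = np.concatenate(([True], np.diff(t_ext) > 0))
    cs = CubicSpline(t_ext[keep], v_ext[keep])
    return cs(np.arange(n))


def sift_first_imf(x: np.ndarray, n_iters: int = 8) -> np.ndarray:
    """Extract the first IMF by fixed-count envelope-mean subtraction.

    A fixed inner iteration count (default 8) is used as the stop criterion;
    it is deterministic and avoids the ambiguity of SD-threshold rules.
    """
    h = np.asarray(x, dtype=float).copy()
    for _ in range(n_iters):
        maxima, minima = _extrema_indices(h)
        if len(maxima) < 2 or len(minima) < 2:
            break
        upper = _envelope(h, maxima)
        lower = _envelope(h, minima)
        h = h - 0.5 * (upper + lower)
    return h


def masked_sift(
    signal: np.ndarray,
    rate: float,
    mask_freqs,
    mask_amp_factor: float = 2.0,
    n_phases: int = 4,
    max_sift_iters: int = 8,
) -> IMFSet:
    """Decompose ``signal`` with one masked sift level per mask frequency.

    At level k a mask sinusoid at ``mask_freqs[k]`` (amplitude =
    ``mask_amp_factor`` times the SD of the current working signal) is added
    at ``n_phases`` equally spaced phases; each masked signal is sifted to
    its first IMF, the mask is subtracted back out, and the phase-averaged
    result becomes IMF k.  Mask frequencies must be descending and below the
    Nyquist frequency.
    """
    x = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    mask_freqs = np.asarray(mask_freqs, dtype=float)
    if mask_freqs.ndim != 1 or len(mask_freqs) == 0:
        raise ValueError("mask_freqs must be a non-empty 1-D sequence")
    if np.any(mask_freqs >= rate / 2):
        raise ValueError("mask frequency at or above Nyquist")
    if np.any(np.diff(mask_freqs) > 0):
        raise ValueError("mask_freqs must be descending")

    t = np.arange(len(x)) / rate
    working = x.copy()
    imfs = []
    for f in mask_freqs:
        amp = mask_amp_factor * working.std()
        if amp == 0:
            imfs.append(np.zeros_like(working))
            continue
        acc = np.zeros_like(working)
        for p in range(n_phases):
            theta = 2 * np.pi * p / n_phases
            mask = amp * np.cos(2 * np.pi * f * t + theta)
            first = sift_first_imf(working + mask, n_iters=max_sift_iters)
            acc += first - mask
        imf = acc / n_phases
        imfs.append(imf)
        working = working - imf
    return IMFSet(imfs=np.array(imfs), residual=working, mask_freqs=mask_freqs, rate=rate)


# --------------------------------------------------------------------------
# scores


def mixing_score(imfs: np.ndarray) -> float:
    """Absolute maximum of all pairwise Pearson correlations between IMFs.

    Zero-variance IMFs are skipped (with a warning); if every pair is
    degenerate a ``ValueError`` is raised.
    """
    imfs = np.atleast_2d(np.asarray(imfs, dtype=float))
    k = imfs.shape[0]
    if k < 2:
        raise ValueError("need at least 2 IMFs")
    sd = imfs.std(axis=1)
    best = None
    skipped = False
    for i in range(k):
        for j in range(i + 1, k):
            if sd[i] == 0 or sd[j] == 0:
                skipped = True
                continue
            r = np.corrcoef(imfs[i], imfs[j])[0, 1]
            a = abs(r)
            if best is None or a > best:
                best = a
    if skipped:
        warnings.warn("constant IMF skipped in mixing score", stacklevel=2)
    if best is None:
        raise ValueError("all IMF pairs degenerate (zero variance)")
    return float(best)


def _zscored_psds(imf_set: IMFSet, nperseg_s: float = 2.0) -> np.ndarray:
    """Per-IMF Welch PSD, z-scored across the frequency grid."""
    nper = min(int(nperseg_s * imf_set.rate), imf_set.imfs.shape[1])
    _, psd = welch(imf_set.imfs, fs=imf_set.rate, nperseg=nper, axis=1)
    mu = psd.mean(axis=1, keepdims=True)
    sd = psd.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (psd - mu) / sd


def consistency_score(imf_sets: list[IMFSet], nperseg_s: float = 2.0) -> float:
    """Between-subject spectral consistency of the decompositions.

    Defined as the mean across IMF levels of the mean pairwise Pearson
    correlation between subjects' z-scored IMF power spectral densities.
    This is a documented default definition: it rewards mask sets that send
    the same spectral content to the same level in every subject.
    """
    if len(imf_sets) < 2:
        raise ValueError("need at least 2 subjects")
    n_imfs = {s.n_imfs for s in imf_sets}
    if len(n_imfs) != 1:
        raise ValueError("subjects have mismatched IMF counts")
    psds = [_zscored_psds(s, nperseg_s) for s in imf_sets]
    n_lvl = imf_sets[0].n_imfs
    n_sub = len(imf_sets)
    level_means = []
    for lvl in range(n_lvl):
        rs = []
        for a in range(n_sub):
            for b in range(a + 1, n_sub):
                pa, pb = psds[a][lvl], psds[b][lvl]
                if pa.std() == 0 or pb.std() == 0:
                    continue
                rs.append(np.corrcoef(pa, pb)[0, 1])
        if rs:
            level_means.append(np.mean(rs))
    if not level_means:
        raise ValueError("no valid level correlations")
    return float(np.mean(level_means))


# --------------------------------------------------------------------------
# tailored mask search


def tmemd_optimize(
    signals_per_subject: list[np.ndarray],
    rate: float,
    init_ranges: list[tuple[float, float]],
    n_candidates: int = 200,
    top_k: int = 10,
    n_iters: int = 3,
    seed: int = 0,
    mask_amp_factor: float = 2.0,
    n_phases: int = 4,
    max_sift_iters: int = 8,
) -> tuple[np.ndarray, list[MaskSearchState]]:
    """Random-search selection of per-level mask frequencies.

    Per iteration: sample ``n_candidates`` mask sets uniformly within the
    current per-level ranges, decompose every subject with each set, score
    by mean mixing (and by between-subject consistency when more than one
    subject is given), then restrict the ranges to the span of the ``top_k``
    candidates by mixing score.  The final selection pools every evaluated
    candidate and minimises the mean of its mixing rank (ascending) and
    consistency rank (descending); with a single subject only the mixing
    rank is used.  Deterministic under ``seed``.
    """
    if not signals_per_subject:
        raise ValueError("need at least one subject signal")
    for lo, hi in init_ranges:
        if lo >= hi:
            raise ValueError(f"degenerate frequency range ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    ranges = [tuple(map(float, r)) for r in init_ranges]
    n_levels = len(ranges)
    multi = len(signals_per_subject) > 1

    history: list[MaskSearchState] = []
    all_cands, all_mix, all_cons = [], [], []

    for it in range(n_iters):
        lows = np.array([r[0] for r in ranges])
        highs = np.array([r[1] for r in ranges])
        cands = rng.uniform(lows, highs, size=(n_candidates, n_levels))
        cands = -np.sort(-cands, axis=1)  # descending mask frequencies per set
        mix = np.empty(n_candidates)
        cons = np.empty(n_candidates) if multi else None
        for c in range(n_candidates):
            sets = [
                masked_sift(sig, rate, cands[c], mask_amp_factor, n_phases, max_sift_iters)
                for sig in signals_per_subject
            ]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mix[c] = np.mean([mixing_score(s.imfs) for s in sets])
            if multi:
                cons[c] = consistency_score(sets)
        history.append(
            MaskSearchState(
                iteration=it,
                candidates=cands,
                mixing_scores=mix,
                consistency_scores=None if cons is None else cons.copy(),
                ranges=list(ranges),
            )
        )
        all_cands.append(cands)
        all_mix.append(mix)
        if multi:
            all_cons.append(cons)
        # narrow each level's range to the span of the top-k mixing scores
        top = np.argsort(mix)[:top_k]
        new_ranges = []
        for lvl in range(n_levels):
            vals = cands[top, lvl]
            lo, hi = float(vals.min()), float(vals.max())
            if hi - lo < 1e-9:  # keep the range samplable
                pad = max(1e-3, 1e-3 * hi)
                lo, hi = lo - pad, hi + pad
            new_ranges.append((lo, hi))
        ranges = new_ranges

    cands = np.concatenate(all_cands, axis=0)
    mix = np.concatenate(all_mix)
    if multi:
        cons = np.concatenate(all_cons)
        mix_rank = np.argsort(np.argsort(mix))            # low mixing -> low rank
        cons_rank = np.argsort(np.argsort(-cons))         # high consistency -> low rank
        score = 0.5 * (mix_rank + cons_rank)
    else:
        score = np.argsort(np.argsort(mix)).astype(float)
    best = int(np.argmin(score))
    return cands[best], history


def best_mixing_trajectory(history: list[MaskSearchState]) -> np.ndarray:
    """Best-so-far (elitist) mixing score after each iteration; non-increasing."""
    best = np.inf
    out = []
    for st in history:
        best = min(best, float(st.mixing_scores.min()))
        out.append(best)
    return np.array(out)


# --------------------------------------------------------------------------
# channel selection and analytic signal helpers


def select_reference_channel(psd_per_channel: np.ndarray, median_psd: np.ndarray) -> int:
    """Channel whose (z-scored) PSD is L2-closest to the cross-animal median.

    Ties break to the lowest index.
    """
    psd_per_channel = np.atleast_2d(np.asarray(psd_per_channel, dtype=float))
    median_psd = np.asarray(median_psd, dtype=float)
    if psd_per_channel.shape[0] == 0:
        raise ValueError("empty channel set")
    if psd_per_channel.shape[1] != len(median_psd):
        raise ValueError("frequency grid mismatch")
    d = np.linalg.norm(psd_per_channel - median_psd[None, :], axis=1)
    return int(np.argmin(d))


def zscore_psd(x: np.ndarray, rate: float, nperseg_s: float = 2.0):
    """Welch PSD (2-s windows, 50% overlap) z-scored across frequency."""
    nper = min(int(nperseg_s * rate), len(x))
    f, psd = welch(x, fs=rate, nperseg=nper)
    sd = psd.std()
    if sd == 0:
        return f, np.zeros_like(psd)
    return f, (psd - psd.mean()) / sd


def analytic_amplitude_phase(imf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous amplitude and phase from the analytic signal.

    Phase lies in (-pi, pi] and is 0 at the peak of a cosine component.
    """
    imf = np.asarray(imf, dtype=float)
    if not np.all(np.isfinite(imf)):
        raise ValueError("non-finite input")
    a = hilbert(imf)
    return np.abs(a), np.angle(a)


def instantaneous_frequency(imf: np.ndarray, rate: float) -> np.ndarray:
    """Phase-derivative instantaneous frequency in Hz (same length as input)."""
    _, phase = analytic_amplitude_phase(imf)
    f = np.diff(np.unwrap(phase)) * rate / (2 * np.pi)
    return np.concatenate([f[:1], f])


def weighted_mean_frequency(imf: np.ndarray, rate: float) -> float:
    """Amplitude-squared-weighted mean instantaneous frequency (Hz)."""
    amp, _ = analytic_amplitude_phase(imf)
    f = instantaneous_frequency(imf, rate)
    w = amp ** 2
    if w.sum() == 0:
        return float("nan")
    return float(np.sum(w * f) / w.sum())


def pick_imf_near(imf_set: IMFSet, target_hz: float) -> int:
    """Index of the IMF whose weighted mean frequency is nearest ``target_hz``."""
    freqs = [weighted_mean_frequency(imf_set.imfs[k], imf_set.rate) for k in range(imf_set.n_imfs)]
    return int(np.nanargmin(np.abs(np.asarray(freqs) - target_hz)))


def select_training_window(
    speed: np.ndarray, speed_rate: float, window_s: float = 300.0, thresh: float = 2.0
) -> tuple[float, float]:
    """Start/end (s) of the window with the highest proportion of speed > thresh.

    Sliding-window argmax over the locomotion indicator; ties take the
    earliest window.  Used to pick the 5-min training segment for the mask
    search during active exploration.
    """
    speed = np.asarray(speed, dtype=float)
    w = int(round(window_s * speed_rate))
    if w <= 0 or w > len(speed):
        raise ValueError("window longer than recording")
    moving = (speed > thresh).astype(float)
    csum = np.concatenate([[0.0], np.cumsum(moving)])
    frac = (csum[w:] - csum[:-w]) / w
    i0 = int(np.argmax(frac))  # argmax returns the first maximum
    return i0 / speed_rate, (i0 + w) / speed_rate
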