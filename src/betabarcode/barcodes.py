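"""Cross-network co-engagement "barcodes": ICA motifs over cross-IMF pairs.

Given K oscillatory components (IMFs) pooled over all regions, the
instantaneous co-engagement vector x_t holds the K(K-1)/2 unique bipartite
products a_i * a_j (i < j) of their instantaneous amplitudes.  Independent
Component Analysis on x_t vectors sampled every 250 ms (from SD-normalised
amplitudes) yields weight vectors -- the barcodes -- each describing a motif
of co-occurring oscillatory activities.  A barcode's strength at time t is
the dot product of its weight vector with the co-engagement vector built
from the NON-normalised amplitudes at the full LFP rate.

The cocaine-paired memory retrieval (CPMR) score of a barcode is the dot
product of its per-stage cocaine-minus-saline zone effect sizes (on 1-s
binned, per-stage z-scored strength during locomotion) with the binary stage
vector (0, 1, 0, 1) for (pre-test, recall, extinction, renewal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import FastICA

from .eststats import cohens_d

STAGE_VECTOR = {"pre-test": 0.0, "recall": 1.0, "extinction": 0.0, "renewal": 1.0}


def pair_index(n_imfs: int) -> list[tuple[int, int]]:
    """Ordered map: co-engagement element m -> (IMF i, IMF j), i < j."""
    if n_imfs < 2:
        raise ValueError("need at least 2 IMFs")
    iu, ju = np.triu_indices(n_imfs, k=1)
    return list(zip(iu.tolist(), ju.tolist()))


def coengagement(a_t: np.ndarray) -> np.ndarray:
    """Upper off-diagonal of the outer product of the amplitude vector.

    Length K(K-1)/2; element m is a_i * a_j for the m-th (i < j) pair.
    """
    a_t = np.asarray(a_t, dtype=float)
    if a_t.ndim != 1 or len(a_t) < 2:
        raise ValueError("need an amplitude vector of length >= 2")
    iu, ju = np.triu_indices(len(a_t), k=1)
    return a_t[iu] * a_t[ju]


def build_feature_matrix(amplitudes: np.ndarray, rate: float, step_s: float = 0.25) -> np.ndarray:
    """Samples x pairs matrix of co-engagement vectors at ``step_s`` strides.

    Each amplitude series is first divided by its own standard deviation
    (unit variance); a zero-variance amplitude raises, naming the IMF.
    """
    amplitudes = np.atleast_2d(np.asarray(amplitudes, dtype=float))
    sd = amplitudes.std(axis=1)
    for k, s in enumerate(sd):
        if s == 0:
            raise ValueError(f"IMF {k} amplitude has zero variance")
    norm = amplitudes / sd[:, None]
    # time-based sampling: exact even when step_s * rate is non-integer
    step = step_s * rate
    n_steps = int(amplitudes.shape[1] / step)
    idx = (np.arange(n_steps) * step).astype(int)
    sampled = norm[:, idx].T               # (n_samples, K)
    iu, ju = np.triu_indices(amplitudes.shape[0], k=1)
    return sampled[:, iu] * sampled[:, ju]


@dataclass
class BarcodeSet:
    """ICA weight vectors over cross-IMF pairs plus the shared pair index."""

    weights: np.ndarray                 # (n_components, n_pairs)
    pairs: list                         # element -> (i, j)
    n_imfs: int
    fit_step_s: float = 0.25

    @property
    def n_components(self) -> int:
        return self.weights.shape[0]


def extract_barcodes(feature_matrix: np.ndarray, n_components: int = 30, seed: int = 0) -> BarcodeSet:
    """FastICA (parallel fixed-point, whitened) on the co-engagement matrix.

    The sign of each weight vector is flipped so its largest-magnitude
    element is positive.  Deterministic under ``seed``.
    """
    X = np.asarray(feature_matrix, dtype=float)
    if X.shape[0] < n_components:
        raise ValueError(
            f"{X.shape[0]} samples < {n_components} components; lower n_components"
        )
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if rank < n_components:
        raise ValueError(
            f"feature matrix rank {rank} below n_components={n_components}; lower n_components"
        )
    ica = FastICA(
        n_components=n_components,
        algorithm="parallel",
        whiten="unit-variance",
        random_state=seed,
        max_iter=1000,
        tol=1e-4,
    )
    ica.fit(X)
    W = ica.components_.copy()
    for k in range(W.shape[0]):
        m = np.argmax(np.abs(W[k]))
        if W[k, m] < 0:
            W[k] = -W[k]
    n_pairs = X.shape[1]
    K = int((1 + np.sqrt(1 + 8 * n_pairs)) / 2)  # invert n_pairs = K(K-1)/2
    return BarcodeSet(weights=W, pairs=pair_index(K), n_imfs=K)


def barcode_strength(w: np.ndarray, amplitudes: np.ndarray) -> np.ndarray:
    """Strength time series <w, x_t> from NON-normalised amplitudes.

    ``amplitudes`` is (K, n_samples) at the original resolution (1250 Hz for
    tracking); computed as a quadratic form to avoid materialising the full
    pair matrix.
    """
    w = np.asarray(w, dtype=float)
    A = np.atleast_2d(np.asarray(amplitudes, dtype=float))
    K = A.shape[0]
    if len(w) != K * (K - 1) // 2:
        raise ValueError("weight length does not match pair count")
    M = barcode_matrix(w)                     # symmetric, zero diagonal
    return 0.5 * np.sum(A * (M @ A), axis=0)  # = sum_{i<j} w_ij a_i a_j


def barcode_matrix(w: np.ndarray) -> np.ndarray:
    """Square symmetric motif matrix (zero diagonal) from a weight vector."""
    w = np.asarray(w, dtype=float)
    n_pairs = len(w)
    K = int((1 + np.sqrt(1 + 8 * n_pairs)) / 2)
    if K * (K - 1) // 2 != n_pairs:
        raise ValueError(f"length {n_pairs} is not K(K-1)/2 for integer K")
    M = np.zeros((K, K))
    iu, ju = np.triu_indices(K, k=1)
    M[iu, ju] = w
    M[ju, iu] = w
    return M


def matrix_to_vector(M: np.ndarray) -> np.ndarray:
    """Inverse of :func:`barcode_matrix` (upper off-diagonal, row-major)."""
    M = np.asarray(M, dtype=float)
    iu, ju = np.triu_indices(M.shape[0], k=1)
    return M[iu, ju]


def band_contribution(w: np.ndarray, mask: np.ndarray) -> float:
    """<mask, w> / sum(mask): mean weight over the masked pair elements."""
    w = np.asarray(w, dtype=float)
    mask = np.asarray(mask, dtype=float)
    if mask.shape != w.shape:
        raise ValueError("mask/weight length mismatch")
    s = mask.sum()
    if s == 0:
        raise ValueError("empty band mask")
    return float(np.dot(mask, w) / s)


def band_mask(pairs: list, imf_band: np.ndarray, band: str) -> np.ndarray:
    """Binary pair mask: 1 where either member IMF belongs to ``band``.

    ``imf_band`` maps IMF index -> band label (e.g. 'beta', 'gamma').
    """
    return np.array(
        [1.0 if (imf_band[i] == band or imf_band[j] == band) else 0.0 for i, j in pairs]
    )


# --------------------------------------------------------------------------
# CPMR score


def binned_zone_strength(
    strength: np.ndarray,
    rate: float,
    stage_bounds: pd.DataFrame,
    zone_intervals: pd.DataFrame,
    speed: np.ndarray,
    speed_rate: float,
    bin_s: float = 1.0,
    speed_thresh: float = 2.0,
) -> pd.DataFrame:
    """Per-stage z-scored strength in 1-s locomotion bins, labelled by zone.

    Strength is z-scored within each stage before binning; a bin is kept if
    the animal's median speed in it exceeds ``speed_thresh`` and it is
    assigned to the zone occupied for the majority of the bin.
    """
    rows = []
    for _, srow in stage_bounds.iterrows():
        stage, s0, s1 = srow["stage"], srow["t_start"], srow["t_end"]
        i0_, i1_ = int(s0 * rate), int(s1 * rate)
        seg = strength[i0_:i1_]
        sd = seg.std()
        z = (seg - seg.mean()) / sd if sd > 0 else np.zeros_like(seg)
        n_bins = int((s1 - s0) // bin_s)
        ziv = zone_intervals[zone_intervals["stage"] == stage]
        per_bin = int(bin_s * rate)
        for b in range(n_bins):
            t0 = s0 + b * bin_s
            t1 = t0 + bin_s
            j0, j1 = int(t0 * speed_rate), int(t1 * speed_rate)
            if j1 > len(speed) or np.median(speed[j0:j1]) <= speed_thresh:
                continue
            # majority-occupancy zone assignment
            occ = {"cocaine": 0.0, "saline": 0.0}
            for _, zrow in ziv.iterrows():
                ov = min(t1, zrow["t_end"]) - max(t0, zrow["t_start"])
                if ov > 0:
                    occ[zrow["zone"]] += ov
            zone = max(occ, key=occ.get)
            if occ[zone] <= bin_s / 2:
                continue
            k0 = b * per_bin
            rows.append((stage, zone, float(z[k0 : k0 + per_bin].mean())))
    return pd.DataFrame(rows, columns=["stage", "zone", "strength"])


def cpmr_score(binned: pd.DataFrame, effect_size_fn=cohens_d, stages=None) -> float:
    """Dot product of per-stage (cocaine - saline) effect sizes with (0,1,0,1).

    ``binned`` is the output of :func:`binned_zone_strength`; every stage
    must have samples in both zones.
    """
    stages = list(stages) if stages is not None else list(STAGE_VECTOR)
    score = 0.0
    for stage in stages:
        sub = binned[binned["stage"] == stage]
        a = sub.loc[sub["zone"] == "cocaine", "strength"].to_numpy()
        b = sub.loc[sub["zone"] == "saline", "strength"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"stage {stage!r} missing zone samples")
        score += STAGE_VECTOR.get(stage, 0.0) * effect_size_fn(a, b)
    return float(score)


def cpmr_scores_for_set(
    barcode_set: BarcodeSet,
    amplitudes: np.ndarray,
    rate: float,
    stage_bounds: pd.DataFrame,
    zone_intervals: pd.DataFrame,
    speed: np.ndarray,
    speed_rate: float,
    effect_size_fn=cohens_d,
) -> np.ndarray:
    """CPMR score for every barcode in a set (shared binning machinery)."""
    scores = np.empty(barcode_set.n_components)
    for k in range(barcode_set.n_components):
        s = barcode_strength(barcode_set.weights[k], amplitudes)
        binned = binned_zone_strength(
            s, rate, stage_bounds, zone_intervals, speed, speed_rate
        )
        scores[k] = cpmr_score(binned, effect_size_fn)
    return scores
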