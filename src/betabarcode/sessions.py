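"""Synthetic multi-region recording sessions and behavioral preference scores.

The generator emulates the statistical structure the downstream analyses
assume for a mouse performing a four-stage conditioned cue-place preference
test (pre-test, recall, extinction, renewal) with simultaneous LFP and
spike-train recordings from PFC, NAc, Amy, Hpc and VTA:

* a 4-Hz oscillation in VTA (attenuated copy in Hpc) whose phase gates the
  occurrence of transient beta (15-25 Hz) bursts in the other regions
  (phase-amplitude coupling with configurable depth and preferred phase);
* continuous low-amplitude gamma-band components and 1/f^alpha background;
* beta bursts amplified in the cocaine-paired LED zone by a per-stage
  multiplicative gain (the planted memory-retrieval effect);
* spike trains generated as inhomogeneous Poisson processes phase-locked
  (von Mises concentration kappa) to a chosen oscillation;
* zone occupancy, LED activation and laser-pulse event streams, and a
  reflected Ornstein-Uhlenbeck speed trace at the 39-Hz tracking rate.

Every planted quantity is written to a :class:`GroundTruthManifest` so the
analysis pipeline can be tested by parameter recovery.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, hilbert
from scipy.special import i0

DEFAULT_REGIONS = ("PFC", "NAc", "Amy", "Hpc", "VTA")
BETA_REGIONS = ("PFC", "NAc", "Amy", "Hpc")
STAGES = ("pre-test", "recall", "extinction", "renewal")
BETA_FREQ = 20.0       # Hz, burst carrier (centre of the 15-25 Hz band)
SLOW_FREQ = 4.0        # Hz, pacing oscillation
GAMMA_FREQS = (40.0, 65.0, 100.0)
GAMMA_AMPS = (0.25, 0.2, 0.15)
TRACKING_RATE = 39.0   # camera frames per second


@dataclass
class UnitSpec:
    """One synthetic unit: where it sits and what it locks to."""

    region: str
    target: str            # 'vta4', 'beta', or 'none'
    kappa: float
    base_rate: float       # Hz
    pref_phase: float      # rad


def default_units(rng: np.random.Generator, per_region: int = 12) -> list[UnitSpec]:
    """Mixed population: per region, 1/3 beta-locked, 1/3 4-Hz-locked, 1/3 unlocked."""
    units = []
    for region in DEFAULT_REGIONS:
        for u in range(per_region):
            kind = u % 3
            if kind == 0:
                target, kappa = ("beta", 2.0) if region != "VTA" else ("vta4", 2.5)
            elif kind == 1:
                target, kappa = "vta4", 2.0
            else:
                target, kappa = "none", 0.0
            units.append(
                UnitSpec(
                    region=region,
                    target=target,
                    kappa=kappa,
                    base_rate=float(rng.uniform(3.0, 8.0)),
                    pref_phase=float(rng.uniform(-np.pi, np.pi)),
                )
            )
    return units


@dataclass
class SessionSpec:
    """Generative parameters of one synthetic session.

    Defaults reproduce the recording conditions the analyses were designed
    for: 1250 samples/s LFP, four 20-minute test stages, five regions, and a
    4-Hz -> beta phase-amplitude coupling of depth 0.8 with the preferred
    phase on the descending slope of the 4-Hz cycle (phase 0 = peak,
    +/- pi = trough).
    """

    regions: tuple = DEFAULT_REGIONS
    lfp_rate: float = 1250.0
    duration_s: float = 1200.0          # per stage
    stages: tuple = STAGES
    pac_depth: float | dict = 0.8
    pac_phase: float | dict = field(default_factory=lambda: {"PFC": 2.6, "NAc": 2.6, "Amy": 2.6, "Hpc": 2.0})
    burst_rate: float = 0.5             # cross-network burst events per second (free parameter)
    burst_sync: float = 0.9             # probability each event expresses in a region
    burst_jitter_s: float = 0.03        # per-region jitter of the shared event time
    beta_amp: float = 1.0
    zone_effect: dict = field(
        default_factory=lambda: {"pre-test": 1.0, "recall": 1.5, "extinction": 1.0, "renewal": 1.5}
    )
    spike_lock: list | None = None      # list[UnitSpec]; None -> default_units
    noise_exponent: float = 1.0
    noise_std: float = 0.5
    vta4_amp: float = 1.0
    hpc4_amp: float = 0.4
    zone_dwell_s: float = 8.0
    off_dwell_s: float = 6.0
    zone_bias: dict = field(
        default_factory=lambda: {"pre-test": 1.0, "recall": 1.8, "extinction": 1.0, "renewal": 1.8}
    )
    led_rate_hz: float = 0.1            # LED activations per second while inside a zone
    n_laser_pulses: int = 0
    laser_interval_s: tuple = (1.0, 10.0)
    seed: int = 0

    def pac_depth_for(self, region: str) -> float:
        d = self.pac_depth[region] if isinstance(self.pac_depth, dict) else self.pac_depth
        return float(d)

    def pac_phase_for(self, region: str) -> float:
        p = self.pac_phase[region] if isinstance(self.pac_phase, dict) else self.pac_phase
        return float(p)

    def validate(self) -> None:
        for region in self.regions:
            if region in BETA_REGIONS:
                d = self.pac_depth_for(region)
                if not 0.0 <= d <= 1.0:
                    raise ValueError(f"pac_depth for {region} outside [0, 1]: {d}")
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("stage labels must be unique")
        if self.lfp_rate <= 2 * max(GAMMA_FREQS):
            raise ValueError("lfp_rate must exceed twice the highest component frequency")
        if self.burst_rate * self.duration_s < 1 and any(r in BETA_REGIONS for r in self.regions):
            raise ValueError("duration too short to contain at least one beta burst")

    def planted_component_freqs(self, region: str) -> list[float]:
        """Oscillatory component frequencies planted in one region's LFP."""
        freqs = list(GAMMA_FREQS)
        if region in BETA_REGIONS and region in self.regions:
            freqs.append(BETA_FREQ)
        if region == "VTA":
            freqs.append(SLOW_FREQ)
        if region == "Hpc":
            freqs.append(SLOW_FREQ)
        return sorted(freqs, reverse=True)


@dataclass
class SessionRecording:
    """Universal input container: per-region LFPs, spikes, speed and events."""

    lfp: dict                       # region -> float array at lfp_rate
    lfp_rate: float
    spike_times: dict               # unit_id -> strictly increasing times (s)
    units: pd.DataFrame             # unit_id, region, gt_class
    speed: np.ndarray               # cm/s at speed_rate
    speed_rate: float
    events: pd.DataFrame            # time_s, kind, zone, stage
    stage_bounds: pd.DataFrame      # stage, t_start, t_end

    def validate(self) -> None:
        for uid, st in self.spike_times.items():
            if len(st) > 1 and not np.all(np.diff(st) > 0):
                raise ValueError(f"spike times not strictly increasing for unit {uid}")
        if np.any(self.speed < 0):
            raise ValueError("speed must be non-negative")
        t0 = self.stage_bounds["t_start"].min()
        t1 = self.stage_bounds["t_end"].max()
        if len(self.events) and (
            self.events["time_s"].min() < t0 - 1e-9 or self.events["time_s"].max() > t1 + 1e-9
        ):
            raise ValueError("event times outside stage bounds")

    # -- session container on disk (manifest.json + flat f32 + csv) --------

    def save_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {
            "regions": list(self.lfp.keys()),
            "lfp_rate": self.lfp_rate,
            "speed_rate": self.speed_rate,
            "stage_bounds": self.stage_bounds.to_dict(orient="records"),
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
        for region, x in self.lfp.items():
            np.asarray(x, dtype="<f4").tofile(path / f"lfp_{region}.f32")
        np.asarray(self.speed, dtype="<f4").tofile(path / "speed.f32")
        rows = []
        region_of = dict(zip(self.units["unit_id"], self.units["region"]))
        for uid, st in self.spike_times.items():
            for t in st:
                rows.append((uid, region_of[uid], t))
        pd.DataFrame(rows, columns=["unit_id", "region", "time_s"]).to_csv(
            path / "spikes.csv", index=False
        )
        self.events.to_csv(path / "events.csv", index=False)
        self.units.to_csv(path / "units.csv", index=False)

    @classmethod
    def load_dir(cls, path) -> "SessionRecording":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        lfp = {
            r: np.fromfile(path / f"lfp_{r}.f32", dtype="<f4").astype(float)
            for r in manifest["regions"]
        }
        speed = np.fromfile(path / "speed.f32", dtype="<f4").astype(float)
        spikes = pd.read_csv(path / "spikes.csv")
        units = pd.read_csv(path / "units.csv")
        spike_times = {
            int(uid): grp["time_s"].to_numpy()
            for uid, grp in spikes.groupby("unit_id")
        }
        for uid in units["unit_id"]:
            spike_times.setdefault(int(uid), np.array([]))
        events = pd.read_csv(path / "events.csv")
        return cls(
            lfp=lfp,
            lfp_rate=manifest["lfp_rate"],
            spike_times=spike_times,
            units=units,
            speed=speed,
            speed_rate=manifest["speed_rate"],
            events=events,
            stage_bounds=pd.DataFrame(manifest["stage_bounds"]),
        )


@dataclass
class GroundTruthManifest:
    """Planted parameters of a synthetic session, for recovery tests."""

    burst_intervals: dict           # region -> (n, 3) array of (t0, t1, amp)
    pac: dict                       # region -> (depth, preferred phase)
    unit_params: pd.DataFrame       # unit_id, region, target, kappa, pref_phase, base_rate
    zone_effect: dict               # stage -> gain
    zone_intervals: pd.DataFrame    # stage, zone, t_start, t_end
    beta_phase: dict                # region -> planted beta analytic phase series
    beta_envelope: dict             # region -> planted beta envelope series
    slow_phase_freq: float          # Hz of the pacing oscillation
    seed: int

    def slow_phase(self, t: np.ndarray) -> np.ndarray:
        """Analytic phase of the planted 4-Hz oscillation (cosine convention)."""
        return np.angle(np.exp(1j * 2 * np.pi * self.slow_phase_freq * np.asarray(t)))


# --------------------------------------------------------------------------
# generation


def _pink_noise(rng: np.random.Generator, n: int, exponent: float, std: float) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x * (std / sd) if sd > 0 else x


def _zone_schedule(rng, stage, t0, t1, spec) -> list[tuple[float, float, str]]:
    """Alternating zone visits separated by off-zone epochs.

    The animal shuttles between the two LED zones; the per-stage bias
    lengthens cocaine-zone dwells (preference expressed as extra time, not
    skipped visits), so both zones are sampled in every stage.
    """
    bias = spec.zone_bias.get(stage, 1.0)
    zone = "cocaine" if rng.random() < 0.5 else "saline"
    out = []
    t = t0 + rng.exponential(spec.off_dwell_s / 2)
    while t < t1:
        mean_dwell = spec.zone_dwell_s * (bias if zone == "cocaine" else 1.0)
        dwell = rng.exponential(mean_dwell)
        end = min(t + dwell, t1)
        if end - t > 0.5:
            out.append((t, end, zone))
        zone = "saline" if zone == "cocaine" else "cocaine"
        t = end + rng.exponential(spec.off_dwell_s)
    return out


def _zone_at(zone_iv: list[tuple[float, float, str]], t: float) -> str | None:
    for a, b, z in zone_iv:
        if a <= t < b:
            return z
    return None


def generate_session(spec: SessionSpec) -> tuple[SessionRecording, GroundTruthManifest]:
    """Generate one synthetic session and its ground-truth manifest.

    Bit-identical output for identical ``spec`` (including ``seed``).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    fs = spec.lfp_rate
    n_stage = int(round(spec.duration_s * fs))
    n_total = n_stage * len(spec.stages)
    t_all = np.arange(n_total) / fs
    phi4 = 2 * np.pi * SLOW_FREQ * t_all  # unwrapped planted 4-Hz phase

    stage_bounds = pd.DataFrame(
        {
            "stage": list(spec.stages),
            "t_start": [k * spec.duration_s for k in range(len(spec.stages))],
            "t_end": [(k + 1) * spec.duration_s for k in range(len(spec.stages))],
        }
    )

    # ---- zone occupancy and events per stage
    zone_rows, event_rows = [], []
    zone_iv_by_stage = {}
    for _, row in stage_bounds.iterrows():
        iv = _zone_schedule(rng, row["stage"], row["t_start"], row["t_end"], spec)
        zone_iv_by_stage[row["stage"]] = iv
        for a, b, z in iv:
            zone_rows.append((row["stage"], z, a, b))
            event_rows.append((a, "zone_entry", z, row["stage"]))
            event_rows.append((b, "zone_exit", z, row["stage"]))
            # LED activations while occupying the zone
            n_led = rng.poisson(spec.led_rate_hz * (b - a))
            kind = "led_cocaine" if z == "cocaine" else "led_saline"
            for t_led in np.sort(rng.uniform(a, b, n_led)):
                event_rows.append((t_led, kind, z, row["stage"]))
    zone_intervals = pd.DataFrame(zone_rows, columns=["stage", "zone", "t_start", "t_end"])

    # ---- laser pulses (optional)
    if spec.n_laser_pulses > 0:
        lo, hi = spec.laser_interval_s
        gaps = rng.uniform(lo, hi, spec.n_laser_pulses)
        onsets = 1.0 + np.cumsum(gaps)
        onsets = onsets[onsets < t_all[-1] - 1.0]
        for t_p in onsets:
            stage = spec.stages[min(int(t_p // spec.duration_s), len(spec.stages) - 1)]
            event_rows.append((t_p, "laser_pulse", "", stage))

    events = pd.DataFrame(event_rows, columns=["time_s", "kind", "zone", "stage"])
    events = events.sort_values("time_s", ignore_index=True)

    # ---- shared cross-network burst events (the planted coordination motif)
    global_events = {}
    for _, row in stage_bounds.iterrows():
        stage, s0, s1 = row["stage"], row["t_start"], row["t_end"]
        n_ev = rng.poisson(spec.burst_rate * (s1 - s0))
        global_events[stage] = np.sort(rng.uniform(s0, s1, n_ev))

    # ---- LFPs
    lfp, burst_iv, beta_phase, beta_env, pac = {}, {}, {}, {}, {}
    for region in spec.regions:
        x = _pink_noise(rng, n_total, spec.noise_exponent, spec.noise_std)
        for f, a in zip(GAMMA_FREQS, GAMMA_AMPS):
            x += a * np.cos(2 * np.pi * f * t_all + rng.uniform(0, 2 * np.pi))
        if region == "VTA":
            x += spec.vta4_amp * np.cos(phi4)
        if region == "Hpc":
            x += spec.hpc4_amp * np.cos(phi4)

        beta_component = np.zeros(n_total)
        intervals = []
        if region in BETA_REGIONS:
            depth = spec.pac_depth_for(region)
            pref = spec.pac_phase_for(region)
            pac[region] = (depth, pref)
            for _, row in stage_bounds.iterrows():
                stage, s0, s1 = row["stage"], row["t_start"], row["t_end"]
                gain = spec.zone_effect.get(stage, 1.0)
                iv = zone_iv_by_stage[stage]
                ev_times = global_events[stage]
                express = rng.random(len(ev_times)) < spec.burst_sync
                jitter = rng.uniform(-spec.burst_jitter_s, spec.burst_jitter_s, len(ev_times))
                durs = rng.uniform(0.3, 0.6, len(ev_times))
                carrier = rng.uniform(0, 2 * np.pi, len(ev_times))
                for tc, keep, dur, psi in zip(ev_times + jitter, express, durs, carrier):
                    if not keep:
                        continue
                    t0b, t1b = tc - dur / 2, tc + dur / 2
                    if t0b < s0 or t1b > s1:
                        continue
                    amp = spec.beta_amp * (gain if _zone_at(iv, tc) == "cocaine" else 1.0)
                    i0b, i1b = int(round(t0b * fs)), int(round(t1b * fs))
                    m = i1b - i0b
                    tau = np.arange(m) / fs
                    env = np.hanning(m)
                    # envelope gated by the 4-Hz phase: unity at the preferred
                    # phase, (1 - depth) at the opposite phase
                    phi_seg = 2 * np.pi * SLOW_FREQ * (t0b + tau)
                    gate = 1.0 - depth / 2 + (depth / 2) * np.cos(phi_seg - pref)
                    beta_component[i0b:i1b] += (
                        amp * env * gate * np.cos(2 * np.pi * BETA_FREQ * tau + psi)
                    )
                    intervals.append((t0b, t1b, amp))
            x += beta_component
            a_beta = hilbert(beta_component)
            beta_phase[region] = np.angle(a_beta)
            beta_env[region] = np.abs(a_beta)
        burst_iv[region] = np.array(intervals).reshape(-1, 3)
        lfp[region] = x

    # ---- speed: reflected Ornstein-Uhlenbeck at the tracking rate
    n_sp = int(round(n_total / fs * TRACKING_RATE))
    dt = 1.0 / TRACKING_RATE
    theta, mu, sigma = 0.5, 6.0, 4.0
    v = np.empty(n_sp)
    v[0] = mu
    noise = rng.standard_normal(n_sp - 1) if n_sp > 1 else np.array([])
    for i in range(1, n_sp):
        v[i] = v[i - 1] + theta * (mu - v[i - 1]) * dt + sigma * np.sqrt(dt) * noise[i - 1]
    speed = np.abs(v)

    # ---- spikes: inhomogeneous Poisson with von Mises phase locking
    unit_specs = spec.spike_lock if spec.spike_lock is not None else default_units(rng)
    unit_specs = [u for u in unit_specs if u.region in spec.regions]
    spike_times, unit_rows = {}, []
    for uid, u in enumerate(unit_specs):
        if u.target == "vta4":
            phase_t = np.angle(np.exp(1j * phi4))
            weight = np.ones(n_total)
        elif u.target == "beta" and u.region in beta_phase:
            phase_t = beta_phase[u.region]
            weight = np.clip(beta_env[u.region] / (0.5 * spec.beta_amp), 0.0, 1.0)
        else:
            phase_t = np.zeros(n_total)
            weight = np.zeros(n_total)
        kw = u.kappa * weight
        lam_max = u.base_rate * np.exp(u.kappa) if u.kappa > 0 else u.base_rate
        n_cand = rng.poisson(lam_max * t_all[-1]) if n_total > 1 else 0
        cand = np.sort(rng.uniform(0, t_all[-1], n_cand))
        idx = np.minimum((cand * fs).astype(int), n_total - 1)
        rate = u.base_rate * np.exp(kw[idx] * np.cos(phase_t[idx] - u.pref_phase)) / i0(kw[idx])
        keep = rng.random(n_cand) < rate / lam_max
        st = cand[keep]
        st = st[np.concatenate([[True], np.diff(st) > 1e-4])]  # enforce strict ordering
        spike_times[uid] = st
        unit_rows.append((uid, u.region, u.target, u.kappa, u.pref_phase, u.base_rate))

    units = pd.DataFrame(
        unit_rows, columns=["unit_id", "region", "gt_class", "kappa", "pref_phase", "base_rate"]
    )
    recording = SessionRecording(
        lfp=lfp,
        lfp_rate=fs,
        spike_times=spike_times,
        units=units,
        speed=speed,
        speed_rate=TRACKING_RATE,
        events=events,
        stage_bounds=stage_bounds,
    )
    recording.validate()
    manifest = GroundTruthManifest(
        burst_intervals=burst_iv,
        pac=pac,
        unit_params=units.copy(),
        zone_effect=dict(spec.zone_effect),
        zone_intervals=zone_intervals,
        beta_phase=beta_phase,
        beta_envelope=beta_env,
        slow_phase_freq=SLOW_FREQ,
        seed=spec.seed,
    )
    return recording, manifest


# --------------------------------------------------------------------------
# behavioral preference scores


def led_preference(events: pd.DataFrame, stage: str, stage_bounds: pd.DataFrame) -> float:
    """Signed LED activation preference: (cocaine - saline) activations / minute."""
    row = stage_bounds[stage_bounds["stage"] == stage]
    if len(row) == 0:
        raise ValueError(f"unknown stage {stage!r}")
    minutes = float(row["t_end"].iloc[0] - row["t_start"].iloc[0]) / 60.0
    if minutes <= 0:
        raise ValueError("empty stage window")
    ev = events[events["stage"] == stage]
    n_coc = int((ev["kind"] == "led_cocaine").sum())
    n_sal = int((ev["kind"] == "led_saline").sum())
    if n_coc + n_sal == 0:
        warnings.warn(f"no LED events in stage {stage!r}", stacklevel=2)
        return 0.0
    return (n_coc - n_sal) / minutes


def cpp_score(time_cocaine: float, time_saline: float) -> float:
    """Place-preference score (Tc - Ts) / (Tc + Ts), in [-1, 1]."""
    if time_cocaine < 0 or time_saline < 0:
        raise ValueError("occupancy times must be non-negative")
    total = time_cocaine + time_saline
    if total == 0:
        raise ValueError("both compartment times are zero")
    return (time_cocaine - time_saline) / total


# --------------------------------------------------------------------------
# recovery helpers


def bandpass_envelope(x: np.ndarray, rate: float, lo: float = 15.0, hi: float = 25.0) -> np.ndarray:
    """Hilbert envelope of the zero-phase band-passed signal."""
    b, a = butter(4, [lo, hi], btype="bandpass", fs=rate)
    return np.abs(hilbert(filtfilt(b, a, np.asarray(x, dtype=float))))


def zone_burst_envelope_ratio(
    recording: SessionRecording,
    manifest: GroundTruthManifest,
    region: str,
    stage: str,
) -> float:
    """Cocaine/saline ratio of mean beta envelope over planted burst windows.

    Recovers the planted per-stage ``zone_effect`` from the raw LFP.
    """
    env = bandpass_envelope(recording.lfp[region], recording.lfp_rate)
    fs = recording.lfp_rate
    ziv = manifest.zone_intervals
    ziv = ziv[ziv["stage"] == stage]
    iv_list = list(zip(ziv["t_start"], ziv["t_end"], ziv["zone"]))
    sums = {"cocaine": [], "saline": []}
    for t0, t1, _amp in manifest.burst_intervals.get(region, np.empty((0, 3))):
        zone = _zone_at(iv_list, 0.5 * (t0 + t1))
        if zone is None:
            continue
        i0_, i1_ = int(t0 * fs), int(t1 * fs)
        sums[zone].append(env[i0_:i1_].mean())
    if not sums["cocaine"] or not sums["saline"]:
        raise ValueError("need planted bursts in both zones")
    return float(np.mean(sums["cocaine"]) / np.mean(sums["saline"]))


PLANTED_BANDS = {
    BETA_FREQ: ("beta", (15.0, 25.0)),
    40.0: ("gamma", (35.0, 45.0)),
    65.0: ("gamma", (58.0, 72.0)),
    100.0: ("gamma", (90.0, 110.0)),
}


def planted_band_amplitudes(
    recording: SessionRecording, spec: SessionSpec
) -> tuple[np.ndarray, pd.DataFrame]:
    """Oracle amplitude matrix for the planted 12-125 Hz components.

    Band-passes each region's LFP around every planted component frequency
    in the transient (12-125 Hz) range and takes the Hilbert envelope; this
    is the decomposition-free stand-in for tmEMD IMF amplitudes used in
    recovery tests and the default-structure configuration check (4 + 4 +
    4 + 4 + 3 = 19 components for the five default regions).

    Returns (amplitudes (K, n_samples), component table with region / centre
    frequency / band label).
    """
    rows, amps = [], []
    for region in recording.lfp:
        for f in spec.planted_component_freqs(region):
            if not 12.0 <= f <= 125.0:
                continue
            band_label, (lo, hi) = PLANTED_BANDS[f]
            b, a = butter(4, [lo, hi], btype="bandpass", fs=recording.lfp_rate)
            amps.append(np.abs(hilbert(filtfilt(b, a, recording.lfp[region]))))
            rows.append((region, f, band_label))
    meta = pd.DataFrame(rows, columns=["region", "center_freq", "band"])
    return np.array(amps), meta


def zone_of_times(zone_intervals: pd.DataFrame, stage: str, times: np.ndarray) -> np.ndarray:
    """Zone label ('cocaine'/'saline'/'') for each time within a stage."""
    ziv = zone_intervals[zone_intervals["stage"] == stage]
    out = np.full(len(times), "", dtype=object)
    for _, row in ziv.iterrows():
        sel = (times >= row["t_start"]) & (times < row["t_end"])
        out[sel] = row["zone"]
    return out
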