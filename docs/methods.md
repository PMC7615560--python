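# Methods notes

## Synthetic sessions: what is modelled and what is not

The generator (`betabarcode.sessions`) emulates a four-stage conditioned
cue-place preference session (pre-test, recall, extinction, renewal) with
simultaneous five-region LFPs at 1250 samples/s, sorted spike trains,
a 39-Hz speed trace, and zone/LED/laser event streams.  Its signal model:

- **Background**: Gaussian 1/f^α noise via spectral shaping (α = 1,
  SD = 0.5 in LFP units).  No biophysical (conductance-based) modelling.
- **Pacing rhythm**: a 4-Hz cosine in VTA (amplitude 1.0) with an
  attenuated copy in Hpc (0.4).  The phase convention everywhere is the
  analytic-signal phase of a cosine: 0 at the peak, ±π at the trough.
- **Beta bursts**: cross-network burst events arrive as a Poisson process
  (default 0.5 events/s — the in-vivo burst rate is not published, so this
  is a free configuration parameter chosen to give bursts that occupy
  roughly a fifth of the session).  Each event expresses in each of
  PFC/NAc/Amy/Hpc with probability 0.9 and ±30 ms jitter, as a 20-Hz
  carrier under a Hanning envelope of 300–600 ms (uniform), matching
  reported bout durations of roughly 0.4–0.5 s.  Sharing event times across
  regions is deliberate: the cross-regional co-activation motif is the
  phenomenon the barcode analysis is built to detect, so it must be planted.
- **Phase–amplitude coupling**: each burst's envelope is gated by the 4-Hz
  phase, g(t) = 1 − d/2 + (d/2)·cos(φ₄(t) − φ_pref), i.e. unity at the
  preferred phase and (1 − d) at the opposite phase.  Default depth
  d = 0.8; preferred phases 2.6 rad for PFC/NAc/Amy and 2.0 rad for Hpc
  (descending slope of the 4-Hz cycle, Hpc earlier).  Gating the envelope
  (rather than thinning burst times) matters because bursts outlast a 4-Hz
  cycle; occurrence-only coupling would smear the amplitude over all phases
  and leave almost no measurable modulation.
- **Zone effect**: bursts whose centre falls inside the cocaine-paired LED
  zone are scaled by a per-stage gain, default (1.0, 1.5, 1.0, 1.5) across
  the four stages — the planted memory-retrieval effect.
- **Behavior**: the animal alternates between the two LED zones
  (exponential dwells, mean 8 s in-zone and 6 s off-zone); the stage bias
  (default 1.8 in recall/renewal) lengthens cocaine-zone dwells rather than
  skipping saline visits, so both zones are sampled in every stage even in
  short sessions.  LED activations are Poisson while a zone is occupied.
  Speed is a reflected Ornstein–Uhlenbeck process (mean 6 cm/s) at the
  39-Hz tracking rate; the 2-cm/s locomotion threshold gates downstream
  binning.
- **Spikes**: inhomogeneous Poisson with rate
  r(t) = base·exp(κ_eff·cos(φ_target − φ_pref))/I₀(κ_eff).  For units
  locked to their region's beta, κ_eff is the planted κ scaled by the
  instantaneous beta envelope (locking exists only when beta is present);
  for 4-Hz-locked units κ_eff = κ throughout.  Default population: 12 units
  per region, one third beta-locked (κ = 2), one third 4-Hz-locked, one
  third unlocked.

What the generator does **not** emulate: non-stationary drift, volume
conduction and shared referencing across regions, spike-sorting errors,
zone-specific firing-rate coding independent of the beta pathway, and
behavioral idiosyncrasies (thigmotaxis, grooming bouts).  Passing recovery
tests therefore demonstrates that each method measures what it claims under
the assumed signal model, not that real recordings satisfy that model.

## tmEMD

`masked_sift` implements per-level masked sifting: at level k a mask
sinusoid at mask_freqs[k] with amplitude 2× the working signal's SD is
added at 4 equally spaced phases; each masked signal is sifted to its first
IMF with cubic-spline envelope-mean subtraction (fixed 8 inner iterations —
deterministic, avoids SD-threshold ambiguity) and the mask subtracted back;
the phase average becomes the level's IMF.  Because the four mask phases
sum to zero, mask leakage cancels even when a level's mask is not captured
by the sift.  Completeness (ΣIMF + residual = input) holds algebraically.

The mask search samples candidate mask sets uniformly within per-level
frequency ranges (200 candidates per iteration by default), scores each by
the mixing score (and by between-subject consistency when several subjects
are supplied), and narrows the ranges to the span of the top 10 by mixing.
The final selection minimises the mean of mixing and consistency ranks over
all evaluated candidates.  The consistency score — the mean across IMF
levels of the mean pairwise Pearson correlation between subjects' z-scored
IMF Welch PSDs (2-s windows, 50% overlap) — is this package's documented
definition; note that because the sift acts as a common filter bank, its
independent-noise floor is ≈0.5, not 0, so only relative comparisons are
meaningful.

Reference-channel selection takes the channel whose z-scored PSD is
L2-closest to the cross-animal median PSD (ties to the lowest index).  The
training segment is the 5-minute window with the highest fraction of speed
above 2 cm/s (sliding argmax, earliest on ties).  Per-region 4-Hz and beta
signals are the IMFs whose amplitude-weighted mean instantaneous frequency
is nearest 4 Hz and 20 Hz respectively.

## Barcodes and the CPMR score

Amplitudes are SD-normalised before ICA fitting (250-ms sampling, FastICA,
parallel fixed-point, whitened, seeded; each weight vector sign-flipped so
its largest-magnitude element is positive) but strength tracking uses the
**non-normalised** amplitudes at the original 1250-Hz resolution — the two
conventions are intentionally different.  Strength is computed as a
quadratic form over the symmetric motif matrix, avoiding materialising the
full pair time series.  For the CPMR score, strength is z-scored within
each stage, averaged in 1-s bins, kept when the bin's median speed exceeds
2 cm/s, and assigned to the zone occupied for the majority of the bin
(bins without a majority zone are dropped); the per-stage effect size is
Cohen's d with pooled SD (the effect-size definition is pluggable since the
in-vivo choice is cited, not printed).  ICA fitting across animals pools
(concatenates) feature rows from all subjects.

Observed behavior worth knowing: ICA fragments the planted beta motif over
a few components, and barcodes loading diffusely on beta-involving pairs
can out-rank the concentrated beta×beta barcode on Cohen's d because their
binned strength has lower variance.  The validated property is therefore
that top-CPMR barcodes carry above-median beta weight and that CPMR
correlates with beta content across barcodes.

## Beta cycles, bouts and modulation

A cycle spans trough to trough and must contain an ascending zero-crossing,
a positive peak and a descending zero-crossing, with a further ascending
crossing at or after the end trough.  A trough that fails this structure is
not treated as a cycle boundary: the span is extended to the next trough.
This keeps detected cycles contiguous, so bout chains break only at the
amplitude threshold (the session-level 50th percentile of cycle mean
amplitudes; the percentile is computed per session, not per stage).
Trough-triggered analyses use one trough per bout — that of the bout's
highest-amplitude cycle — thinned greedily to ≥250-ms separation.

Phase modulation bins the z-scored amplitude into 32 equal phase bins;
strength is the max-minus-min bin mean and the preferred phase the centre
of the max bin; a constant amplitude returns strength 0 with a warning.
Morlet spectrograms use L2-normalised complex wavelets of width 6 cycles
(configurable; the width is not pinned by the analysis) on the z-scored
LFP over a 119-frequency grid (2–100 Hz in 1-Hz steps, 105–200 Hz in 5-Hz
steps).  Trigger-averaged spectrograms are z-scored per frequency with mean
and SD pooled over both zone conditions, and the beta summary samples
15–25-Hz z-power at the cross-condition median lag of maximal beta.

## Spiking statistics

Spike-phase coherence is the mean resultant length of spike-sampled phases
(nearest-sample lookup); units with fewer than 20 spikes in the scoring
windows are unscored (the 20-spike floor is applied globally).  The null
rotates the entire bout-window pattern by a uniform circular offset —
preserving every bout duration and inter-bout gap; windows wrapping the
recording end are split — and recomputes R from the spikes falling in the
rotated windows; significance is the 95th percentile.  Note the null spike
count can differ slightly from the observed one since different spikes fall
in rotated windows; this is inherent to the construction.  The Rayleigh p
is computed from Z = nR² as p ≈ e^{−Z}(1 + (2Z − Z²)/(4n)).

The place-LED decoder is an LDA on disjoint 100-ms population spike-count
vectors restricted to LED-zone occupancy; validation is stratified 5-fold
cross-validation within recall (the in-vivo validation scheme is not
printed), and cross-stage application freezes the recall-fitted weights.
Per-unit contribution is the absolute LDA coefficient.

Optotagging splits pulses randomly in halves, builds 2-ms-bin PSTHs, and
samples the half-2 response at the half-1 post-onset peak bin; tagging
requires both halves above the 99th percentile of their −1000..−500-ms
baseline bins and the half-2 maximum within 6 ms of onset.  Entrainment
uses the 95th percentile of −1000..−50 ms and no latency cap.  Calibration
is sensitive to count discreteness: with few pulses or very low rates the
test is conservative.

Spike-triggered spectrograms use isolated spikes and burst-first spikes
(an inter-spike interval below 10 ms starts a burst; configurable), require
20 spikes, and subtract a speed-matched control in which each spike is
reassigned a random time from the same speed-percentile bin (100 bins),
excluding real spike times; real and control averages are z-scored per
frequency over both before subtraction.  VTA waveform clustering
max-abs-normalises mean waveforms, retains principal components to ≥95%
variance, embeds them in 2-D with UMAP, and k-means (k = 3) labels the
embedding (clustering the embedding rather than the PCs is this package's
choice; the source pipeline is ambiguous).

## Real-time phase tracking

The causal chain: 1st-order IIR high-pass at 0.4 Hz, then a 4th-order
anti-alias low-pass at 64 Hz (an implementation addition — decimating
125-fold without band-limiting would alias; acquisition hardware
band-limits upstream), then 125-fold decimation of the 20-kHz stream to
160 Hz.  The tracker keeps a complex amplitude c against a free-running
reference phasor at 4 Hz and updates it by exponential demodulation,
c ← c + g·(2·y·e^{−iθ} − c) with g = 0.0625; the emitted phase is
arg(c·e^{iθ}).  This core is a reconstruction consistent with the stated
configuration, not the published hardware algorithm: it is causal, locks to
off-centre frequencies with a static lag of ≈atan(2πΔf/(g·f_s)), and
free-runs at the centre frequency on zero input.  Pulse scheduling applies
a phase lead of 2π·4·(125/2)/1000 = π/2 so the target phase falls at the
125-ms pulse midpoint, with a one-pulse refractory period.

The closed-loop simulator suppresses the downstream beta envelope
multiplicatively during light, weighted by the planted 4-Hz drive profile
(1 + cos(φ − φ_pref))/2 — silencing the upstream population matters only
when it is active — which is why opposite-phase light produces a much
weaker change.  Because pulses trigger phase-locked to rising beta
envelopes, every arm shows a small common pulse-on offset; arms are
therefore compared against the no-opsin control.

## Estimation statistics

Bootstrap difference estimates resample within groups (pairs jointly when
paired) with 5,000 resamples and report the 2.5th/97.5th percentiles.  The
permutation p shuffles group labels (or swaps pair labels with equal
chance) 10,000 times and reports the +1-smoothed two-sided fraction — the
smoothing prevents p = 0.  Median-based differences are available for
skewed data; the caller decides.  Cohen's d with pooled SD stands in for
the cited (unprinted) zone effect-size definition and is pluggable.

## Problem sizes used in tests and validation

Test sessions use 60–300-s stages (the generator default remains the
session's 20-minute stages), one to five regions as needed, and the mask
search runs on short two/three-tone signals or 30-s LFP segments with
reduced candidate counts; calibration loops use 200–500 seeded repeats with
100–400 shuffles.  These sizes were chosen so the full validation suite
completes in a few minutes while leaving every statistical check at a
resolution where its nominal behavior (coverage, false-positive rate,
recovery tolerance) is measurable.

## Known limitations

- The consistency score and the tracker core are documented reconstructions
  of components whose exact in-vivo definitions are unpublished.
- The generator plants no zone coding in firing rates beyond the beta-burst
  pathway, so decoding accuracy on synthetic sessions reflects burst-zone
  coupling (plus temporal autocorrelation of bursts across neighbouring
  bins), not place-cell-like coding.
- Narrowband noise around 20 Hz produces above-threshold noise cycles that
  can extend detected bouts beyond planted burst edges; bout boundary
  precision degrades as burst duty cycle falls.
- UMAP embeddings are seeded but not stable across library versions;
  cluster labels are arbitrary up to permutation.
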