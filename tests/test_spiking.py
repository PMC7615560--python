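"""Spike-phase coherence with shuffle nulls, decoding, optotagging, clustering."""

import numpy as np
import pytest
from scipy.special import i0, i1
from scipy.stats import vonmises

from betabarcode import spiking

RATE = 250.0


def four_hz_phase(T, rate=RATE):
    t = np.arange(int(T * rate)) / rate
    return np.angle(np.exp(1j * 2 * np.pi * 4.0 * t))


def irregular_windows(rng, T, n=60, dur=(0.3, 0.5)):
    starts = np.cumsum(rng.uniform(1.0, 3.0, n))
    starts = starts[starts < T - 1]
    return np.column_stack([starts, starts + rng.uniform(*dur, len(starts))])


class TestCoherence:
    def test_point_mass_phases(self):
        phase = np.full(1000, np.pi / 3)
        st = np.linspace(0.1, 3.9, 100)
        s = spiking.spike_phase_coherence(st, phase, RATE)
        assert s.R == pytest.approx(1.0)
        assert s.preferred_phase == pytest.approx(np.pi / 3)

    def test_uniform_phases_small_R(self, rng):
        phases = rng.uniform(-np.pi, np.pi, 10000)
        assert spiking.resultant_length(phases) < 0.03

    def test_von_mises_matches_bessel_ratio(self):
        """Simulated von Mises R matches I1(kappa)/I0(kappa) within 0.03."""
        for kappa in (0.5, 1.0, 2.0, 4.0):
            r = np.random.default_rng(int(kappa * 10))
            ph = vonmises.rvs(kappa, size=5000, random_state=r)
            R = spiking.resultant_length(ph)
            assert abs(R - i1(kappa) / i0(kappa)) < 0.03

    def test_too_few_spikes_unscored(self):
        s = spiking.spike_phase_coherence(np.array([1.0]), four_hz_phase(10), RATE)
        assert not s.scored

    def test_rayleigh_p_behaviour(self):
        # strong locking at large n -> tiny p; uniform -> large p
        assert spiking.rayleigh_p(0.8, 500) < 1e-10
        assert spiking.rayleigh_p(0.01, 500) > 0.5


class TestBoutShuffleNull:
    def test_durations_preserved_by_rotation(self, rng):
        wins = irregular_windows(rng, 100.0)
        shifted = spiking.rotate_windows(wins, 37.7, 100.0)
        orig = np.sort(wins[:, 1] - wins[:, 0])
        new = np.sort(shifted[:, 1] - shifted[:, 0])
        # wrap may split one window into two pieces
        assert abs(orig.sum() - new.sum()) < 1e-9
        assert len(new) in (len(orig), len(orig) + 1)

    def test_false_positive_rate_calibrated(self):
        """Non-modulated Poisson units flagged in ~5% of 400 seeded simulations."""
        T = 120.0
        phase = four_hz_phase(T)
        fp = 0
        n_rep = 400
        for k in range(n_rep):
            r = np.random.default_rng(k)
            wins = irregular_windows(r, T)
            st = np.sort(r.uniform(0, T, 600))
            stats = spiking.coherence_with_null(
                st, phase, RATE, wins, T, n_shuffles=200, seed=10000 + k
            )
            fp += bool(stats.significant)
        assert 0.02 * n_rep <= fp <= 0.09 * n_rep

    def test_locked_unit_significant(self):
        T = 120.0
        r = np.random.default_rng(7)
        phase = four_hz_phase(T)
        wins = irregular_windows(r, T)
        # locked only inside bouts (von Mises kappa=4 at 4-Hz peaks); uniform
        # background firing elsewhere, so rotated windows sample unlocked spikes
        peaks = np.arange(0.0, T, 0.25)
        jit = vonmises.rvs(4.0, size=len(peaks), random_state=r) / (2 * np.pi * 4.0)
        locked = spiking._spikes_in_windows(np.sort(peaks + jit), wins)
        background = r.uniform(0, T, 800)
        in_win = spiking._spikes_in_windows(background, wins)
        background = np.setdiff1d(background, in_win)
        st = np.sort(np.concatenate([locked, background]))
        stats = spiking.coherence_with_null(st, phase, RATE, wins, T, n_shuffles=200, seed=1)
        assert stats.scored and stats.significant

    def test_total_bout_time_guard(self):
        wins = np.array([[0.0, 6.0], [6.0, 12.0]])
        with pytest.raises(ValueError):
            spiking.bout_shuffle_null(wins, four_hz_phase(10), RATE, np.array([1.0]), 10.0)


class TestPercentileCurves:
    def test_random_subsample_within_band_and_boundary(self, rng):
        R = rng.uniform(0, 1, 200)
        groups = np.where(rng.random(200) < 0.3, "a", "b")
        res = spiking.population_percentile_curve(R, groups, n_shuffles=300, seed=0)
        for g in ("a", "b"):
            assert res.curves[g][0] == pytest.approx(1.0)  # percentile 0: all above
            assert res.significant[g].mean() < 0.2          # exchangeable: mostly in band

    def test_planted_top_quartile_group_over_represented(self, rng):
        R = np.sort(rng.uniform(0, 1, 200))
        groups = np.array(["low"] * 200, dtype=object)
        groups[-40:] = "high"  # top R values
        res = spiking.population_percentile_curve(R, groups, n_shuffles=300, seed=0)
        over_75 = res.percentiles >= 75
        assert res.significant["high"][over_75].any()
        assert (res.curves["high"][over_75] > res.null_high["high"][over_75]).any()

    def test_single_group_error(self):
        with pytest.raises(ValueError):
            spiking.population_percentile_curve(np.ones(10), np.zeros(10))


class TestTroughTriggeredRate:
    def test_spikes_at_troughs_peak_at_zero_lag(self):
        troughs = np.arange(1.0, 50.0, 0.5)
        centers, rate = spiking.trough_triggered_rate(troughs.copy(), troughs)
        assert abs(centers[np.argmax(rate)]) < 0.002

    def test_poisson_flat(self, rng):
        st = np.sort(rng.uniform(0, 200, 4000))
        troughs = np.arange(5.0, 195.0, 1.0)
        _, rate = spiking.trough_triggered_rate(st, troughs, bin_s=0.025)
        se = np.sqrt(rate.mean() / len(troughs))
        assert np.abs(rate - rate.mean()).max() < 4 * (se + 1e-9) + 0.05

    def test_20hz_locked_side_peaks(self, rng):
        """Unit locked to 20 Hz shows side peaks at +/- 50 ms around troughs."""
        spikes = np.arange(1.0, 99.0, 0.05)  # fires every 20-Hz cycle
        spikes = spikes + 0.002 * rng.standard_normal(len(spikes))
        troughs = np.arange(2.0, 98.0, 0.271)  # arbitrary references on the comb
        troughs = np.round((troughs - 1.0) / 0.05) * 0.05 + 1.0
        centers, rate = spiking.trough_triggered_rate(
            np.sort(spikes), troughs, bin_s=0.0015, window_s=(-0.08, 0.08)
        )
        peak_lags = centers[rate > 0.5 * rate.max()]
        assert any(abs(abs(l) - 0.05) < 0.005 for l in peak_lags)

    def test_no_troughs_error(self):
        with pytest.raises(ValueError):
            spiking.trough_triggered_rate(np.array([1.0]), np.array([]))


class TestDecoder:
    def test_label_permutation_chance_level(self):
        """Permuted labels give ~50% held-out accuracy (2500 bins, 60 units)."""
        accs = []
        for k in range(5):
            r = np.random.default_rng(k)
            base = r.uniform(0.2, 1.5, 60)
            X = r.poisson(base, size=(2500, 60)).astype(float)
            y = r.integers(0, 2, 2500)
            accs.append(spiking.fit_place_led_decoder(X, y, seed=k).cv_accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.03

    def test_separable_classes_perfect(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (100, 5)), rng.normal(5, 0.1, (100, 5))])
        y = np.repeat([0, 1], 100)
        m = spiking.fit_place_led_decoder(X, y, seed=0)
        assert m.cv_accuracy == 1.0
        assert spiking.apply_decoder(m, X, y) == 1.0

    def test_contribution_ranks_informative_units(self):
        """Planted class-coding units (20 of 60) rank top by |weight| (AUC > 0.8)."""
        r = np.random.default_rng(0)
        base = r.uniform(0.2, 1.5, 60)
        y = r.integers(0, 2, 2500)
        eff = np.zeros(60)
        eff[:20] = r.uniform(0.3, 0.8, 20)
        X = r.poisson(base[None, :] * (1 + np.outer(y, eff))).astype(float)
        m = spiking.fit_place_led_decoder(X, y, seed=0)
        from scipy.stats import mannwhitneyu

        auc = mannwhitneyu(m.contributions[:20], m.contributions[20:]).statistic / (20 * 40)
        assert auc > 0.8

    def test_single_class_error(self, rng):
        with pytest.raises(ValueError):
            spiking.fit_place_led_decoder(rng.random((50, 4)), np.zeros(50))

    def test_spike_count_matrix_shape(self):
        X, t0 = spiking.spike_count_matrix({0: np.array([0.05, 0.17]), 1: np.array([])}, 0.0, 1.0)
        assert X.shape == (10, 2)
        assert X[:, 0].sum() == 2 and X[:, 1].sum() == 0


class TestContributionCoherence:
    def test_identical_vectors_r_one(self):
        v = np.linspace(0.1, 1, 50)
        r, _ = spiking.contribution_vs_coherence(v, v)
        assert r == pytest.approx(1.0)

    def test_planted_association_positive(self, rng):
        informative = np.repeat([1.0, 0.0], 50)
        contrib = informative * 0.5 + 0.1 * rng.random(100)
        R = 0.1 + 0.3 * informative + 0.05 * rng.standard_normal(100)
        r, p = spiking.contribution_vs_coherence(contrib, R)
        assert r > 0 and p < 0.001

    def test_independent_near_zero(self, rng):
        r, _ = spiking.contribution_vs_coherence(rng.random(200), rng.random(200))
        assert abs(r) < 0.1


class TestOptotagging:
    def _responder(self, latency, rng, n_pulses=60, T=200.0, background=2.0):
        pulses = np.sort(rng.uniform(5, T - 5, n_pulses))
        st = np.sort(
            np.concatenate([pulses + latency, rng.uniform(0, T, int(background * T))])
        )
        return st, pulses

    def test_short_latency_responder_tagged(self, rng):
        st, pulses = self._responder(0.003, rng)
        assert spiking.optotag_classify(st, pulses, seed=2) is True

    def test_ten_ms_latency_rejected(self, rng):
        st, pulses = self._responder(0.011, rng)
        assert spiking.optotag_classify(st, pulses, seed=2) is False

    def test_thirty_ms_entrained_but_not_tagged(self, rng):
        st, pulses = self._responder(0.030, rng)
        assert spiking.optotag_classify(st, pulses, seed=2) is False
        assert spiking.entrainment_classify(st, pulses, seed=2) is True

    def test_silent_or_few_pulses_unscored(self, rng):
        _, pulses = self._responder(0.003, rng)
        assert spiking.entrainment_classify(np.array([]), pulses, seed=1) is None
        assert spiking.optotag_classify(np.array([1.0]), pulses[:5], seed=1) is None

    def test_optotag_false_positive_rate(self):
        """Homogeneous Poisson units tagged in < 2% of 500 seeded trials."""
        fp = 0
        for k in range(500):
            r = np.random.default_rng(k)
            pulses = np.sort(r.uniform(5, 195, 60))
            st = np.sort(r.uniform(0, 200, 1600))
            fp += bool(spiking.optotag_classify(st, pulses, seed=k))
        assert fp < 0.02 * 500

    def test_entrainment_false_positive_rate(self):
        """Poisson units entrained in ~5% of seeded trials (binomial CI of 5%)."""
        fp = 0
        n_rep = 400
        for k in range(n_rep):
            r = np.random.default_rng(k)
            pulses = np.sort(r.uniform(5, 595, 200))
            st = np.sort(r.uniform(0, 600, 12000))
            fp += bool(spiking.entrainment_classify(st, pulses, seed=k))
        assert 0.02 * n_rep <= fp <= 0.09 * n_rep


class TestSpikeTriggeredSpectrogram:
    def _speed(self, rng, T, rate=39.0):
        return np.abs(5 + rng.standard_normal(int(T * rate)))

    def test_control_spike_count_matches(self, rng):
        T = 60.0
        lfp = rng.standard_normal(int(T * RATE))
        st = np.sort(rng.uniform(2, T - 2, 60))
        out = spiking.spike_triggered_spectrogram(
            lfp, RATE, st, self._speed(rng, T), 39.0,
            np.arange(10.0, 40.0, 5.0), seed=0, window_s=(-0.3, 0.3),
        )
        assert out is not None  # >= 20 qualifying spikes used, same count for control

    def test_random_spikes_zero_response_in_expectation(self, rng):
        """Speed-independent LFP + random spikes: control equals treatment on average."""
        T = 120.0
        lfp = rng.standard_normal(int(T * RATE))
        speed = self._speed(rng, T)
        unit_means = []
        for k in range(8):
            st = np.sort(rng.uniform(2, T - 2, 150))
            diff, _ = spiking.spike_triggered_spectrogram(
                lfp, RATE, st, speed, 39.0,
                np.arange(10.0, 40.0, 5.0), seed=k, window_s=(-0.3, 0.3),
            )
            unit_means.append(diff.mean())
        unit_means = np.asarray(unit_means)
        se = unit_means.std(ddof=1) / np.sqrt(len(unit_means))
        assert abs(unit_means.mean()) < 3 * se + 0.05

    def test_spikes_preceding_bursts_positive_beta_response(self, rng):
        """Spiking just before planted beta bursts yields post-spike beta power."""
        T = 120.0
        t = np.arange(int(T * RATE)) / RATE
        lfp = 0.3 * rng.standard_normal(len(t))
        burst_times = np.arange(3.0, T - 3, 2.0)
        for tb in burst_times:
            i0 = int(tb * RATE)
            m = int(0.4 * RATE)
            lfp[i0 : i0 + m] += np.hanning(m) * np.cos(2 * np.pi * 20 * np.arange(m) / RATE)
        st = burst_times - 0.05  # spikes 50 ms before burst onset
        freqs = np.arange(10.0, 40.0, 2.0)
        diff, lags = spiking.spike_triggered_spectrogram(
            lfp, RATE, st, self._speed(rng, T), 39.0, freqs, seed=0, window_s=(-0.5, 0.5)
        )
        beta_rows = (freqs >= 15) & (freqs <= 25)
        post = lags > 0
        pre = lags < -0.3
        assert diff[beta_rows][:, post].mean() > diff[beta_rows][:, pre].mean() + 0.2

    def test_too_few_spikes_unscored(self, rng):
        out = spiking.spike_triggered_spectrogram(
            rng.standard_normal(1000), RATE, np.array([1.0]), self._speed(rng, 4.0),
            39.0, np.arange(10.0, 20.0, 5.0),
        )
        assert out is None


class TestWaveformClustering:
    @pytest.fixture(scope="class")
    def model_and_truth(self):
        r = np.random.default_rng(3)
        tt = np.linspace(-1, 2, 48)

        def wf(width, sign, amp):
            return sign * (
                -amp * np.exp(-((tt / width) ** 2))
                + 0.35 * amp * np.exp(-(((tt - 0.9) / (1.6 * width)) ** 2))
            )

        W, truth = [], []
        for fam, (width, sign) in enumerate([(0.18, 1.0), (0.45, 1.0), (0.30, -1.0)]):
            for _ in range(15):
                w = wf(width * (1 + 0.05 * r.standard_normal()), sign, 1 + 0.3 * r.random())
                W.append(w + 0.02 * r.standard_normal(len(tt)))
                truth.append(fam)
        W.append(W[0].copy())  # duplicated unit
        truth.append(truth[0])
        model = spiking.cluster_vta_waveforms(np.array(W), seed=0)
        return model, np.array(truth)

    def test_recovers_planted_families(self, model_and_truth):
        from sklearn.metrics import adjusted_rand_score

        model, truth = model_and_truth
        assert adjusted_rand_score(truth, model.labels) > 0.9

    def test_normalised_waveforms_unit_peak(self, model_and_truth):
        model, _ = model_and_truth
        assert np.allclose(np.abs(model.waveforms).max(axis=1), 1.0)

    def test_duplicated_unit_same_cluster(self, model_and_truth):
        model, _ = model_and_truth
        assert model.labels[-1] == model.labels[0]

    def test_too_few_units_error(self, rng):
        with pytest.raises(ValueError):
            spiking.cluster_vta_waveforms(rng.random((2, 30)), k=3)
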