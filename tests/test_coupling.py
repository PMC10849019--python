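"""Coherence machinery: epoching, rejection, spectra, peaks, surrogates."""

import numpy as np
import pytest

from ckcpipe.coupling import (EpochSet, ckc_analysis, coherence_spectra,
                              expected_epoch_count, fourier_surrogate,
                              make_epochs, pick_peaks, pool_epochs,
                              reject_epochs, significance_threshold,
                              spectral_snr)
from ckcpipe.recording import Recording

FS = 1000.0


def _recording(samples, labels=None, roles=None):
    n = samples.shape[0]
    labels = labels or [f"E{i}" for i in range(n)]
    roles = roles or ["EEG"] * (n - 1) + ["EMG"]
    return Recording(samples=samples, sample_rate=FS, channel_labels=labels,
                     channel_roles=roles)


class TestEpoching:
    @pytest.mark.parametrize("duration,expected", [(60, 56), (5, 1), (12.3, 8)])
    def test_epoch_count_formula(self, duration, expected):
        assert expected_epoch_count(duration) == expected
        rng = np.random.default_rng(0)
        rec = _recording(rng.standard_normal((3, int(duration * FS))))
        assert make_epochs(rec).n_epochs == expected

    def test_three_trials_pool_to_168(self):
        rng = np.random.default_rng(1)
        sets = [make_epochs(_recording(rng.standard_normal((3, 60000))),
                            trial_id=t) for t in range(3)]
        assert pool_epochs(sets).n_epochs == 168

    def test_frequency_resolution_is_inverse_epoch_length(self):
        rng = np.random.default_rng(2)
        es = make_epochs(_recording(rng.standard_normal((3, 20000))))
        assert es.frequency_resolution == pytest.approx(0.2)
        spectra = coherence_spectra(es, "E2")
        assert np.diff(spectra.frequencies)[0] == pytest.approx(0.2)

    def test_short_recording_rejected(self):
        rec = _recording(np.random.default_rng(3).standard_normal((3, 3000)))
        with pytest.raises(ValueError, match="shorter"):
            make_epochs(rec)


class TestRejection:
    def test_clean_gaussian_data_rejects_few(self):
        rng = np.random.default_rng(4)
        rec = _recording(rng.standard_normal((4, 120000)))
        es = reject_epochs(make_epochs(rec))
        # P(any sample of a 5 s epoch beyond 5 SD) is tiny for Gaussian data
        assert len(es.rejected_epoch_ids) <= 2

    def test_injected_spike_rejects_exactly_that_epoch(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((4, 60000))
        x[1, 30500] = 10.0 * x[1].std()  # inside epochs starting 26..30 s
        es = reject_epochs(make_epochs(_recording(x)))
        expected = {i for i, s in enumerate(range(0, 55001, 1000))
                    if s <= 30500 < s + 5000}
        assert set(es.rejected_epoch_ids) == expected

    def test_infinite_threshold_is_identity(self):
        rng = np.random.default_rng(6)
        es = make_epochs(_recording(rng.standard_normal((4, 30000))))
        assert reject_epochs(es, np.inf).n_epochs == es.n_epochs

    def test_all_rejected_aborts(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((4, 30000))
        es = make_epochs(_recording(x))
        with pytest.raises(ValueError, match="rejected"):
            reject_epochs(es, sd_threshold=0.0)


class TestCoherence:
    def test_reference_with_itself_is_one(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(60000)
        rec = _recording(np.stack([x, x]), labels=["E0", "EMG_ref"],
                         roles=["EEG", "EMG"])
        sp = coherence_spectra(make_epochs(rec), "EMG_ref")
        valid = sp.power[1] > 1e-12 * sp.power[1].max()
        np.testing.assert_allclose(sp.coherence[1][valid], 1.0, atol=1e-9)

    def test_independent_noise_bias_is_one_over_epochs(self):
        # with L *non-overlapping* epochs, E[MSC] ~ 1/L for independent noise
        rng = np.random.default_rng(9)
        rec = _recording(rng.standard_normal((2, 300000)))
        es = make_epochs(rec, epoch_length=5.0, overlap=0.0)
        sp = coherence_spectra(es, "E1", taper="none")
        assert sp.coherence[0].mean() == pytest.approx(1 / es.n_epochs, rel=0.15)

    def test_tone_in_noise_matches_signal_plus_noise_closed_form(self):
        # x = a s + n, y = s  ->  MSC at the tone bin = a^2 P / (a^2 P + N)
        rng = np.random.default_rng(10)
        n = 300000
        t = np.arange(n) / FS
        s = np.sin(2 * np.pi * 2.0 * t)
        a, sigma = 0.05, 1.0
        x = a * s + sigma * rng.standard_normal(n)
        rec = _recording(np.stack([x, s]))
        es = make_epochs(rec, overlap=0.0)
        sp = coherence_spectra(es, "E1")
        i = int(round(2.0 / 0.2))
        win = np.hanning(5000)
        ps = np.abs(np.fft.rfft(s[:5000] * win))[10] ** 2  # tone bin power
        pn = sigma ** 2 * np.sum(win ** 2)                 # E[noise periodogram]
        expected = (a ** 2 * ps) / (a ** 2 * ps + pn)
        assert sp.coherence[0, i] == pytest.approx(expected, abs=0.05)

    def test_single_epoch_rejected(self):
        rng = np.random.default_rng(11)
        es = make_epochs(_recording(rng.standard_normal((2, 5000))))
        with pytest.raises(ValueError, match="at least 2"):
            coherence_spectra(es, "E1")


class TestSpectralSNR:
    def test_flat_spectrum_gives_one(self):
        freqs = np.arange(0, 10, 0.2)
        assert spectral_snr(np.ones_like(freqs), freqs, 3.0) == pytest.approx(1.0)

    def test_tone_over_floor(self):
        freqs = np.arange(0, 10, 0.2)
        p = np.ones_like(freqs)
        p[int(3.0 / 0.2)] = 10.0  # tone of power 9 + unit floor
        assert spectral_snr(p, freqs, 3.0) == pytest.approx(10.0)

    def test_doubling_neighbours_halves_snr(self):
        rng = np.random.default_rng(12)
        freqs = np.arange(0, 10, 0.2)
        p = rng.uniform(0.5, 2.0, len(freqs))
        base = spectral_snr(p, freqs, 3.0)
        q = p.copy()
        i = int(3.0 / 0.2)
        q[i - 2] *= 2
        q[i + 2] *= 2
        assert spectral_snr(q, freqs, 3.0) == pytest.approx(base / 2)

    def test_edge_frequency_rejected(self):
        freqs = np.arange(0, 10, 0.2)
        with pytest.raises(ValueError):
            spectral_snr(np.ones_like(freqs), freqs, 0.2)


class TestPickPeaks:
    def _coupled_spectra(self, f0=1.5, gain=0.4, seed=13):
        from ckcpipe.synthetic import SubjectSimConfig, generate_subject
        from ckcpipe.preprocess import preprocess_recording
        cfg = SubjectSimConfig(movement_rate=f0, rate_jitter_sd=0.0,
                               coupling_gain_f0=gain, coupling_gain_f1=gain,
                               duration=60, n_trials=1, n_channels=16, seed=seed)
        rec = preprocess_recording(generate_subject(cfg).trials[0]).recording
        return coherence_spectra(reject_epochs(make_epochs(rec)), "EMG_FDI")

    def test_coupling_at_1p5_hz_found_at_f1_3hz(self):
        res = pick_peaks(self._coupled_spectra())
        assert abs(res.f0 - 1.5) <= 0.2 + 1e-9   # 1.5 Hz is off the 0.2 Hz grid
        assert res.f1 == pytest.approx(3.0)
        assert res.ckc_f1 > 0.3

    def test_on_grid_movement_rate_detected_exactly(self):
        res = pick_peaks(self._coupled_spectra(f0=1.2))
        assert res.f0 == pytest.approx(1.2)
        assert res.f1 == pytest.approx(2.4)
        assert res.electrode_f1 not in ("", None)

    def test_winning_electrode_is_not_edge_flagged(self):
        sp = self._coupled_spectra(f0=1.2)
        res = pick_peaks(sp)
        for el in (res.electrode_f0, res.electrode_f1):
            i = sp.channel_labels.index(el)
            assert not sp.edge_flags[i]

    def test_null_spectra_deterministic_tie_break(self):
        rng = np.random.default_rng(14)
        rec = _recording(rng.standard_normal((5, 60000)))
        sp = coherence_spectra(make_epochs(rec), "E4")
        a, b = pick_peaks(sp), pick_peaks(sp)
        assert (a.f0, a.electrode_f0) == (b.f0, b.electrode_f0)
        assert a.ckc_f0 < 0.3  # near the small-sample bias floor


class TestFourierSurrogate:
    def test_power_spectrum_preserved_bin_exact(self):
        rng = np.random.default_rng(15)
        for n in (1000, 1001):  # even and odd lengths
            x = rng.standard_normal(n)
            y = fourier_surrogate(x, rng)
            np.testing.assert_allclose(np.abs(np.fft.rfft(y)),
                                       np.abs(np.fft.rfft(x)), rtol=1e-9)
            assert np.isrealobj(y)

    def test_white_noise_surrogate_stays_white(self):
        rng = np.random.default_rng(16)
        x = rng.standard_normal(4000)
        specs = np.stack([np.abs(np.fft.rfft(fourier_surrogate(x, rng))) ** 2
                          for _ in range(50)])
        flatness = specs.mean(0)[1:-1]
        assert flatness.std() / flatness.mean() < 1.5  # no spectral structure

    def test_burst_train_loses_burst_shape(self, burst_train):
        from scipy.stats import kurtosis
        env, _ = burst_train
        rng = np.random.default_rng(17)
        surr = fourier_surrogate(env, rng)
        assert kurtosis(surr) < kurtosis(env) / 2


class TestSignificance:
    def _null_setup(self, seed=18, n_ch=6, duration=60):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((n_ch, int(duration * FS)))
        # reference: rectified band-limited noise, like a real rectified EMG
        from ckcpipe.preprocess import FilterSpec, filter_zero_lag, rectify
        x[-1] = rectify(filter_zero_lag(x[-1], FS, FilterSpec()))
        rec = _recording(x)
        es = reject_epochs(make_epochs(rec))
        return es, {0: x[-1]}, rec.channel_labels[-1]

    def test_threshold_reproducible_and_bounded(self):
        es, refs, ref = self._null_setup()
        a = significance_threshold(es, ref, refs, n_surrogates=60, seed=7)
        b = significance_threshold(es, ref, refs, n_surrogates=60, seed=7)
        assert a.threshold_95 == b.threshold_95
        assert 0 < a.threshold_95 < 1
        assert np.all((a.max_coherence_draws >= 0) & (a.max_coherence_draws <= 1))

    def test_threshold_invariant_to_channel_relabelling(self):
        es, refs, ref = self._null_setup()
        a = significance_threshold(es, ref, refs, n_surrogates=40, seed=9)
        # permute EEG channels (max statistic is symmetric in channels)
        perm = [2, 0, 1, 4, 3]
        es2 = EpochSet(
            epochs=np.concatenate([es.epochs[:, perm, :], es.epochs[:, 5:, :]],
                                  axis=1),
            sample_rate=es.sample_rate, epoch_length=es.epoch_length,
            overlap=es.overlap,
            channel_labels=[es.channel_labels[i] for i in perm] + [ref],
            channel_roles=es.channel_roles, edge_flags=None,
            starts=es.starts, trial_ids=es.trial_ids,
            epoch_peak_z=es.epoch_peak_z)
        b = significance_threshold(es2, ref, refs, n_surrogates=40, seed=9)
        assert a.threshold_95 == pytest.approx(b.threshold_95, rel=1e-9)

    def test_fast_blockwise_path_matches_direct_surrogate_coherence(self):
        """The GEMM-based surrogate coherence equals brute-force epoching of
        the same surrogate signal through coherence_spectra."""
        es, refs, ref_label = self._null_setup(n_ch=4, duration=30)
        null = significance_threshold(es, ref_label, refs, n_surrogates=20,
                                      seed=123)
        # recompute draw 0 by hand with the same surrogate realization
        rng = np.random.default_rng(123)
        amp = np.abs(np.fft.rfft(refs[0]))
        phases = rng.uniform(-np.pi, np.pi, size=(20, len(amp)))
        phases[:, 0] = 0.0
        phases[:, -1] = 0.0
        surr = np.fft.irfft(amp[None] * np.exp(1j * phases), n=len(refs[0]),
                            axis=1)
        draws = []
        for k in range(20):
            x = es.epochs.copy()
            sidx = es.channel_labels.index(ref_label)
            for e, s in enumerate(es.starts):
                x[e, sidx] = surr[k, s:s + 5000]
            es_k = EpochSet(epochs=x, sample_rate=es.sample_rate,
                            epoch_length=es.epoch_length, overlap=es.overlap,
                            channel_labels=es.channel_labels,
                            channel_roles=es.channel_roles,
                            edge_flags=es.edge_flags, starts=es.starts,
                            trial_ids=es.trial_ids, epoch_peak_z=es.epoch_peak_z)
            sp = coherence_spectra(es_k, ref_label)
            band = (sp.frequencies >= 1.0 - 1e-9) & (sp.frequencies <= 4.0 + 1e-9)
            eeg = [i for i, r in enumerate(es.channel_roles) if r == "EEG"]
            draws.append(sp.coherence[np.ix_(eeg, np.where(band)[0])].max())
        np.testing.assert_allclose(null.max_coherence_draws, draws, atol=1e-3)

    def test_too_few_surrogates_rejected(self):
        es, refs, ref = self._null_setup()
        with pytest.raises(ValueError, match="20 surrogates"):
            significance_threshold(es, ref, refs, n_surrogates=5, seed=0)


def test_strong_coupling_detected_with_high_power(small_subject):
    """Analytic coherence far above the null ceiling is declared significant."""
    from ckcpipe.preprocess import preprocess_recording
    trials = [preprocess_recording(r).recording for r in small_subject.trials]
    res = ckc_analysis(trials, n_surrogates=100, seed=21)
    assert res.significant_f1
    assert res.ckc_f1 > res.significance_threshold


def test_coherence_decreases_with_added_noise(small_subject):
    """Monotone degradation: adding independent EEG noise lowers peak CKC."""
    from ckcpipe.preprocess import preprocess_recording
    rec = preprocess_recording(small_subject.trials[0]).recording
    rng = np.random.default_rng(22)
    noise = rng.standard_normal(rec.samples[rec.eeg_indices].shape)
    c3 = rec.channel_labels.index("C3")
    values = []
    for extra in (0.0, 6.0, 30.0):
        noisy = rec.copy()
        noisy.samples[noisy.eeg_indices] += extra * noise
        sp = coherence_spectra(reject_epochs(make_epochs(noisy)), "EMG_FDI")
        i = int(round(2.4 / 0.2))  # F1 bin for the 1.2 Hz default rate
        values.append(sp.coherence[c3, i])
    assert values[0] > values[1] > values[2]


class TestMovementFrequency:
    def _spectra(self, rate, gain=0.0, seed=23):
        from ckcpipe.preprocess import preprocess_recording
        from ckcpipe.synthetic import SubjectSimConfig, generate_subject
        cfg = SubjectSimConfig(movement_rate=rate, coupling_gain_f0=gain,
                               coupling_gain_f1=gain, duration=60,
                               n_trials=1, n_channels=12, seed=seed)
        rec = preprocess_recording(generate_subject(cfg).trials[0]).recording
        return coherence_spectra(reject_epochs(make_epochs(rec)), "EMG_FDI")

    @pytest.mark.parametrize("rate", [1.0, 1.2, 1.4])
    def test_rate_read_from_emg_power_without_any_coupling(self, rate):
        from ckcpipe.coupling import movement_frequency
        # zero coupling: the rate line lives in the EMG burst envelope alone
        f = movement_frequency(self._spectra(rate))
        assert abs(f - rate) <= 0.2 + 1e-9

    def test_off_grid_rate_lands_on_neighbouring_bin(self):
        from ckcpipe.coupling import movement_frequency
        f = movement_frequency(self._spectra(1.3))
        assert min(abs(f - 1.2), abs(f - 1.4)) < 1e-9

    def test_band_outside_spectrum_rejected(self):
        from ckcpipe.coupling import movement_frequency
        with pytest.raises(ValueError, match="movement band"):
            movement_frequency(self._spectra(1.2), band=(600.0, 700.0))


def test_rate_anchoring_rescues_harmonic_capture():
    """A slow movement rate whose strong first harmonic falls at the top of
    the default movement band: the full-band search mistakes the harmonic
    for F0, the rate-anchored search does not."""
    from ckcpipe.preprocess import preprocess_recording
    from ckcpipe.synthetic import SubjectSimConfig, generate_subject
    cfg = SubjectSimConfig(movement_rate=1.0, coupling_gain_f0=0.05,
                           coupling_gain_f1=0.4, duration=60,
                           n_trials=1, n_channels=16, seed=24)
    trials = [preprocess_recording(r).recording
              for r in generate_subject(cfg).trials]
    anchored = ckc_analysis(trials, n_surrogates=0)
    assert anchored.f0 == pytest.approx(1.0)
    assert anchored.f1 == pytest.approx(2.0)
    free = ckc_analysis(trials, n_surrogates=0, rate_anchored=False)
    # the 2 Hz harmonic carries far more coherence and sits inside [0.8, 2]
    assert free.f0 == pytest.approx(2.0)
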