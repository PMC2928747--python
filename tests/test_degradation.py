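import numpy as np
import pytest

from songshare import (
    ChannelSpec,
    Recording,
    bandpass,
    degradation_table,
    degradation_wide,
    envelope,
    feature_correlations,
    mean_spectrum,
    propagate,
    spectrogram_xcorr,
)
from songshare.degradation import snr_db

SR = 48_000


def tone(freq, dur=0.5, sr=SR, amp=0.5):
    t = np.arange(int(dur * sr)) / sr
    return amp * np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_in_band_tone_preserved(self):
        rec = Recording(tone(3_000), SR)
        out = bandpass(rec)
        ratio = np.sqrt(np.mean(out.waveform**2) / np.mean(rec.waveform**2))
        assert abs(20 * np.log10(ratio)) < 1.0

    def test_out_of_band_tone_rejected(self):
        # 800 Hz is one octave below the 1.6 kHz edge
        rec = Recording(tone(800), SR)
        out = bandpass(rec)
        ratio = np.sqrt(np.mean(out.waveform**2) / np.mean(rec.waveform**2))
        assert 20 * np.log10(ratio) < -40.0

    def test_idempotent_in_band(self):
        rec = Recording(tone(4_000), SR)
        once = bandpass(rec)
        twice = bandpass(once)
        ratio = np.sqrt(np.mean(twice.waveform**2) / np.mean(once.waveform**2))
        assert abs(20 * np.log10(ratio)) < 1.0

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError, match="invalid band"):
            bandpass(Recording(tone(3_000), SR), low=7_000, high=1_600)


class TestEnvelope:
    def test_constant_tone_envelope_flat(self):
        env = envelope(Recording(tone(3_000, dur=1.0), SR))
        core = env[len(env) // 10 : -len(env) // 10]
        assert np.ptp(core) / np.mean(core) < 0.05

    def test_am_tone_envelope_tracks_modulator(self):
        t = np.arange(SR) / SR
        mod = 1.0 + 0.8 * np.sin(2 * np.pi * 10 * t)
        wave = 0.3 * mod * np.sin(2 * np.pi * 4_000 * t)
        env = envelope(Recording(wave, SR))
        step = SR // len(env) if len(env) < SR else 1
        mod_ds = mod[:: SR // 1000][: len(env)]
        core = slice(50, min(len(env), len(mod_ds)) - 50)
        r = np.corrcoef(env[core], mod_ds[core])[0, 1]
        assert r > 0.99

    def test_silence_gives_zero_envelope(self):
        env = envelope(Recording(np.zeros(SR // 2), SR))
        assert np.allclose(env, 0.0)

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError, match="smoothing_window"):
            envelope(Recording(tone(3_000), SR), smoothing_window=0)


class TestMeanSpectrum:
    def test_pure_tone_peak_bin(self):
        spec = mean_spectrum(Recording(tone(3_000, dur=1.0), SR), nfft=1_024)
        freqs = np.fft.rfftfreq(1_024, 1 / SR)
        assert abs(freqs[np.argmax(spec)] - 3_000) <= SR / 1_024

    def test_white_noise_flat_after_averaging(self):
        rng = np.random.default_rng(0)
        wave = rng.normal(size=SR * 3)  # > 100 frames of 1024 at 50% hop
        spec = mean_spectrum(Recording(wave, SR), nfft=1_024)
        core = spec[5:-5]
        assert 20 * np.log10(core.max() / core.min()) < 3.0

    def test_parseval_power_consistency(self):
        rng = np.random.default_rng(1)
        wave = rng.normal(size=SR)
        spec = mean_spectrum(Recording(wave, SR), nfft=1_024)
        # Welch PSD integrates to signal power: spectrum is sqrt(PSD)
        df = SR / 1_024
        power = np.sum(spec**2) * df
        assert power == pytest.approx(np.mean(wave**2), rel=0.01)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError, match="nfft"):
            mean_spectrum(Recording(np.ones(100), SR), nfft=1_024)


class TestSpectrogramXcorr:
    def test_identity_peak_at_zero_lag(self, song_wave):
        _, control = song_wave
        r, lag = spectrogram_xcorr(control, control)
        assert r == pytest.approx(1.0, abs=1e-12) and lag == 0.0

    def test_delayed_copy_found_at_correct_lag(self, song_wave):
        wave, control = song_wave
        delayed = Recording(np.concatenate([np.zeros(int(0.25 * SR)), wave]), SR)
        r, lag = spectrogram_xcorr(control, delayed, nfft=256)
        hop = 128 / SR
        assert r >= 0.99
        assert abs(lag - 0.25) <= hop + 1e-9

    def test_independent_noise_uncorrelated(self, song_wave):
        _, control = song_wave
        rng = np.random.default_rng(3)
        noise = Recording(rng.normal(0, 0.1, len(control.waveform)), SR)
        r, _ = spectrogram_xcorr(control, noise)
        assert r < 0.3

    def test_sample_rate_mismatch_rejected(self, song_wave):
        _, control = song_wave
        with pytest.raises(ValueError, match="sample-rate"):
            spectrogram_xcorr(control, Recording(control.waveform, 44_100))


class TestDegradationTable:
    def test_identity_recordings_give_unit_correlations(self, song_wave):
        wave, control = song_wave
        prop = Recording(wave, SR, "propagated", 12.5, 2.0, 0)
        table = degradation_table([control], [prop], band=None)
        assert np.allclose(table["r"], 1.0)
        assert table["usable"].all()

    def test_correlations_scale_invariant(self, song_wave):
        """Feature correlations ignore a global rescaling of the test
        waveform (the field protocol RMS-equalizes stimuli)."""
        wave, control = song_wave
        ch = ChannelSpec(distance=50.0, noise_floor=0.0, seed=0)
        y = propagate(wave, ch, SR)
        r1 = feature_correlations(control, Recording(y, SR))
        r2 = feature_correlations(control, Recording(7.3 * y, SR))
        for f in r1:
            assert r1[f] == pytest.approx(r2[f], abs=1e-9)

    def test_time_shift_invariance(self, song_wave):
        wave, control = song_wave
        shifted = Recording(np.concatenate([np.zeros(int(0.1 * SR)), wave]), SR)
        r0 = feature_correlations(control, Recording(wave, SR))
        r1 = feature_correlations(control, shifted)
        assert abs(r0["envelope"] - r1["envelope"]) <= 0.01
        assert abs(r0["spectrogram"] - r1["spectrogram"]) <= 0.01

    def test_all_noise_cells_flagged_unusable(self, song_wave):
        wave, control = song_wave
        rng = np.random.default_rng(5)
        noise = rng.normal(0, 5e-4, len(wave))
        prop = Recording(noise, SR, "propagated", 400.0, 2.0, 0)
        table = degradation_table([control], [prop])
        assert not table["usable"].any()
        assert table["r"].isna().all()

    def test_mismatched_exemplars_error_names_cell(self, song_wave):
        wave, control = song_wave
        prop = Recording(wave, SR, "propagated", 12.5, 2.0, exemplar=3)
        with pytest.raises(ValueError, match="distance=12.5"):
            degradation_table([control], [prop])

    def test_wide_layout_mirrors_long_table(self, song_wave):
        wave, control = song_wave
        props = [
            Recording(propagate(wave, ChannelSpec(distance=d, seed=1), SR),
                      SR, "propagated", d, 2.0, 0)
            for d in (12.5, 50.0)
        ]
        long = degradation_table([control], props)
        wide = degradation_wide(long)
        assert wide.shape == (3, 2)
        row = long[(long.feature == "spectrum") & (long.distance == 50.0)]
        assert wide.loc[("spectrum", 2.0), 50.0] == row["r"].iloc[0]
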