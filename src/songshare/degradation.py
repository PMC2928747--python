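"""Transmission-degradation analysis of propagated recordings.

Each propagated re-recording is compared with a close-range control along
three acoustic features: the amplitude envelope (main amplitude fluctuations),
the averaged magnitude spectrum (frequency composition), and the magnitude
spectrogram via spectrographic cross-correlation (frequency modulation).
Per (height, distance) cell the Bravais-Pearson r against the control is
averaged over exemplars, yielding a table of mean r per feature x height x
distance; cells whose signal power sits within 3 dB of the background noise
are flagged unusable rather than correlated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .permstats import pearson_r

FEATURES = ("envelope", "spectrum", "spectrogram")

BAND_LOW_HZ = 1_600.0
BAND_HIGH_HZ = 7_000.0


@dataclass(frozen=True)
class Recording:
    waveform: np.ndarray
    sample_rate: int
    role: str = "propagated"  # "control" | "propagated"
    distance: float = np.nan
    height: float = np.nan
    exemplar: int = 0

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if len(np.asarray(self.waveform)) == 0:
            raise ValueError("waveform must be non-empty")


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def bandpass(
    rec: Recording,
    low: float = BAND_LOW_HZ,
    high: float = BAND_HIGH_HZ,
    order: int = 5,
) -> Recording:
    """Zero-phase Butterworth band-pass (default 1.6-7 kHz song band).

    Forward-backward filtering doubles the effective order, giving well over
    40 dB rejection one octave outside the band.
    """
    if not 0 < low < high < rec.sample_rate / 2:
        raise ValueError(
            f"invalid band [{low}, {high}] Hz for sample rate {rec.sample_rate}"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", output="sos",
                     fs=rec.sample_rate)
    y = sps.sosfiltfilt(sos, np.asarray(rec.waveform, dtype=float))
    return replace(rec, waveform=y)


def envelope(
    rec: Recording,
    smoothing_window: float = 0.01,
    env_rate: float = 1_000.0,
) -> np.ndarray:
    """Amplitude envelope: magnitude of the analytic signal, smoothed by a
    moving average of ``smoothing_window`` seconds and decimated to
    ``env_rate`` Hz.  Non-negative by construction."""
    if smoothing_window <= 0:
        raise ValueError("smoothing_window must be > 0")
    x = np.asarray(rec.waveform, dtype=float)
    win = int(round(smoothing_window * rec.sample_rate))
    if len(x) <= win:
        raise ValueError("waveform shorter than the smoothing window")
    env = np.abs(sps.hilbert(x))
    kernel = np.ones(win) / win
    env = np.convolve(env, kernel, mode="same")
    step = max(int(round(rec.sample_rate / env_rate)), 1)
    return env[::step]


def mean_spectrum(rec: Recording, nfft: int = 1_024) -> np.ndarray:
    """Magnitude spectrum averaged over successive frames (Welch-style),
    length nfft/2 + 1."""
    x = np.asarray(rec.waveform, dtype=float)
    if len(x) < nfft:
        raise ValueError(f"waveform shorter than nfft ({len(x)} < {nfft})")
    _, psd = sps.welch(x, fs=rec.sample_rate, window="hann", nperseg=nfft,
                       noverlap=nfft // 2)
    return np.sqrt(psd)


def _magnitude_spectrogram(rec: Recording, nfft: int) -> tuple[np.ndarray, float]:
    """Magnitude spectrogram and its hop in seconds (Hann window, 50% hop)."""
    hop = nfft // 2
    _, _, Z = sps.stft(np.asarray(rec.waveform, dtype=float),
                       fs=rec.sample_rate, window="hann", nperseg=nfft,
                       noverlap=nfft - hop, boundary=None, padded=False)
    return np.abs(Z), hop / rec.sample_rate


def spectrogram_xcorr(
    control: Recording,
    test: Recording,
    nfft: int = 256,
    max_lag: float = 0.5,
) -> tuple[float, float]:
    """Spectrographic cross-correlation: the peak normalized correlation of
    the two magnitude spectrograms over time lags within +/- max_lag seconds,
    and the lag (s) at which it occurs."""
    if control.sample_rate != test.sample_rate:
        raise ValueError(
            f"sample-rate mismatch: {control.sample_rate} vs {test.sample_rate}"
        )
    A, hop_s = _magnitude_spectrogram(control, nfft)
    B, _ = _magnitude_spectrogram(test, nfft)
    if A.shape[1] < 1 or B.shape[1] < 1:
        raise ValueError("recording shorter than one analysis frame")
    max_lag_frames = max(int(round(max_lag / hop_s)), 0)

    best_r, best_lag = -1.0, 0.0
    for lag in range(-max_lag_frames, max_lag_frames + 1):
        # Positive lag: test delayed relative to control.
        a_lo, b_lo = max(0, -lag), max(0, lag)
        width = min(A.shape[1] - a_lo, B.shape[1] - b_lo)
        if width < 2:
            continue
        a = A[:, a_lo : a_lo + width].ravel()
        b = B[:, b_lo : b_lo + width].ravel()
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            continue
        r = pearson_r(a, b)
        if r > best_r:
            best_r, best_lag = r, lag * hop_s
    if best_r < -1.0 + 1e-12 and best_lag == 0.0:
        raise ValueError("no overlapping frames within max_lag")
    return best_r, best_lag


# ---------------------------------------------------------------------------
# Pairwise feature correlations and the degradation table
# ---------------------------------------------------------------------------

def _aligned_envelope_r(env_c: np.ndarray, env_t: np.ndarray) -> float:
    """Pearson r between envelopes after alignment at the cross-correlation
    best lag (an unaligned r would measure recorder timing, not degradation)."""
    c = env_c - env_c.mean()
    t = env_t - env_t.mean()
    xc = sps.correlate(t, c, mode="full")
    lag = int(np.argmax(xc)) - (len(c) - 1)
    t_lo, c_lo = max(0, lag), max(0, -lag)
    width = min(len(env_t) - t_lo, len(env_c) - c_lo)
    if width < 2:
        raise ValueError("envelopes do not overlap after alignment")
    return pearson_r(env_c[c_lo : c_lo + width], env_t[t_lo : t_lo + width])


def feature_correlations(
    control: Recording,
    test: Recording,
    nfft_spectrum: int = 1_024,
    nfft_spectrogram: int = 256,
    max_lag: float = 0.5,
) -> dict[str, float]:
    """r per feature between one propagated recording and its control."""
    return {
        "envelope": _aligned_envelope_r(envelope(control), envelope(test)),
        "spectrum": pearson_r(mean_spectrum(control, nfft_spectrum),
                              mean_spectrum(test, nfft_spectrum)),
        "spectrogram": spectrogram_xcorr(control, test, nfft_spectrogram,
                                         max_lag)[0],
    }


def snr_db(rec: Recording) -> float:
    """Crude signal-to-noise estimate from the smoothed amplitude envelope:
    song peaks (95th percentile) against the background floor read from the
    quietest decile (song has silent gaps, so that decile is background).
    A signal indistinguishable from stationary noise scores near 0 dB."""
    env = envelope(rec)
    floor = float(np.quantile(env, 0.10))
    peak = float(np.quantile(env, 0.95))
    if floor <= 0:
        return np.inf if peak > 0 else 0.0
    return 20.0 * np.log10(peak / floor)


def degradation_table(
    controls: list[Recording],
    propagated: list[Recording],
    nfft_spectrum: int = 1_024,
    nfft_spectrogram: int = 256,
    max_lag: float = 0.5,
    band: tuple[float, float] | None = (BAND_LOW_HZ, BAND_HIGH_HZ),
    snr_floor_db: float = 3.0,
) -> pd.DataFrame:
    """Mean r per feature x height x distance, averaged over exemplars.

    Controls are matched to propagated recordings by exemplar index; every
    (height, distance) cell must contain the same exemplar set as the
    controls.  Cells whose median SNR falls below ``snr_floor_db`` (signal
    indistinguishable from background noise) get usable=False and NaN r.

    Returns a long-format DataFrame: feature, height, distance, r,
    n_exemplars, usable.
    """
    if not controls or not propagated:
        raise ValueError("need at least one control and one propagated recording")
    if band is not None:
        controls = [bandpass(r, *band) for r in controls]
        propagated = [bandpass(r, *band) for r in propagated]
    ctrl_by_ex = {r.exemplar: r for r in controls}

    cells: dict[tuple[float, float], list[Recording]] = {}
    for r in propagated:
        cells.setdefault((r.height, r.distance), []).append(r)

    rows = []
    for (height, dist) in sorted(cells):
        recs = cells[(height, dist)]
        exemplars = sorted(r.exemplar for r in recs)
        if exemplars != sorted(ctrl_by_ex):
            raise ValueError(
                f"cell (height={height}, distance={dist}) has exemplars "
                f"{exemplars}, controls have {sorted(ctrl_by_ex)}"
            )
        snrs = [snr_db(r) for r in recs]
        usable = bool(np.median(snrs) >= snr_floor_db)
        per_feature: dict[str, list[float]] = {f: [] for f in FEATURES}
        if usable:
            for r in recs:
                fc = feature_correlations(ctrl_by_ex[r.exemplar], r,
                                          nfft_spectrum, nfft_spectrogram,
                                          max_lag)
                for f in FEATURES:
                    per_feature[f].append(fc[f])
        for f in FEATURES:
            rows.append({
                "feature": f,
                "height": height,
                "distance": dist,
                "r": float(np.mean(per_feature[f])) if usable else np.nan,
                "n_exemplars": len(recs),
                "usable": usable,
            })
    return pd.DataFrame(rows, columns=["feature", "height", "distance", "r",
                                       "n_exemplars", "usable"])


def degradation_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long table into feature x height rows by distance columns."""
    return table.pivot_table(index=["feature", "height"], columns="distance",
                             values="r", dropna=False)
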