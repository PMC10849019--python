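"""Preprocessing: bad-channel handling, re-referencing and EMG filtering.

EEG channels are screened with three robust criteria (wide-band amplitude,
high/low-frequency amplitude ratio, correlation with the other channels),
interpolated from their neighbours when flagged, and re-referenced to the
common average.  EMG channels are band-pass filtered 20-295 Hz with notches
at the power-line frequency and its harmonics using a zero-lag FFT-domain
filter, then rectified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recording import Recording


@dataclass(frozen=True)
class FilterSpec:
    """Zero-lag FFT-domain band-pass + notch filter description.

    ``band`` is the pass band in Hz; raised-cosine transitions of width
    ``transition`` Hz are centred on each band edge.  Notches are placed at
    ``notch_fundamental`` and its harmonics up to the band's upper edge
    (``notch_harmonics="auto"``) or at a fixed count of harmonics, each a
    raised-cosine stop of half-width ``notch_halfwidth`` Hz.
    """

    band: tuple[float, float] = (20.0, 295.0)
    notch_fundamental: float = 50.0
    notch_harmonics: int | str = "auto"
    transition: float = 1.0
    notch_halfwidth: float = 1.0

    def validate(self, sample_rate: float) -> None:
        low, high = self.band
        nyq = sample_rate / 2.0
        if not (0 <= low < high < nyq):
            raise ValueError(f"band {self.band} must satisfy 0 <= low < high < Nyquist ({nyq} Hz)")
        if self.notch_fundamental <= 0 or self.notch_fundamental >= nyq:
            raise ValueError("notch fundamental must lie below Nyquist")

    def notch_frequencies(self, sample_rate: float) -> list[float]:
        low, high = self.band
        if self.notch_harmonics == "auto":
            kmax = int(np.floor(high / self.notch_fundamental))
        else:
            kmax = int(self.notch_harmonics)
        freqs = [self.notch_fundamental * k for k in range(1, kmax + 1)]
        return [f for f in freqs if f < sample_rate / 2.0]


@dataclass
class BadChannelThresholds:
    """Robust-z thresholds for the three bad-channel criteria."""

    amplitude_z: float = 5.0
    noisiness_z: float = 3.0
    correlation_min: float = 0.4


def _raised_cosine_step(f: np.ndarray, edge: float, width: float, rising: bool) -> np.ndarray:
    """Smooth 0->1 (rising) or 1->0 step centred on ``edge`` over ``width`` Hz."""
    x = np.clip((f - (edge - width / 2.0)) / max(width, 1e-12), 0.0, 1.0)
    ramp = 0.5 - 0.5 * np.cos(np.pi * x)
    return ramp if rising else 1.0 - ramp


def filter_mask(freqs: np.ndarray, spec: FilterSpec, sample_rate: float) -> np.ndarray:
    """Frequency-domain gain mask implementing the band-pass + notches."""
    low, high = spec.band
    mask = np.ones_like(freqs)
    if low > 0:
        mask *= _raised_cosine_step(freqs, low, spec.transition, rising=True)
    mask *= _raised_cosine_step(freqs, high, spec.transition, rising=False)
    for f0 in spec.notch_frequencies(sample_rate):
        d = np.abs(freqs - f0)
        notch = np.ones_like(freqs)
        inside = d < spec.notch_halfwidth
        notch[inside] = 0.5 - 0.5 * np.cos(np.pi * d[inside] / spec.notch_halfwidth)
        mask *= notch
    return mask


def filter_zero_lag(signal: np.ndarray, sample_rate: float, spec: FilterSpec) -> np.ndarray:
    """Apply the zero-lag FFT-domain filter along the last axis.

    The gain mask is real and even in frequency, so the filter has exactly
    zero phase shift (a passband sinusoid and its filtered version peak at
    lag 0 in cross-correlation).
    """
    spec.validate(sample_rate)
    x = np.asarray(signal, dtype=float)
    n = x.shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    if n < int(sample_rate / max(spec.transition, 1e-9)):
        raise ValueError("signal too short for the requested transition width")
    spec_f = np.fft.rfft(x, axis=-1)
    return np.fft.irfft(spec_f * filter_mask(freqs, spec, sample_rate), n=n, axis=-1)


def rectify(signal: np.ndarray) -> np.ndarray:
    """Full-wave rectification (elementwise absolute value)."""
    return np.abs(np.asarray(signal, dtype=float))


# ---------------------------------------------------------------------------
# Bad channels
# ---------------------------------------------------------------------------

def _robust_z(values: np.ndarray, scale_floor: float) -> np.ndarray:
    """Deviation from the median in units of the MAD-derived robust SD.

    The scale is floored so that a nearly homogeneous channel population
    (MAD ~ 0) does not turn negligible fluctuations into huge z-scores; for
    log-amplitude metrics the floor is expressed as a log-ratio.
    """
    med = np.median(values)
    scale = max(1.4826 * np.median(np.abs(values - med)), scale_floor)
    return (values - med) / scale


def detect_bad_channels(rec: Recording,
                        thresholds: BadChannelThresholds | None = None) -> list[str]:
    """Flag noisy EEG channels by three robust criteria.

    A channel is flagged when (1) its robust z-scored log wide-band RMS
    amplitude exceeds ``amplitude_z``, or (2) the robust z-score of its
    high/low-frequency amplitude ratio exceeds ``noisiness_z``, or (3) its
    best absolute correlation with any other (low-passed) EEG channel falls
    below ``correlation_min``.
    """
    thresholds = thresholds or BadChannelThresholds()
    eeg = rec.eeg_indices
    if len(eeg) < 8:
        raise ValueError("bad-channel detection requires at least 8 EEG channels")
    x = rec.samples[eeg]
    x = x - x.mean(axis=1, keepdims=True)
    fs = rec.sample_rate

    rms = np.sqrt(np.mean(x ** 2, axis=1))
    if np.any(rms <= 0):
        flat = [rec.channel_labels[eeg[i]] for i in np.where(rms <= 0)[0]]
        raise ValueError(f"flat EEG channels (zero amplitude): {flat}")
    amp_z = _robust_z(np.log(rms), scale_floor=np.log(1.1))

    # split at 40 Hz: EEG power is concentrated below, broadband noise above
    spec = np.abs(np.fft.rfft(x, axis=1))
    freqs = np.fft.rfftfreq(x.shape[1], d=1.0 / fs)
    lo = np.sqrt(np.mean(spec[:, (freqs >= 1) & (freqs < 40)] ** 2, axis=1))
    hi = np.sqrt(np.mean(spec[:, (freqs >= 40) & (freqs < fs / 2 - 1)] ** 2, axis=1))
    ratio_z = _robust_z(np.log(hi / np.maximum(lo, 1e-30)), scale_floor=np.log(1.25))

    # correlation criterion on 1-40 Hz signals to avoid line-noise dominance
    mask = (freqs >= 1) & (freqs < 40)
    fspec = np.fft.rfft(x, axis=1)
    fspec[:, ~mask] = 0
    xl = np.fft.irfft(fspec, n=x.shape[1], axis=1)
    sd = xl.std(axis=1)
    corr = np.corrcoef(xl) if np.all(sd > 0) else np.eye(len(eeg))
    np.fill_diagonal(corr, 0.0)
    best_corr = np.max(np.abs(corr), axis=1)

    flagged = (amp_z > thresholds.amplitude_z) | (ratio_z > thresholds.noisiness_z) \
        | (best_corr < thresholds.correlation_min)
    if np.all(flagged):
        raise ValueError("all EEG channels flagged as bad; recording unusable "
                         f"(amplitude z range {amp_z.min():.1f}..{amp_z.max():.1f})")
    return [rec.channel_labels[eeg[i]] for i in np.where(flagged)[0]]


def interpolate_channels(rec: Recording, flagged: list[str], k: int = 4) -> Recording:
    """Replace flagged EEG channels by an inverse-distance average of the
    ``k`` nearest non-flagged EEG neighbours on the 2-D layout."""
    if not flagged:
        return rec.copy()
    if rec.layout is None:
        raise ValueError("interpolation requires a 2-D electrode layout")
    out = rec.copy()
    eeg = rec.eeg_indices
    eeg_labels = [rec.channel_labels[i] for i in eeg]
    unknown = set(flagged) - set(eeg_labels)
    if unknown:
        raise ValueError(f"flagged channels not found among EEG channels: {sorted(unknown)}")
    bad_idx = [rec.channel_labels.index(lab) for lab in flagged]
    good_idx = [i for i in eeg if i not in bad_idx and np.all(np.isfinite(rec.layout[i]))]
    if not good_idx:
        raise ValueError("no good EEG channels left to interpolate from")
    for bi in bad_idx:
        d = np.linalg.norm(rec.layout[good_idx] - rec.layout[bi], axis=1)
        if not np.any(np.isfinite(d)):
            raise ValueError(f"channel {rec.channel_labels[bi]!r} has no located neighbours")
        order = np.argsort(d)[:k]
        w = 1.0 / np.maximum(d[order], 1e-9)
        w /= w.sum()
        out.samples[bi] = w @ rec.samples[np.array(good_idx)[order]]
    return out


def rereference_common_average(rec: Recording) -> Recording:
    """Subtract the instantaneous mean across EEG channels from each EEG channel."""
    eeg = rec.eeg_indices
    if len(eeg) == 0:
        raise ValueError("no EEG channels to re-reference")
    out = rec.copy()
    out.samples[eeg] -= out.samples[eeg].mean(axis=0, keepdims=True)
    return out


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

@dataclass
class PreprocessResult:
    recording: Recording
    bad_channels: list[str] = field(default_factory=list)


def preprocess_recording(rec: Recording,
                         emg_filter: FilterSpec | None = None,
                         bad_thresholds: BadChannelThresholds | None = None,
                         interpolate: bool = True,
                         cleanup_hook=None) -> PreprocessResult:
    """Standard preprocessing chain for one trial.

    EEG: bad-channel detection (+ optional interpolation), common-average
    reference.  EMG: zero-lag band-pass/notch filter and rectification.
    ``cleanup_hook`` is an optional callable ``Recording -> Recording``
    applied to the EEG after re-referencing (e.g. externally ICA-cleaned
    data can be substituted here); it is plumbing only and defaults to a
    pass-through.
    """
    emg_filter = emg_filter or FilterSpec()
    bad: list[str] = []
    out = rec.copy()
    if len(rec.eeg_indices) >= 8:
        bad = detect_bad_channels(rec, bad_thresholds)
        if bad and interpolate:
            out = interpolate_channels(out, bad)
        out = rereference_common_average(out)
        if cleanup_hook is not None:
            out = cleanup_hook(out)
    emg = out.emg_indices
    if len(emg):
        out.samples[emg] = rectify(
            filter_zero_lag(out.samples[emg], out.sample_rate, emg_filter))
    return PreprocessResult(recording=out, bad_channels=bad)
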