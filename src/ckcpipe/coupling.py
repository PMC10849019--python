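"""Corticokinematic coherence (CKC): spectra, peak picking, surrogate tests.

Continuous trials are split into 5 s epochs with 4 s overlap (0.2 Hz
frequency resolution), epochs with extreme EEG amplitude are rejected, and
magnitude-squared coherence is computed between each EEG channel and the
rectified reference EMG (first dorsal interosseous).  CKC peaks are read out
at the movement frequency F0 and its first harmonic F1 over non-edge
electrodes, together with a spectral SNR.  Statistical significance uses
Fourier-transform surrogates of the reference: the threshold is the 95th
percentile of the maximum surrogate coherence across 1-4 Hz and the
considered electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recording import Recording


@dataclass
class EpochSet:
    """Pooled sliding epochs (epoch x channel x time) with rejection metadata.

    ``epoch_peak_z`` holds, per epoch, the maximum absolute deviation of any
    EEG sample from its channel mean in units of the channel SD, both
    computed over the full source trial before epoching; amplitude rejection
    thresholds this number.
    """

    epochs: np.ndarray
    sample_rate: float
    epoch_length: float
    overlap: float
    channel_labels: list[str]
    channel_roles: list[str]
    edge_flags: np.ndarray | None
    starts: np.ndarray
    trial_ids: np.ndarray
    epoch_peak_z: np.ndarray
    rejected_epoch_ids: list[int] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def frequency_resolution(self) -> float:
        return 1.0 / self.epoch_length


def expected_epoch_count(duration: float, epoch_length: float = 5.0,
                         overlap: float = 4.0) -> int:
    stride = epoch_length - overlap
    if duration < epoch_length:
        return 0
    return int(np.floor((duration - epoch_length) / stride)) + 1


def make_epochs(rec: Recording, epoch_length: float = 5.0, overlap: float = 4.0,
                trial_id: int = 0) -> EpochSet:
    """Sliding epochs over one trial (trials are epoched separately and then
    pooled; epochs never straddle trial boundaries)."""
    if overlap >= epoch_length:
        raise ValueError("overlap must be smaller than the epoch length")
    n_len = int(round(epoch_length * rec.sample_rate))
    stride = int(round((epoch_length - overlap) * rec.sample_rate))
    if rec.n_samples < n_len:
        raise ValueError(
            f"recording ({rec.duration:.1f} s) shorter than one epoch ({epoch_length} s)")
    starts = np.arange(0, rec.n_samples - n_len + 1, stride)
    epochs = np.stack([rec.samples[:, s:s + n_len] for s in starts])

    eeg = rec.eeg_indices
    if len(eeg):
        x = rec.samples[eeg]
        mean = x.mean(axis=1)
        sd = x.std(axis=1)
        sd = np.where(sd > 0, sd, np.inf)
        # per-sample worst deviation across EEG channels, then per-epoch max
        zmax = np.max(np.abs(x - mean[:, None]) / sd[:, None], axis=0)
        peak_z = np.array([zmax[s:s + n_len].max() for s in starts])
    else:
        peak_z = np.zeros(len(starts))
    return EpochSet(
        epochs=epochs, sample_rate=rec.sample_rate, epoch_length=epoch_length,
        overlap=overlap, channel_labels=list(rec.channel_labels),
        channel_roles=list(rec.channel_roles), edge_flags=rec.edge_flags,
        starts=starts, trial_ids=np.full(len(starts), trial_id),
        epoch_peak_z=peak_z,
    )


def pool_epochs(sets: list[EpochSet]) -> EpochSet:
    """Concatenate epoch sets from several trials of one subject."""
    first = sets[0]
    for es in sets[1:]:
        if es.channel_labels != first.channel_labels:
            raise ValueError("cannot pool epochs with different channel sets")
    return EpochSet(
        epochs=np.concatenate([es.epochs for es in sets]),
        sample_rate=first.sample_rate, epoch_length=first.epoch_length,
        overlap=first.overlap, channel_labels=first.channel_labels,
        channel_roles=first.channel_roles, edge_flags=first.edge_flags,
        starts=np.concatenate([es.starts for es in sets]),
        trial_ids=np.concatenate([es.trial_ids for es in sets]),
        epoch_peak_z=np.concatenate([es.epoch_peak_z for es in sets]),
    )


def reject_epochs(es: EpochSet, sd_threshold: float = 5.0) -> EpochSet:
    """Drop epochs where any EEG sample deviates more than ``sd_threshold``
    channel SDs from the channel mean (statistics from the full trial)."""
    keep = es.epoch_peak_z <= sd_threshold
    if not np.any(keep):
        raise ValueError(
            f"all {es.n_epochs} epochs rejected at {sd_threshold} SD; "
            "recording too artefacted to analyse")
    rejected = list(np.where(~keep)[0])
    return EpochSet(
        epochs=es.epochs[keep], sample_rate=es.sample_rate,
        epoch_length=es.epoch_length, overlap=es.overlap,
        channel_labels=es.channel_labels, channel_roles=es.channel_roles,
        edge_flags=es.edge_flags, starts=es.starts[keep],
        trial_ids=es.trial_ids[keep], epoch_peak_z=es.epoch_peak_z[keep],
        rejected_epoch_ids=rejected,
    )


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

@dataclass
class SpectraSet:
    """Averaged power, cross- and magnitude-squared-coherence spectra.

    ``power`` and ``coherence`` are (n_channels, n_freqs); ``cross`` is the
    complex cross-spectrum of each channel with the reference EMG.
    """

    power: np.ndarray
    cross: np.ndarray
    coherence: np.ndarray
    frequencies: np.ndarray
    channel_labels: list[str]
    channel_roles: list[str]
    edge_flags: np.ndarray | None
    reference_label: str
    n_epochs: int


def _taper(name: str, n: int) -> np.ndarray:
    if name == "hann":
        # periodic Hann (denominator n, not n - 1): the spectral-estimation
        # convention, whose DFT has exact support on bins {0, +-1}
        return 0.5 - 0.5 * np.cos(2.0 * np.pi * np.arange(n) / n)
    if name in (None, "none", "boxcar"):
        return np.ones(n)
    raise ValueError(f"unknown taper {name!r}")


def coherence_spectra(es: EpochSet, reference_label: str,
                      taper: str = "hann") -> SpectraSet:
    """Welch-style averaged spectra between every channel and the reference.

    Per-epoch tapered FFTs are averaged into power and cross spectra;
    magnitude-squared coherence is |Sxy|^2 / (Sxx Syy).  At least two
    retained epochs are required (single-epoch coherence is identically 1).
    """
    if es.n_epochs < 2:
        raise ValueError("coherence needs at least 2 epochs (it is trivially 1 with one)")
    try:
        ref_idx = es.channel_labels.index(reference_label)
    except ValueError as err:
        raise KeyError(f"reference channel {reference_label!r} not found") from err
    n = es.epochs.shape[2]
    win = _taper(taper, n)
    fx = np.fft.rfft(es.epochs * win, axis=2)
    # epoch-mean subtraction, applied in the spectral domain by linearity:
    # rfft((x - m) w) = rfft(x w) - m rfft(w), and rfft(w) is non-zero on a
    # handful of low bins only, so the correction is cheap
    spec_w = np.fft.rfft(win)
    low = np.where(np.abs(spec_w) > 1e-12 * np.abs(spec_w[0]))[0]
    fx[:, :, low] -= es.epochs.mean(axis=2)[:, :, None] * spec_w[low]
    fr, fi = fx.real, fx.imag
    power = (np.einsum("ijk,ijk->jk", fr, fr)
             + np.einsum("ijk,ijk->jk", fi, fi)) / es.n_epochs
    rr, ri = fr[:, ref_idx], fi[:, ref_idx]
    cross = (np.einsum("ijk,ik->jk", fr, rr) + np.einsum("ijk,ik->jk", fi, ri)
             + 1j * (np.einsum("ijk,ik->jk", fi, rr)
                     - np.einsum("ijk,ik->jk", fr, ri))) / es.n_epochs
    denom = power * power[ref_idx]
    coherence = np.abs(cross) ** 2 / np.where(denom > 0, denom, np.inf)
    return SpectraSet(
        power=power, cross=cross, coherence=np.clip(coherence, 0.0, 1.0),
        frequencies=np.fft.rfftfreq(n, d=1.0 / es.sample_rate),
        channel_labels=es.channel_labels, channel_roles=es.channel_roles,
        edge_flags=es.edge_flags, reference_label=reference_label,
        n_epochs=es.n_epochs,
    )


def spectral_snr(power_row: np.ndarray, frequencies: np.ndarray, f: float) -> float:
    """Power at ``f`` divided by the geometric mean of power 2 bins away."""
    df = frequencies[1] - frequencies[0]
    i = int(round(f / df))
    if i < 2 or i + 2 >= len(frequencies):
        raise ValueError(f"frequency {f} Hz too close to the spectrum edge")
    lo, hi = power_row[i - 2], power_row[i + 2]
    if lo <= 0 or hi <= 0:
        raise ValueError("zero neighbour power; SNR undefined")
    return float(power_row[i] / np.sqrt(lo * hi))


# ---------------------------------------------------------------------------
# Peak picking
# ---------------------------------------------------------------------------

@dataclass
class CKCResult:
    f0: float
    f1: float
    ckc_f0: float
    ckc_f1: float
    electrode_f0: str
    electrode_f1: str
    snr_f0: float
    snr_f1: float
    significance_threshold: float | None = None
    significant_f0: bool | None = None
    significant_f1: bool | None = None
    n_epochs: int = 0
    spectra: SpectraSet | None = None
    surrogate_null: "SurrogateNull | None" = None


def _considered_channels(spectra: SpectraSet) -> np.ndarray:
    """EEG channels that enter peak picking: non-edge (or all EEG if no
    layout information is attached)."""
    roles = np.array(spectra.channel_roles)
    mask = roles == "EEG"
    if spectra.edge_flags is not None:
        mask &= ~spectra.edge_flags
    if not np.any(mask):
        raise ValueError("no non-edge EEG channels available for peak picking")
    return np.where(mask)[0]


def movement_frequency(spectra: SpectraSet,
                       band: tuple[float, float] = (0.8, 2.0)) -> float:
    """Movement rate estimated from the reference EMG power spectrum.

    The rectified EMG of a rhythmic task carries a strong spectral line at
    the movement rate (the per-cycle burst envelope), independent of any
    cortical coupling, so the power maximum of the reference channel within
    the candidate band identifies the rate to within one frequency bin.
    """
    ref = spectra.channel_labels.index(spectra.reference_label)
    freqs = spectra.frequencies
    in_band = (freqs >= band[0] - 1e-9) & (freqs <= band[1] + 1e-9)
    if not np.any(in_band):
        raise ValueError("spectra do not cover the movement band")
    idx = np.where(in_band)[0]
    return float(freqs[idx[np.argmax(spectra.power[ref, idx])]])


def pick_peaks(spectra: SpectraSet, movement_band: tuple[float, float] = (0.8, 2.0),
               ) -> CKCResult:
    """Locate CKC maxima at F0 (within the movement band) and F1 (within one
    frequency bin of 2 x F0), over non-edge EEG electrodes.

    Ties resolve to the lowest channel index then lowest frequency
    (deterministic).  SNR is evaluated on the winning electrode's power
    spectrum at the winning frequency.
    """
    chans = _considered_channels(spectra)
    freqs = spectra.frequencies
    df = freqs[1] - freqs[0]
    in_band = (freqs >= movement_band[0] - 1e-9) & (freqs <= movement_band[1] + 1e-9)
    if not np.any(in_band):
        raise ValueError("spectra do not cover the movement band")
    band_idx = np.where(in_band)[0]
    sub = spectra.coherence[np.ix_(chans, band_idx)]
    ci, fi = np.unravel_index(np.argmax(sub), sub.shape)
    ch_f0, idx_f0 = chans[ci], band_idx[fi]
    f0 = float(freqs[idx_f0])

    near = np.where(np.abs(freqs - 2.0 * f0) <= df + 1e-9)[0]
    near = near[(near > 2) & (near + 2 < len(freqs))]
    sub1 = spectra.coherence[np.ix_(chans, near)]
    ci1, fi1 = np.unravel_index(np.argmax(sub1), sub1.shape)
    ch_f1, idx_f1 = chans[ci1], near[fi1]
    f1 = float(freqs[idx_f1])

    return CKCResult(
        f0=f0, f1=f1,
        ckc_f0=float(spectra.coherence[ch_f0, idx_f0]),
        ckc_f1=float(spectra.coherence[ch_f1, idx_f1]),
        electrode_f0=spectra.channel_labels[ch_f0],
        electrode_f1=spectra.channel_labels[ch_f1],
        snr_f0=spectral_snr(spectra.power[ch_f0], freqs, f0),
        snr_f1=spectral_snr(spectra.power[ch_f1], freqs, f1),
        n_epochs=spectra.n_epochs,
        spectra=spectra,
    )


# ---------------------------------------------------------------------------
# Fourier-transform surrogates
# ---------------------------------------------------------------------------

def fourier_surrogate(signal: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Phase-randomized surrogate preserving the amplitude spectrum exactly.

    The rfft phases of all strictly positive, non-Nyquist frequencies are
    replaced by uniform draws in (-pi, pi); the DC and Nyquist coefficients
    are kept, so the output is real with a bin-exact power spectrum.
    """
    x = np.asarray(signal, dtype=float)
    n = x.shape[-1]
    spec = np.fft.rfft(x)
    k = len(spec)
    phases = rng.uniform(-np.pi, np.pi, size=k)
    phases[0] = np.angle(spec[0])
    if n % 2 == 0:
        phases[-1] = np.angle(spec[-1])
    return np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=n)


@dataclass
class SurrogateNull:
    n_surrogates: int
    max_coherence_draws: np.ndarray
    threshold_95: float
    band: tuple[float, float]
    observed_max: float | None = None

    @property
    def significant(self) -> bool | None:
        if self.observed_max is None:
            return None
        return bool(self.observed_max > self.threshold_95)


def _band_dft_matrix(n: int, sample_rate: float, bin_idx: np.ndarray,
                     win: np.ndarray) -> np.ndarray:
    """(n, n_bins) complex matrix computing windowed DFT coefficients at the
    selected rfft bins by matrix product (cheaper than a full FFT when only a
    narrow band is needed)."""
    t = np.arange(n)
    return (win[:, None] * np.exp(-2j * np.pi * t[:, None] * bin_idx[None, :] / n))


def significance_threshold(es: EpochSet, reference_label: str,
                           reference_trials: dict[int, np.ndarray],
                           n_surrogates: int = 1000,
                           band: tuple[float, float] = (1.0, 4.0),
                           seed: int | np.random.SeedSequence | None = None,
                           taper: str = "hann", chunk: int = 50,
                           observed: SpectraSet | None = None) -> SurrogateNull:
    """Max-statistic surrogate threshold for CKC significance.

    For each surrogate, the continuous reference EMG of every trial is
    replaced by its Fourier-transform surrogate, re-epoched at the retained
    epoch positions, and coherence with every considered (non-edge EEG)
    channel is recomputed over ``band``; the draw is the maximum across
    channels and frequencies.  The threshold is the 95th percentile of the
    draws.  The electrode set matches the one used for the observed
    statistic.
    """
    if n_surrogates < 20:
        raise ValueError("need at least 20 surrogates for a stable 95th percentile")
    rng = np.random.default_rng(seed)
    n = es.epochs.shape[2]
    fs = es.sample_rate
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    bin_idx = np.where((freqs >= band[0] - 1e-9) & (freqs <= band[1] + 1e-9))[0]
    if len(bin_idx) == 0:
        raise ValueError("band contains no frequency bins")
    win = _taper(taper, n)
    if observed is None:
        observed = coherence_spectra(es, reference_label, taper=taper)
    chans = _considered_channels(observed)

    # band-restricted EEG epoch spectra (channel, epoch, bin)
    x = (es.epochs[:, chans, :] - es.epochs[:, chans, :].mean(axis=2, keepdims=True))
    fx = np.fft.rfft(x * win, axis=2)[:, :, bin_idx]
    fx = np.transpose(fx, (1, 0, 2))
    pxx = np.mean(np.abs(fx) ** 2, axis=1)

    # Real/imag parts of the windowed band DFT as float32 matrices: the
    # surrogate loop is two real GEMMs per chunk instead of a complex
    # matmul.  Epoch means are not subtracted: the Hann window's leakage is
    # exactly zero beyond +-1 bin, so the DC term cannot reach the band.
    dft = _band_dft_matrix(n, fs, bin_idx, win)
    dft_r = np.ascontiguousarray(dft.real, dtype=np.float32)
    dft_i = np.ascontiguousarray(dft.imag, dtype=np.float32)
    n_ep = es.n_epochs
    trial_ids = np.unique(es.trial_ids)
    trial_amp = {}
    trial_starts = {}
    for t in trial_ids:
        if t not in reference_trials:
            raise KeyError(f"no continuous reference signal supplied for trial {t}")
        ref = np.asarray(reference_trials[t], dtype=float)
        trial_amp[t] = (np.abs(np.fft.rfft(ref)), len(ref))
        trial_starts[t] = es.starts[es.trial_ids == t]

    from numpy.lib.stride_tricks import sliding_window_view

    stride = int(round((es.epoch_length - es.overlap) * fs))
    nb = len(bin_idx)

    def _epoch_band_dft(surr: np.ndarray, starts: np.ndarray) -> np.ndarray:
        """Windowed band DFT of every epoch of every surrogate, (m, ep, bins).

        When the epoch length is a whole number of strides (the usual
        5 s / 1 s case) the DFT is assembled from per-block GEMMs over the
        non-overlapping stride blocks, avoiding any gather of overlapping
        epoch copies; otherwise fall back to slicing.
        """
        m = surr.shape[0]
        if n % stride == 0 and np.all(starts % stride == 0):
            nblk = n // stride
            total = surr.shape[1] // stride
            blocks = np.ascontiguousarray(
                surr[:, :total * stride], dtype=np.float32).reshape(m * total, stride)
            parts = []
            for j in range(nblk):
                dr = np.ascontiguousarray(dft_r[j * stride:(j + 1) * stride])
                di = np.ascontiguousarray(dft_i[j * stride:(j + 1) * stride])
                parts.append((blocks @ dr).astype(np.float64).reshape(m, total, nb)
                             + 1j * (blocks @ di).astype(np.float64).reshape(m, total, nb))
            off = starts // stride
            fy = np.zeros((m, len(starts), nb), dtype=complex)
            for j in range(nblk):
                fy += parts[j][:, off + j, :]
            return fy
        windows = sliding_window_view(surr, n, axis=1)[:, starts, :]
        seg = np.ascontiguousarray(windows, dtype=np.float32).reshape(-1, n)
        return ((seg @ dft_r).astype(np.float64)
                + 1j * (seg @ dft_i).astype(np.float64)).reshape(m, len(starts), nb)

    draws = np.empty(n_surrogates)
    done = 0
    while done < n_surrogates:
        m = min(chunk, n_surrogates - done)
        cross = np.zeros((m, len(chans), nb), dtype=complex)
        pyy = np.zeros((m, nb))
        for t in trial_ids:
            amp, nref = trial_amp[t]
            phases = rng.uniform(-np.pi, np.pi, size=(m, len(amp)))
            phases[:, 0] = 0.0
            if nref % 2 == 0:
                phases[:, -1] = 0.0
            surr = np.fft.irfft(amp[None, :] * np.exp(1j * phases), n=nref, axis=1)
            fy = _epoch_band_dft(surr, trial_starts[t])
            mask = es.trial_ids == t
            cross += np.einsum("ceb,meb->mcb", np.conj(fx[:, mask, :]), fy)
            pyy += np.sum(np.abs(fy) ** 2, axis=1)
        coh = np.abs(cross / n_ep) ** 2 / (pxx[None] * (pyy / n_ep)[:, None, :])
        draws[done:done + m] = coh.reshape(m, -1).max(axis=1)
        done += m

    obs_band = observed.coherence[np.ix_(chans, bin_idx)]
    return SurrogateNull(
        n_surrogates=n_surrogates, max_coherence_draws=draws,
        # 'higher' rounds up to the next order statistic, giving
        # P(observed > threshold) = k/(N+1) <= 0.05 under exchangeability
        # (k = 10 at N = 200, k = 50 at N = 1000); linear interpolation
        # between order statistics is slightly anti-conservative.
        threshold_95=float(np.percentile(draws, 95, method="higher")), band=band,
        observed_max=float(obs_band.max()),
    )


# ---------------------------------------------------------------------------
# End-to-end per-subject analysis
# ---------------------------------------------------------------------------

def ckc_analysis(trials: list[Recording], reference_label: str = "EMG_FDI",
                 epoch_length: float = 5.0, overlap: float = 4.0,
                 reject_sd: float = 5.0,
                 movement_band: tuple[float, float] = (0.8, 2.0),
                 rate_anchored: bool = True,
                 n_surrogates: int = 1000,
                 surrogate_band: tuple[float, float] = (1.0, 4.0),
                 seed: int | np.random.SeedSequence | None = None,
                 taper: str = "hann") -> CKCResult:
    """Full CKC readout for one subject from preprocessed trials.

    Epochs each trial, rejects extreme-amplitude epochs, pools across
    trials, computes coherence with the rectified reference EMG, picks F0/F1
    peaks with their SNR, and (when ``n_surrogates > 0``) attaches the
    surrogate significance threshold.

    With ``rate_anchored`` (the default) the movement frequency is first
    read from the reference EMG power spectrum within ``movement_band``,
    and the F0 coherence search is restricted to one frequency bin around
    it.  This prevents the first harmonic of a slow movement rate (which
    typically carries the stronger coherence) from leaking into the top of
    the movement band and being mistaken for F0.  With
    ``rate_anchored=False`` the F0 search spans the whole band.
    """
    sets = [make_epochs(rec, epoch_length, overlap, trial_id=t)
            for t, rec in enumerate(trials)]
    pooled = reject_epochs(pool_epochs(sets), reject_sd)
    spectra = coherence_spectra(pooled, reference_label, taper=taper)
    pick_band = movement_band
    if rate_anchored:
        f_mov = movement_frequency(spectra, movement_band)
        df = float(spectra.frequencies[1] - spectra.frequencies[0])
        pick_band = (f_mov - df, f_mov + df)
    result = pick_peaks(spectra, pick_band)
    if n_surrogates > 0:
        refs = {t: rec.channel(reference_label) for t, rec in enumerate(trials)}
        null = significance_threshold(
            pooled, reference_label, refs, n_surrogates=n_surrogates,
            band=surrogate_band, seed=seed, taper=taper, observed=spectra)
        result.surrogate_null = null
        result.significance_threshold = null.threshold_95
        result.significant_f0 = bool(result.ckc_f0 > null.threshold_95)
        result.significant_f1 = bool(result.ckc_f1 > null.threshold_95)
    return result
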