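"""Synthetic EEG/EMG cohorts with known ground truth.

The generator emulates the statistical structure of a rhythmic block-transfer
task recorded with 64-channel EEG and three bipolar EMG channels (first
dorsal interosseous, biceps, deltoid) at 1,000 Hz:

* movement cycles at 1-1.5 Hz with cycle-to-cycle duration jitter,
* one EMG burst per muscle per cycle (the deltoid optionally biphasic),
  riding on a 20-295 Hz band-limited noise carrier, with a slow
  multiplicative amplitude drift across cycles,
* EEG = 1/f background noise plus movement-locked oscillations at the cycle
  rate (F0) and its first harmonic (F1), phase-continuous through the
  jittered cycles and projected onto a fixed left-central scalp weighting
  peaking near C3,
* behavioural scores statistically tied to the per-subject coupling gain
  through a Gaussian copula, so that cohort-level analyses have a known
  ground truth.

Everything is reproducible from ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .layout import CHANNELS_64, standard_layout
from .preprocess import FilterSpec, filter_zero_lag
from .recording import Recording

EMG_LABELS = ("EMG_FDI", "EMG_biceps", "EMG_deltoid")


@dataclass(frozen=True)
class SubjectSimConfig:
    """Parameters of a single synthetic subject.

    Movement rate is the target F0 in Hz; ``rate_jitter_sd`` (seconds) is the
    SD of cycle-duration jitter.  ``coupling_gain_f0``/``coupling_gain_f1``
    set the amplitude of the movement-locked EEG components in units of the
    (unit-variance) background-noise SD at the peak-weight electrode.
    ``shared_burst_fraction`` is the fraction of burst-timing variance shared
    across the three muscles (1 = perfectly coordinated burst timing).
    ``amplitude_drift_sd`` is the SD of the log of the slow multiplicative
    EMG gain.
    """

    movement_rate: float = 1.2
    rate_jitter_sd: float = 0.03
    coupling_gain_f0: float = 0.05
    coupling_gain_f1: float = 0.07
    muscle_phase_offsets: tuple[float, float, float] = (0.05, 0.15, 0.30)
    shared_burst_fraction: float = 0.7
    amplitude_drift_sd: float = 0.2
    eeg_noise_exponent: float = 1.0
    duration: float = 60.0
    sample_rate: float = 1000.0
    seed: int = 0
    # secondary knobs
    n_trials: int = 3
    n_channels: int = 64
    burst_jitter_sd: float = 0.04
    burst_width: float = 0.07
    deltoid_biphasic: bool = True
    emg_baseline: float = 0.10
    emg_band: tuple[float, float] = (20.0, 295.0)
    f1_phase: float = 0.8
    spatial_mixing_sigma: float = 0.5
    heartbeat: bool = False
    heartbeat_rate: float = 1.1
    eeg_noise_scale: float = 1.0

    def validate(self) -> None:
        if self.sample_rate <= 2 * self.emg_band[1]:
            raise ValueError("sample_rate must exceed twice the EMG band upper edge")
        if self.duration * self.movement_rate < 10:
            raise ValueError("duration must cover at least 10 movement cycles")
        if self.rate_jitter_sd < 0:
            raise ValueError("rate_jitter_sd must be non-negative")
        if self.coupling_gain_f0 < 0 or self.coupling_gain_f1 < 0:
            raise ValueError("coupling gains must be non-negative")
        if not 0.0 <= self.shared_burst_fraction <= 1.0:
            raise ValueError("shared_burst_fraction must lie in [0, 1]")
        if self.amplitude_drift_sd < 0:
            raise ValueError("amplitude_drift_sd must be non-negative")
        if not 3 <= self.n_channels <= 64:
            raise ValueError("n_channels must be between 3 and 64")


def channel_subset(n: int) -> list[str]:
    """An ``n``-channel subset of the 64-channel montage, always containing C3.

    Used for scaled-down simulations; evenly spaced across the cap so the
    subset still has interior and edge electrodes.
    """
    if n >= 64:
        return list(CHANNELS_64)
    idx = sorted(set(np.round(np.linspace(0, 63, n)).astype(int)))
    labels = [CHANNELS_64[i] for i in idx]
    if "C3" not in labels:
        labels[min(range(len(labels)), key=lambda j: abs(idx[j] - CHANNELS_64.index("C3")))] = "C3"
    return labels


# ---------------------------------------------------------------------------
# Movement rhythm
# ---------------------------------------------------------------------------

def generate_cycles(config: SubjectSimConfig,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Cycle onset times (s) over one trial.

    Inter-onset intervals are ``1/movement_rate`` plus Gaussian jitter of SD
    ``rate_jitter_sd`` (clipped to at least 30% of the nominal interval so
    onsets stay strictly increasing).  Degenerate durations (shorter than one
    cycle) yield an empty or single-onset array without error.
    """
    if config.rate_jitter_sd < 0:
        raise ValueError("rate_jitter_sd must be non-negative")
    if config.movement_rate <= 0 or config.duration < 0:
        raise ValueError("movement_rate and duration must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    nominal = 1.0 / config.movement_rate
    onsets = [0.0]
    while onsets[-1] < config.duration:
        step = nominal + (rng.normal(0.0, config.rate_jitter_sd)
                          if config.rate_jitter_sd > 0 else 0.0)
        onsets.append(onsets[-1] + max(step, 0.3 * nominal))
    return np.array([t for t in onsets if t < config.duration])


def _cycle_index(onsets: np.ndarray, t: np.ndarray, nominal: float) -> np.ndarray:
    """Continuous cycle index k(t): k at onset k, linear in between.

    Extrapolated at the nominal rate past the last onset so the rhythm never
    freezes at the end of a trial.
    """
    knots_t = np.concatenate([onsets, [onsets[-1] + nominal, onsets[-1] + 2 * nominal + t[-1]]])
    knots_k = np.arange(len(knots_t), dtype=float)
    knots_k[-1] = knots_k[-2] + (knots_t[-1] - knots_t[-2]) / nominal
    return np.interp(t, knots_t, knots_k)


# ---------------------------------------------------------------------------
# EMG
# ---------------------------------------------------------------------------

def generate_emg(config: SubjectSimConfig, cycles: np.ndarray,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Three-channel raw EMG for one trial, shape ``(3, n_samples)``.

    Each muscle fires one Gaussian burst per movement cycle at its phase
    offset; burst timing jitters with a variance split
    ``shared_burst_fraction`` : ``1 - shared_burst_fraction`` between a
    cycle-wise component common to all muscles and muscle-specific
    components.  The burst envelope multiplies a 20-295 Hz band-limited
    noise carrier and a slow multiplicative amplitude drift.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fs = config.sample_rate
    n = int(round(config.duration * fs))
    t = np.arange(n) / fs
    nominal = 1.0 / config.movement_rate
    intervals = np.diff(np.concatenate([cycles, [cycles[-1] + nominal]]))
    k_cycles = len(cycles)

    shared = rng.standard_normal(k_cycles)
    own = rng.standard_normal((3, k_cycles))
    f = config.shared_burst_fraction
    timing = config.burst_jitter_sd * (np.sqrt(f) * shared[None, :]
                                       + np.sqrt(1.0 - f) * own)

    w = config.burst_width
    half = int(round(4 * w * fs))
    out = np.empty((3, n))
    for m in range(3):
        env = np.zeros(n)
        centers = cycles + config.muscle_phase_offsets[m] * intervals + timing[m]
        bursts = [(centers, 1.0)]
        if m == 2 and config.deltoid_biphasic:
            bursts.append((centers + 0.35 * intervals, 0.7))
        for cs, amp in bursts:
            for c in cs:
                i0 = max(0, int(round((c - 4 * w) * fs)))
                i1 = min(n, i0 + 2 * half + 1)
                if i1 <= i0:
                    continue
                tt = t[i0:i1] - c
                env[i0:i1] += amp * np.exp(-0.5 * (tt / w) ** 2)

        if config.amplitude_drift_sd > 0:
            # slow log-gain: white noise smoothed to ~0.1 Hz in the spectral
            # domain (Gaussian transfer, sigma_t = 2 s), rescaled to the
            # requested SD
            raw = rng.standard_normal(n)
            fr = np.fft.rfft(raw)
            fgrid = np.fft.rfftfreq(n, d=1.0 / fs)
            slow = np.fft.irfft(fr * np.exp(-2.0 * np.pi ** 2 * (2.0 * fgrid) ** 2),
                                n=n)
            sd = slow.std()
            slow = slow / sd * config.amplitude_drift_sd if sd > 0 else slow * 0.0
            gain = np.exp(slow)
        else:
            rng.standard_normal(n)  # keep the stream aligned across configs
            gain = 1.0

        carrier = rng.standard_normal(n)
        carrier = filter_zero_lag(carrier, fs, FilterSpec(band=config.emg_band))
        carrier /= max(carrier.std(), 1e-12)
        out[m] = (config.emg_baseline + env) * gain * carrier
    return out


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def _one_over_f_noise(rng: np.random.Generator, n_ch: int, n: int,
                      fs: float, exponent: float) -> np.ndarray:
    """Unit-variance noise with a 1/f**exponent power spectrum (per channel)."""
    white = rng.standard_normal((n_ch, n))
    if exponent == 0:
        return white
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    shape[0] = shape[1]
    x = np.fft.irfft(spec * shape, n=n, axis=1)
    return x / x.std(axis=1, keepdims=True)


def scalp_weights(labels: list[str], center: str = "C3", sigma: float = 0.45) -> np.ndarray:
    """Fixed synthetic scalp projection: Gaussian in 2-D layout distance from
    a C3-like focus, normalized to peak 1.  No head model is involved; the
    analysis is sensor-level throughout."""
    pos, _ = standard_layout(labels)
    cpos, _ = standard_layout([center])
    d = np.linalg.norm(pos - cpos[0], axis=1)
    w = np.exp(-0.5 * (d / sigma) ** 2)
    w[~np.isfinite(w)] = 0.0
    return w / w.max()


def generate_eeg(config: SubjectSimConfig, cycles: np.ndarray,
                 rng: np.random.Generator | None = None,
                 labels: list[str] | None = None) -> tuple[np.ndarray, dict]:
    """EEG for one trial: ``(samples, ground_truth)``.

    ``samples`` has shape ``(n_channels, n_samples)``.  The movement-locked
    components are phase-continuous oscillations that follow the
    instantaneous cycle rate (so rate jitter smears coherence realistically
    rather than producing a fixed spectral line).  ``ground_truth`` records
    the scalp weights, the F0/F1 rhythm waveforms and the electrode labels
    that carry the coupling (weight >= 0.5).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    labels = labels or channel_subset(config.n_channels)
    fs = config.sample_rate
    n = int(round(config.duration * fs))
    t = np.arange(n) / fs

    k = _cycle_index(cycles, t, 1.0 / config.movement_rate)
    rhythm_f0 = np.cos(2 * np.pi * k)
    rhythm_f1 = np.cos(4 * np.pi * k + config.f1_phase)

    noise = _one_over_f_noise(rng, len(labels), n, fs, config.eeg_noise_exponent)
    if config.spatial_mixing_sigma > 0:
        # volume-conduction-like spatial blur: neighbouring electrodes see
        # strongly correlated background activity, as real EEG does
        pos, _ = standard_layout(labels)
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
        mix = np.exp(-0.5 * (d / config.spatial_mixing_sigma) ** 2)
        mix[~np.isfinite(mix)] = 0.0
        noise = mix @ noise
        noise /= noise.std(axis=1, keepdims=True)
    noise *= config.eeg_noise_scale
    w = scalp_weights(labels)
    eeg = noise + np.outer(w, config.coupling_gain_f0 * rhythm_f0
                           + config.coupling_gain_f1 * rhythm_f1)

    if config.heartbeat:
        beat_times = np.arange(0.3, config.duration, 1.0 / config.heartbeat_rate)
        artifact = np.zeros(n)
        for bt in beat_times:
            i0 = int(bt * fs)
            i1 = min(n, i0 + int(0.05 * fs))
            artifact[i0:i1] += np.hanning(i1 - i0)
        eeg += 0.5 * artifact[None, :]

    truth = {
        "weights": w,
        "labels": list(labels),
        "coupled_channels": [lab for lab, wi in zip(labels, w) if wi >= 0.5],
        "rhythm_f0": rhythm_f0,
        "rhythm_f1": rhythm_f1,
        "noise_sd": config.eeg_noise_scale,
    }
    return eeg, truth


# ---------------------------------------------------------------------------
# Whole subject
# ---------------------------------------------------------------------------

@dataclass
class SubjectData:
    """Simulated subject: one Recording per trial plus generation ground truth."""

    trials: list[Recording]
    ground_truth: dict
    config: SubjectSimConfig


def generate_subject(config: SubjectSimConfig) -> SubjectData:
    """Simulate all trials of one subject (EEG + EMG in one Recording each)."""
    config.validate()
    labels = channel_subset(config.n_channels)
    pos, edge = standard_layout(labels)
    all_labels = labels + list(EMG_LABELS)
    roles = ["EEG"] * len(labels) + ["EMG"] * 3
    full_pos = np.vstack([pos, np.full((3, 2), np.nan)])
    full_edge = np.concatenate([edge, np.ones(3, dtype=bool)])

    ss = np.random.SeedSequence(config.seed)
    trial_seeds = ss.spawn(config.n_trials)
    trials, truth_trials = [], []
    for tr, seed in enumerate(trial_seeds):
        r_cyc, r_emg, r_eeg = (np.random.default_rng(s) for s in seed.spawn(3))
        cycles = generate_cycles(config, r_cyc)
        emg = generate_emg(config, cycles, r_emg)
        eeg, truth = generate_eeg(config, cycles, r_eeg, labels)
        truth["cycles"] = cycles
        truth_trials.append(truth)
        trials.append(Recording(
            samples=np.vstack([eeg, emg]),
            sample_rate=config.sample_rate,
            channel_labels=all_labels,
            channel_roles=roles,
            layout=full_pos,
            edge_flags=full_edge,
            meta={"trial": tr, "seed": int(config.seed)},
        ))
    ground_truth = {
        "gain_f0": config.coupling_gain_f0,
        "gain_f1": config.coupling_gain_f1,
        "movement_rate": config.movement_rate,
        "weights": truth_trials[0]["weights"],
        "coupled_channels": truth_trials[0]["coupled_channels"],
        "trials": truth_trials,
    }
    return SubjectData(trials=trials, ground_truth=ground_truth, config=config)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSimConfig:
    """Cohort-level simulation parameters.

    A standard-normal latent ``u`` per subject drives the F1 coupling gain
    (log-normally) and, through a Gaussian copula, the gross-motor score
    ``score1`` with rank correlation ``target_spearman_ckc_score1``.  The
    fine-motor score ``score2`` correlates with ``score1`` only through the
    part of ``score1`` unrelated to coupling (by default), reproducing a
    cohort where score2 carries no direct information about coupling.
    Score scales default to published healthy-adult norms for the two tests
    (76.2 +/- 7.6 blocks, 15.7 +/- 1.7 pegs).
    """

    n_subjects: int = 61
    target_spearman_ckc_score1: float = 0.5
    score2_corr_score1: float = 0.39
    score2_corr_gain: float = 0.0
    gain_f1_base: float = 0.07
    gain_f0_ratio: float = 0.7
    gain_sigma: float = 0.6
    score1_mean: float = 76.2
    score1_sd: float = 7.6
    score2_mean: float = 15.7
    score2_sd: float = 1.7
    rate_range: tuple[float, float] = (1.0, 1.5)
    subject_template: SubjectSimConfig = field(default_factory=SubjectSimConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("a cohort needs at least 3 subjects")
        for r in (self.target_spearman_ckc_score1, self.score2_corr_score1,
                  self.score2_corr_gain):
            if not -1.0 <= r <= 1.0:
                raise ValueError("target correlations must lie in [-1, 1]")


@dataclass
class Cohort:
    """Scores table plus the per-subject configs needed to regenerate data."""

    scores: pd.DataFrame
    subject_configs: list[SubjectSimConfig]
    config: CohortSimConfig

    def iter_subjects(self):
        for cfg in self.subject_configs:
            yield generate_subject(cfg)


def generate_cohort(config: CohortSimConfig) -> Cohort:
    """Draw a cohort: behavioural scores and per-subject simulation configs.

    The rank correlation between the true F1 coupling gain and ``score1``
    equals the target in population; the recovered correlation after running
    the pipeline is attenuated by CKC estimation noise.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_subjects

    u = rng.standard_normal(n)          # latent coupling propensity
    e1 = rng.standard_normal(n)
    e2 = rng.standard_normal(n)
    eta = rng.standard_normal(n)

    # bivariate-normal Pearson correlation matching the target Spearman
    rho_p = 2.0 * np.sin(np.pi * config.target_spearman_ckc_score1 / 6.0)
    z1 = rho_p * u + np.sqrt(max(0.0, 1.0 - rho_p ** 2)) * e1

    a = config.score2_corr_gain
    rest = np.sqrt(max(1e-12, 1.0 - rho_p ** 2))
    b = (config.score2_corr_score1 - a * rho_p) / rest
    c2 = 1.0 - a * a - b * b
    if c2 < 0:
        raise ValueError("score2 correlation targets are jointly infeasible")
    z2 = a * u + b * e1 + np.sqrt(c2) * e2

    gain_f1 = config.gain_f1_base * np.exp(config.gain_sigma * u)
    gain_f0 = config.gain_f0_ratio * gain_f1 * np.exp(0.3 * eta)
    rates = rng.uniform(*config.rate_range, size=n)
    subject_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                     for s in np.random.SeedSequence(config.seed).spawn(n)]

    subject_configs = [
        replace(config.subject_template,
                movement_rate=float(rates[i]),
                coupling_gain_f0=float(gain_f0[i]),
                coupling_gain_f1=float(gain_f1[i]),
                seed=subject_seeds[i])
        for i in range(n)
    ]
    scores = pd.DataFrame({
        "subject_id": [f"S{i:03d}" for i in range(n)],
        "score1": config.score1_mean + config.score1_sd * z1,
        "score2": config.score2_mean + config.score2_sd * z2,
        "true_gain_f0": gain_f0,
        "true_gain_f1": gain_f1,
        "movement_rate": rates,
        "seed": subject_seeds,
    })
    return Cohort(scores=scores, subject_configs=subject_configs, config=config)
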