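"""EMG-derived features: recruitment traces, coordination, regularity,
modulation depth.

The muscle *recruitment trace* is the ratio of a fast (3 Hz low-pass) to a
slow (0.7 Hz low-pass) Gaussian envelope of the rectified EMG.  It keeps the
within-cycle activation rhythm while cancelling slow amplitude
non-stationarity, which makes every downstream feature invariant to slowly
varying positive gains on the raw EMG.

Coordination between muscle pairs is quantified four ways: maximum lagged
Pearson cross-correlation, and three mutual-information variants (on the
traces quantized into equally populated bins, on their Hilbert phases, and
on ordinal permutation patterns).  Regularity is the magnitude of the first
negative and positive side peaks of the trace autocorrelation; modulation
depth is the coefficient of variation of the trace, averaged over muscles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import hilbert

#: Default fast / slow envelope cutoffs (Hz), chosen to bracket 1-1.5 Hz
#: movement rates.
FAST_CUTOFF = 3.0
SLOW_CUTOFF = 0.7


@dataclass
class EnvelopePair:
    fast: np.ndarray
    slow: np.ndarray
    cutoffs: tuple[float, float] = (FAST_CUTOFF, SLOW_CUTOFF)


@dataclass
class RecruitmentTrace:
    values: np.ndarray
    muscle: str
    sample_rate: float


@dataclass
class CoordinationResult:
    """Per-subject coordination scalars (averaged over the three muscle pairs)."""

    xcorr_max_per_pair: np.ndarray
    mi_binned_per_pair: np.ndarray
    mi_phase_per_pair: np.ndarray
    mi_permutation_per_pair: np.ndarray

    @property
    def xcorr_mean(self) -> float:
        return float(np.mean(self.xcorr_max_per_pair))

    @property
    def mi_binned_mean(self) -> float:
        return float(np.mean(self.mi_binned_per_pair))

    @property
    def mi_phase_mean(self) -> float:
        return float(np.mean(self.mi_phase_per_pair))

    @property
    def mi_permutation_mean(self) -> float:
        return float(np.mean(self.mi_permutation_per_pair))


@dataclass
class RegularityResult:
    neg_side_peak: float
    pos_side_peak: float


@dataclass
class ModulationDepth:
    cv_per_muscle: np.ndarray

    @property
    def mean_cv(self) -> float:
        return float(np.mean(self.cv_per_muscle))


# ---------------------------------------------------------------------------
# Envelopes and recruitment trace
# ---------------------------------------------------------------------------

def gaussian_kernel_sigma(cutoff: float, sample_rate: float) -> float:
    """Kernel SD (in samples) of a Gaussian smoother whose frequency response
    is 0.5 at ``cutoff`` (half-amplitude convention).

    A unit-area Gaussian of SD ``s`` seconds has |H(f)| = exp(-2 pi^2 s^2 f^2),
    so |H(fc)| = 0.5 gives s = sqrt(ln 2 / 2) / (pi fc).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    s_seconds = math.sqrt(math.log(2.0) / 2.0) / (math.pi * cutoff)
    return s_seconds * sample_rate


def gaussian_envelope(rectified_emg: np.ndarray, cutoff: float,
                      sample_rate: float) -> np.ndarray:
    """Smooth a rectified EMG with the unit-DC-gain Gaussian low-pass kernel.

    Output length equals input length (reflection padding at the edges).
    """
    x = np.asarray(rectified_emg, dtype=float)
    if cutoff >= sample_rate / 2:
        raise ValueError("cutoff must be below Nyquist")
    sigma = gaussian_kernel_sigma(cutoff, sample_rate)
    return gaussian_filter1d(x, sigma=sigma, mode="reflect")


def envelopes(rectified_emg: np.ndarray, sample_rate: float,
              fast_cutoff: float = FAST_CUTOFF,
              slow_cutoff: float = SLOW_CUTOFF) -> EnvelopePair:
    return EnvelopePair(
        fast=gaussian_envelope(rectified_emg, fast_cutoff, sample_rate),
        slow=gaussian_envelope(rectified_emg, slow_cutoff, sample_rate),
        cutoffs=(fast_cutoff, slow_cutoff),
    )


def recruitment_trace(rectified_emg: np.ndarray, sample_rate: float,
                      muscle: str = "", fast_cutoff: float = FAST_CUTOFF,
                      slow_cutoff: float = SLOW_CUTOFF) -> RecruitmentTrace:
    """Fast/slow envelope ratio of a rectified EMG.

    The slow envelope is floored at 1e-12 of its maximum to avoid division
    blow-ups; an all-zero input is rejected because the ratio is undefined.
    """
    x = np.asarray(rectified_emg, dtype=float)
    if np.all(x == 0):
        raise ValueError("recruitment trace undefined for an all-zero EMG")
    if np.any(x < 0):
        raise ValueError("input must be rectified (non-negative)")
    pair = envelopes(x, sample_rate, fast_cutoff, slow_cutoff)
    floor = 1e-12 * float(np.max(pair.slow))
    values = pair.fast / np.maximum(pair.slow, floor)
    return RecruitmentTrace(values=values, muscle=muscle, sample_rate=sample_rate)


# ---------------------------------------------------------------------------
# Lagged Pearson correlation machinery
# ---------------------------------------------------------------------------

def lag_grid_samples(sample_rate: float, max_lag: float = 2.0,
                     step: float = 0.02) -> np.ndarray:
    """Lag grid in samples: -max_lag..max_lag seconds by ``step`` seconds."""
    n_steps = int(round(max_lag / step))
    return np.round(np.arange(-n_steps, n_steps + 1) * step * sample_rate).astype(int)


def lagged_pearson(x: np.ndarray, y: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Pearson correlation of ``x[t]`` with ``y[t - lag]`` at each lag
    (overlapping segments only)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant trace")
    n = len(x)
    out = np.empty(len(lags))
    for i, lag in enumerate(lags):
        if abs(lag) >= n:
            out[i] = np.nan
            continue
        a = x[lag:] if lag >= 0 else x[:n + lag]
        b = y[:n - lag] if lag >= 0 else y[-lag:]
        sa, sb = a.std(), b.std()
        out[i] = np.nan if sa == 0 or sb == 0 else \
            float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
    return out


def xcorr_coordination(traces: list[RecruitmentTrace], max_lag: float = 2.0,
                       step: float = 0.02) -> tuple[np.ndarray, float]:
    """Max |lagged Pearson r| per muscle pair, and the across-pair average."""
    if len(traces) < 2:
        raise ValueError("need at least two traces")
    fs = traces[0].sample_rate
    n = len(traces[0].values)
    if n / fs <= 2 * max_lag:
        raise ValueError("traces must be longer than the full lag window")
    lags = lag_grid_samples(fs, max_lag, step)
    pairs = [(i, j) for i in range(len(traces)) for j in range(i + 1, len(traces))]
    maxima = np.array([
        float(np.nanmax(np.abs(lagged_pearson(traces[i].values, traces[j].values, lags))))
        for i, j in pairs
    ])
    return maxima, float(np.mean(maxima))


# ---------------------------------------------------------------------------
# Mutual information estimators
# ---------------------------------------------------------------------------

def equal_population_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantize into ``n_bins`` equally populated bins.

    Ties are broken by original temporal order (stable rank), which makes the
    quantization deterministic and gives exactly equal bin counts whenever
    ``len(x)`` is a multiple of ``n_bins``.
    """
    x = np.asarray(x)
    n = len(x)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return (ranks * n_bins) // n


def _discrete_mi(sx: np.ndarray, sy: np.ndarray, kx: int, ky: int) -> float:
    """Plug-in mutual information (bits) between two integer symbol streams."""
    joint = np.bincount(sx * ky + sy, minlength=kx * ky).astype(float)
    joint /= joint.sum()
    px = joint.reshape(kx, ky).sum(axis=1)
    py = joint.reshape(kx, ky).sum(axis=0)
    nz = joint > 0
    outer = np.outer(px, py).ravel()
    return float(np.sum(joint[nz] * np.log2(joint[nz] / outer[nz])))


def binned_mi(x: np.ndarray, y: np.ndarray, n_bins: int = 10) -> float:
    """Mutual information (bits) after equal-population quantization.

    With ``y = x`` and ``n`` a multiple of ``n_bins`` this equals
    ``log2(n_bins)`` exactly (the marginal entropy of the quantized series).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    if len(x) < 10 * n_bins:
        raise ValueError(f"need at least {10 * n_bins} samples for {n_bins} bins")
    for name, s in (("x", x), ("y", y)):
        if len(np.unique(s)) < n_bins:
            raise ValueError(f"{name} has fewer distinct values than bins")
    return _discrete_mi(equal_population_bins(x, n_bins),
                        equal_population_bins(y, n_bins), n_bins, n_bins)


def phase_mi(x: np.ndarray, y: np.ndarray, n_bins: int = 10) -> float:
    """Binned MI between the instantaneous Hilbert phases of two traces."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    px = np.angle(hilbert(x - x.mean()))
    py = np.angle(hilbert(y - y.mean()))
    return binned_mi(px, py, n_bins)


def _ordinal_symbols(x: np.ndarray, order: int, delay: int) -> np.ndarray:
    """Ordinal-pattern symbol stream: each time point maps to the permutation
    sorting ``x[t], x[t+d], ..., x[t+(order-1)d]`` (ties by temporal index)."""
    n = len(x)
    m = n - (order - 1) * delay
    if m <= 0:
        raise ValueError("series shorter than the ordinal-pattern support")
    emb = np.stack([x[i * delay:i * delay + m] for i in range(order)], axis=1)
    perm = np.argsort(emb, axis=1, kind="stable")
    ranks = np.argsort(perm, axis=1, kind="stable")
    codes = np.zeros(m, dtype=np.int64)
    for j in range(order):
        codes = codes * order + ranks[:, j]
    return codes


def permutation_mi(x: np.ndarray, y: np.ndarray, order: int = 4,
                   delay_s: float = 0.1, sample_rate: float = 1000.0) -> float:
    """Permutation mutual information (bits).

    Each series is mapped to a stream of ordinal patterns over ``order``
    points spaced ``delay_s`` seconds apart; the plug-in MI between the two
    symbol streams measures whether activation orderings in one muscle
    predict orderings in the other.  Exactly invariant to strictly monotone
    transforms of either input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    delay = max(1, int(round(delay_s * sample_rate)))
    sx = _ordinal_symbols(x, order, delay)
    sy = _ordinal_symbols(y, order, delay)
    k = order ** order  # dense code space (only order! codes occur)
    if len(np.unique(sx)) == 1 or len(np.unique(sy)) == 1:
        warnings.warn("constant ordinal-pattern stream; MI is 0")
        return 0.0
    return _discrete_mi(sx, sy, k, k)


def coordination(traces: list[RecruitmentTrace], max_lag: float = 2.0,
                 step: float = 0.02, n_bins: int = 10, order: int = 4,
                 delay_s: float = 0.1) -> CoordinationResult:
    """All four coordination measures over every muscle pair."""
    pairs = [(i, j) for i in range(len(traces)) for j in range(i + 1, len(traces))]
    xc, _ = xcorr_coordination(traces, max_lag, step)
    fs = traces[0].sample_rate
    mb, mp, mo = [], [], []
    for i, j in pairs:
        a, b = traces[i].values, traces[j].values
        mb.append(binned_mi(a, b, n_bins))
        mp.append(phase_mi(a, b, n_bins))
        mo.append(permutation_mi(a, b, order, delay_s, fs))
    return CoordinationResult(
        xcorr_max_per_pair=xc,
        mi_binned_per_pair=np.array(mb),
        mi_phase_per_pair=np.array(mp),
        mi_permutation_per_pair=np.array(mo),
    )


# ---------------------------------------------------------------------------
# Regularity and modulation depth
# ---------------------------------------------------------------------------

def regularity(trace: RecruitmentTrace, max_lag: float = 2.0,
               step: float = 0.02, smooth_steps: int = 5) -> RegularityResult:
    """First negative and positive autocorrelation side-peak magnitudes.

    The autocorrelation over the +-2 s lag grid is smoothed with a short
    moving average for peak *location* only (so broadband noise does not
    spawn spurious extrema); magnitudes are read from the unsmoothed
    autocorrelation at the located lags.
    """
    fs = trace.sample_rate
    lags = lag_grid_samples(fs, max_lag, step)
    ac = lagged_pearson(trace.values, trace.values, lags)
    pos = ac[lags > 0]
    if smooth_steps > 1:
        h = smooth_steps // 2
        padded = np.concatenate([pos[:h][::-1], pos, pos[-h:][::-1]])
        smoothed = np.convolve(padded, np.ones(smooth_steps) / smooth_steps,
                               mode="valid")
    else:
        smoothed = pos

    def _is_extremum(arr, i, half, minimum):
        lo, hi = max(0, i - half), min(len(arr), i + half + 1)
        seg = arr[lo:hi]
        return arr[i] == (seg.min() if minimum else seg.max())

    half = 3
    first_min = None
    for i in range(1, len(smoothed) - 1):
        if _is_extremum(smoothed, i, half, minimum=True) and smoothed[i] < 0:
            first_min = i
            break
    if first_min is None:
        raise ValueError("no negative autocorrelation side peak within the lag "
                         "window (movement slower than 0.5 Hz or no rhythm)")
    first_max = None
    for i in range(first_min + 1, len(smoothed) - 1):
        if _is_extremum(smoothed, i, half, minimum=False) and smoothed[i] > smoothed[first_min]:
            first_max = i
            break
    if first_max is None:
        raise ValueError("no positive autocorrelation side peak after the "
                         "first minimum within the lag window")
    return RegularityResult(neg_side_peak=float(abs(pos[first_min])),
                            pos_side_peak=float(abs(pos[first_max])))


def modulation_depth(traces: list[RecruitmentTrace]) -> ModulationDepth:
    """Coefficient of variation (SD/mean) per recruitment trace."""
    cvs = []
    for tr in traces:
        m = float(np.mean(tr.values))
        if m <= 0:
            raise ValueError("recruitment trace mean must be positive")
        cvs.append(float(np.std(tr.values)) / m)
    return ModulationDepth(cv_per_muscle=np.array(cvs))


# ---------------------------------------------------------------------------
# Cohort-level composite
# ---------------------------------------------------------------------------

def combine_standardized(columns: "np.ndarray | list | dict") -> np.ndarray:
    """Average of z-scored columns (classical standard normalization).

    ``columns`` is a (n_subjects, n_measures) array, a list of equal-length
     1-D arrays, or a dict of named columns.  Each column is centred and
    divided by its (ddof=1) SD before averaging; zero-SD columns are
    rejected by name/index.
    """
    if isinstance(columns, dict):
        names = list(columns)
        mat = np.column_stack([np.asarray(columns[k], dtype=float) for k in names])
    else:
        mat = np.column_stack([np.asarray(c, dtype=float) for c in columns]) \
            if isinstance(columns, (list, tuple)) else np.asarray(columns, dtype=float)
        names = [str(i) for i in range(mat.shape[1])]
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValueError("need at least two columns to combine")
    if mat.shape[0] < 3:
        raise ValueError("need at least three subjects")
    sds = mat.std(axis=0, ddof=1)
    for name, sd in zip(names, sds):
        if sd == 0:
            raise ValueError(f"column {name!r} has zero standard deviation")
    z = (mat - mat.mean(axis=0)) / sds
    return z.mean(axis=1)


# ---------------------------------------------------------------------------
# Per-subject feature extraction
# ---------------------------------------------------------------------------

def subject_emg_features(rectified_emg: np.ndarray, sample_rate: float,
                         muscle_labels: tuple[str, ...] = ("FDI", "biceps", "deltoid"),
                         ) -> dict[str, float]:
    """All per-subject EMG scalars from a (3, n) rectified EMG block.

    Returns the four coordination measures (pair-averaged), the two
    regularity side-peak magnitudes (muscle-averaged) and the mean
    coefficient of variation.  Cohort-level composites are formed later by
    z-scoring across subjects.
    """
    traces = [recruitment_trace(rectified_emg[i], sample_rate, muscle=lab)
              for i, lab in enumerate(muscle_labels)]
    coord = coordination(traces)
    regs = [regularity(tr) for tr in traces]
    mod = modulation_depth(traces)
    return {
        "xcorr_coord": coord.xcorr_mean,
        "mi_binned": coord.mi_binned_mean,
        "mi_phase": coord.mi_phase_mean,
        "mi_permutation": coord.mi_permutation_mean,
        "reg_neg_peak": float(np.mean([r.neg_side_peak for r in regs])),
        "reg_pos_peak": float(np.mean([r.pos_side_peak for r in regs])),
        "modulation_depth": mod.mean_cv,
    }
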