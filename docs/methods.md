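# Methods

`ckcpipe` analyses the coupling between cortical activity and peripheral
movement rhythm — corticokinematic coherence (CKC) — in EEG/EMG recordings
of rhythmic manual tasks, and relates it to behavioural motor scores at the
cohort level. This note documents the model assumptions, the tunable
parameters and their defaults, the synthetic-data generator, and the
numerical choices where the design was genuinely open.

## Signal model and analysis chain

A recording holds 64 EEG channels (extended 10-20 layout) and three bipolar
EMG channels (first dorsal interosseous, biceps, anterior deltoid) sampled
at 1,000 Hz during repeated ~1 min trials of a block-transfer-style task
performed at 1–1.5 movement cycles per second.

**Preprocessing.** EEG channels are screened by three robust criteria —
wide-band amplitude, high/low-frequency amplitude ratio (split at 40 Hz),
and best absolute correlation with other channels (computed on 1–40 Hz
band-limited signals) — each expressed as a deviation from the channel
population (robust z via median/MAD; defaults z > 5 for amplitude, z > 3
for the noisiness ratio, best correlation < 0.4). The MAD-derived scale is
floored (log-ratio 1.1 for amplitude, 1.25 for noisiness) so that nearly
homogeneous channel populations do not amplify negligible fluctuations
into spurious flags. Flagged channels are rebuilt as an inverse-distance
average of their k = 4 nearest good neighbours on the 2-D layout
(the interpolation scheme is a package choice; any local smoother
behaves equivalently at these densities). EEG is then re-referenced to the
common average. An optional cleanup hook accepts externally ICA-cleaned
data; no ICA is performed internally.

EMG is band-pass filtered 20–295 Hz with notches at 50 Hz and all
harmonics below the band's upper edge, using a zero-phase FFT-domain mask
(raised-cosine transitions of 1 Hz at the band edges, ±1 Hz notch width —
the mask shape is a package choice; only the filter type and cutoffs are
fixed by the analysis definition), then full-wave rectified.

**EMG features.** The muscle recruitment trace is the ratio of a fast
(3 Hz) to a slow (0.7 Hz) Gaussian-smoothed envelope of the rectified EMG.
The Gaussian kernel uses the half-amplitude convention: |H(f_c)| = 0.5,
i.e. kernel SD = sqrt(ln 2 / 2) / (π f_c) seconds (62.5 ms at 3 Hz). The
cutoff convention was open; half-amplitude is documented here and verified
by test. The trace is invariant to multiplicative gains varying slower
than the slow cutoff, which makes all downstream features insensitive to
electrode-gain drift. The slow envelope is floored at 1e-12 of its maximum.

Per subject we compute: (1) coordination as the maximum absolute lagged
Pearson correlation between recruitment-trace pairs over ±2 s in 20 ms
steps, averaged across the three muscle pairs, plus three
mutual-information variants — MI of the traces quantized into 10 equally
populated bins, MI of their Hilbert phases (same binning), and permutation
MI over order-4 ordinal patterns with 100 ms spacing; (2) regularity as
the absolute magnitudes of the first negative and first subsequent
positive side peaks of the trace autocorrelation on the same lag grid
(peak *locations* found on a 5-point moving average of the autocorrelation
so broadband noise does not spawn spurious extrema; magnitudes read from
the unsmoothed values); (3) modulation depth as the coefficient of
variation of the trace, averaged over muscles. Quantization ties break by
stable (temporal) order; ordinal-pattern ties break by temporal index; the
100 ms delay is rounded to samples. MI is reported in bits. Cohort-level
composites (4 coordination measures; 2 regularity measures) are averages
of across-subject z-scores (ddof = 1).

**Coherence.** Trials are epoched into 5 s windows with 4 s overlap
(0.2 Hz resolution); epochs never straddle trial boundaries. An epoch is
rejected when any EEG sample deviates more than 5 SDs from its channel
mean, both computed over the full trial before epoching (the absolute
deviation is used; with clean Gaussian data this trims roughly 4% of
epochs). Welch-averaged power and cross spectra between each EEG channel
and the rectified FDI EMG give magnitude-squared coherence. Each epoch is
Hann-tapered (the taper was an open choice; it is config-switchable to
none, and coherence ratios are taper-consistent between observed and
surrogate statistics). F0 is the coherence maximum over non-edge
electrodes within the movement band (default 0.8–2 Hz); F1 is the maximum
within ±1 bin of 2·F0 (the one-bin slack absorbs jitter smearing and
off-grid movement rates). Ties resolve to the lowest channel then lowest
frequency. By default the per-subject analysis first reads the movement
frequency from the reference EMG *power* spectrum — the rectified EMG of
a rhythmic task carries a strong line at the movement rate (its per-cycle
burst envelope) independent of any cortical coupling — and restricts the
F0 coherence search to ±1 bin around it. Without this anchor, the first
harmonic of a ~1 Hz movement rate (which typically carries the stronger
coherence) leaks into the top of the movement band and is mistaken for
F0, which sends the F1 window to ~4 Hz where there is nothing; anchoring
fixes the peak identification while leaving the peak definition (the
coherence maximum within the band) unchanged. The full-band search
remains available (`rate_anchored=False`). Spectral SNR at F0/F1 is the power at the peak divided by the
geometric mean of the power ±2 bins away, on the winning electrode. Edge
electrodes come from a bundled outer-ring list for the 64-channel layout
(23 labels), overridable per recording.

**Significance.** The reference EMG of each trial is replaced by its
Fourier-transform surrogate (phases of all positive, non-Nyquist rfft bins
drawn uniformly in (−π, π); DC and Nyquist kept, so the amplitude spectrum
is preserved bin-exactly), re-epoched at the retained epoch positions, and
the coherence maximum across 1–4 Hz and the non-edge electrodes is
recorded; the significance threshold is the 95th percentile of 1,000 such
maxima. The percentile is taken as the next-higher order statistic (the
k-th largest draw with k/(N+1) ≤ 5%: k = 50 at N = 1,000), for which the
exceedance probability under exchangeability is exactly k/(N+1) — the
standard Monte-Carlo-test convention; interpolating between order
statistics is slightly anti-conservative. The surrogate electrode set
matches the observed statistic's set.
Implementation note: when the epoch length is a whole number of strides
(the standard 5 s/1 s case) the surrogate band DFTs are assembled from
per-block GEMMs over non-overlapping stride blocks in float32 — this is
algebraically the same windowed DFT (verified against direct re-epoching
to ~1e-5 in coherence) and roughly ten times faster.

A caveat verified in development: with a *perfectly periodic* (zero
jitter) rhythm, the reference's spectral line survives phase randomization
as a constant phase offset, which coherence ignores; the surrogate
threshold then approaches the observed coherence and the test becomes
conservative-to-degenerate. With realistic nonzero cycle jitter the
procedure calibrates within the binomial sampling band of the nominal 5%
rate (verified over 200 null runs; controlled variants with a stationary
Gaussian reference, no amplitude drift, or no bursts all land in the same
band, with at most a small anti-conservative tilt from residual reference
non-stationarity).

**Cohort statistics.** Associations use Spearman rank correlation
(average ranks for ties, two-sided t-approximation p). Confound handling:
candidates are screened in a fixed order against the *current* dependent
variable; each significant confound is mean-centred, orthogonalized
against previously removed confounds (Gram–Schmidt), and its least-squares
projection subtracted, so the corrected variable is linearly uncorrelated
(|r| < 1e-10) with every removed confound. The standard orders are:
regularity ← modulation depth; coordination ← modulation depth, corrected
regularity; CKC ← modulation depth, corrected regularity, EEG SNR.

The partial information decomposition of the two motor scores about CKC
uses Gaussian-copula rank normalization (average ranks → uniforms
r/(n+1) → standard normal quantiles) and closed-form Gaussian mutual
informations from the empirical correlation matrix. Redundancy is
minimum mutual information (MMI), the standard closed-form choice for two
(copula-)Gaussian sources; unique and synergistic terms follow from the
lattice identities, which then hold to machine precision and keep all
four components non-negative up to estimation noise in the synergy term.
Exactly duplicated sources are handled by the lattice-forced limit
(joint MI = max of the marginals; everything redundant). Information is
natural-log internally and reported in bits. Significance permutes the
two score columns jointly across subjects (preserving their mutual
structure under the null of no score–CKC association), with
z = (observed − mean)/SD and one-sided p = (1 + #{perm ≥ obs})/(n + 1)
over 1,000 permutations; PID p-values are one-sided because the components
are non-negative effects, while Spearman p-values are two-sided.

The headline battery also reports the contrast z(CKC at F1) − z(gross
score) against the fine score, and a Wilcoxon signed-rank comparison of
CKC at F0 vs F1. No multiple-testing correction is applied across the
battery.

## Synthetic-data generator

The generator is first-class, tested code; it emulates the statistical
assumptions of the task, not its biophysics.

* **Cycles**: onsets with inter-onset intervals 1/rate + N(0, jitter SD),
  clipped at 30% of the nominal interval; defaults rate 1.2 Hz, jitter
  30 ms.
* **EMG**: per muscle, one Gaussian burst per cycle (width 70 ms) at a
  muscle-specific phase offset; the deltoid fires a second burst (0.7
  amplitude) at +0.35 cycles, emulating its biphasic activation. Burst
  timing jitter (SD 40 ms) splits into a shared and a muscle-specific
  component with fraction `shared_burst_fraction` (default 0.7) — the
  knob behind coordination. The burst envelope (tonic baseline 0.1)
  multiplies a slow log-normal gain (Gaussian log-gain smoothed to ~0.1 Hz,
  SD 0.2 — the amplitude non-stationarity the recruitment trace must
  cancel) and a unit-RMS 20–295 Hz noise carrier.
* **EEG**: per channel, unit-variance 1/f^1 background noise spectrally
  shaped from white noise, then spatially blurred across electrodes with a
  Gaussian kernel (σ = 0.5 rad in the 2-D layout) so neighbouring channels
  correlate as volume-conducted EEG does, and re-standardized. The
  movement-locked components are cosines of the *instantaneous* cycle
  phase (piecewise-linear through the jittered onsets) at F0 and its
  double at F1, so jitter smears coherence realistically; they are scaled
  by the coupling gains and a fixed synthetic scalp weighting (Gaussian in
  layout distance from C3, σ = 0.45 rad, peak 1 — no head model; the
  analysis is sensor-level). An optional heartbeat artifact train is off
  by default. Default gains (0.05 at F0, 0.07 at F1) were chosen from the
  signal+noise closed form to land typical peak coherence in the 0.1–0.4
  range seen for such tasks.
* **Cohort**: a standard-normal latent u per subject drives the F1 gain
  log-normally (base 0.07, σ_log 0.6 — a wide realistic spread) and,
  through a bivariate Gaussian copula (Pearson 2·sin(π·ρ_s/6) for a target
  Spearman ρ_s), the gross-motor score; the fine-motor score correlates
  with the gross score (0.39) only through the gain-unrelated part by
  default, so it carries no direct coupling information. Score scales
  follow published healthy-adult norms (76.2 ± 7.6 blocks; 15.7 ± 1.7
  pegs). Movement rates draw uniformly from 1.0–1.5 Hz. All randomness
  fans out from a single seed through `numpy.random.SeedSequence`.

What the generator does **not** emulate: real volume-conduction geometry,
motor-unit physiology, eyeblink artifacts, non-stationary movement
strategies, or electrode drift over minutes. Passing tests therefore show
that the *estimators* behave as specified under the stated statistical
assumptions — not that real recordings satisfy those assumptions.

## Problem sizes in the test suite

The acceptance-style experiments run at desk scale by the package's own
choice of problem sizes: surrogate calibration uses 200 zero-coupling
subjects (16 channels, one 60 s trial, 200 surrogates each); closed-form
coherence recovery uses three 60 s trials (168 epochs before amplitude
rejection, which trims a few); cohort recovery uses 20 replicate
60-subject cohorts (12 channels, three 60 s trials per subject, no
per-subject surrogate testing, which the recovery statistic does not
need). Estimator tests use
n = 10,000–100,000 samples where bias bounds require it.

## Degenerate inputs and numerical conventions

All-zero EMG, constant traces, constant columns, single epochs, empty
non-edge electrode sets, all-flagged channel sets and all-rejected epoch
sets raise informative errors rather than propagating NaNs. Coherence is
clipped to [0, 1] against rounding. The 1.5 Hz worked example sits off the
0.2 Hz grid: F0 is detected at 1.4/1.6 Hz (spectral leakage splits the
off-grid line) while F1 = 3.0 Hz is on-grid and detected exactly — an
intrinsic property of the epoching, not an implementation artifact.

## Known limitations

* Cohort-level recovery of a designed coupling–score association is
  attenuated from the built-in rank correlation 0.5 to a recovered ~0.35
  (mean over 20 replicate 60-subject cohorts, three 60 s trials each):
  coherence estimation noise at 168 epochs, the max-statistic noise floor
  (~0.05) swallowing the lower half of the log-normal gain distribution,
  and rate-dependent off-grid scalloping each take a share. At that
  effect size, a 60-subject cohort flags the association (two-sided
  p < 0.05) in roughly 4 of 5 replicates — 17 of 20 in the suite's
  fixed-seed experiment — so single-cohort null results at this scale are
  weak evidence of absence.

* The surrogate test degenerates for perfectly periodic rhythms (above).
* Plug-in MI estimators carry the usual positive bias ((K−1)(L−1)/(2N ln 2)
  bits); at the pipeline's trace lengths this is ≪ 0.01 bits.
* The MMI redundancy measure is one defensible choice among PID
  measures; for two copula-Gaussian sources it is the standard closed
  form, and the measure name is recorded in the report output.
* EDF export is a minimal 16-bit writer meant for fixtures and
  interoperability smoke tests, not clinical archiving.
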