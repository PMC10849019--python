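"""EMG feature extraction: recruitment traces and the per-subject scalars.

Preprocesses the EMG (20-295 Hz band-pass with 50 Hz notches,
rectification), forms fast/slow-envelope recruitment traces, and prints the
coordination, regularity and modulation-depth scalars that later enter the
cohort table.
"""

import ckcpipe
from ckcpipe.preprocess import preprocess_recording

subject = ckcpipe.generate_subject(
    ckcpipe.SubjectSimConfig(duration=60, n_trials=1, seed=21,
                             shared_burst_fraction=0.8))
rec = preprocess_recording(subject.trials[0]).recording
features = ckcpipe.subject_emg_features(rec.samples[rec.emg_indices],
                                        rec.sample_rate)

for name, value in features.items():
    print(f"{name:18s} {value:7.3f}")
# xcorr_coord is the pair-averaged max lagged correlation (0-1; higher =
# more similar activation patterns across muscles); the three mi_* values
# are mutual-information variants of the same idea in bits; reg_*_peak are
# autocorrelation side-peak magnitudes (cycle-to-cycle consistency); and
# modulation_depth is the coefficient of variation of the recruitment trace
# (salience of the rhythmic activation).
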