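"""64-channel scalp layout based on the extended international 10-20 system.

Electrode positions come from MNE's standard montage and are projected to a
2-D plane with an azimuthal-equidistant projection (the usual "top view" of
the head).  The outermost ring of the cap is flagged as *edge* electrodes:
these sit closest to neck/face muscles and are excluded from coherence peak
picking.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np

#: Canonical 64-channel montage used by the synthetic generator and the
#: bundled layout table (a superset of the classic 10-20 positions).
CHANNELS_64: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2", "Iz",
)

#: Outermost cap ring — excluded from CKC peak extraction.
EDGE_CHANNELS: frozenset[str] = frozenset({
    "Fp1", "Fpz", "Fp2", "AF7", "AF8", "F7", "F8", "FT7", "FT8",
    "T7", "T8", "TP7", "TP8", "TP9", "TP10", "P7", "P8",
    "PO7", "PO8", "O1", "Oz", "O2", "Iz",
})


@lru_cache(maxsize=1)
def _standard_positions_2d() -> dict[str, tuple[float, float]]:
    """2-D positions (azimuthal-equidistant projection) for CHANNELS_64."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            montage = mne.channels.make_standard_montage("standard_1005")
        except ValueError:  # pragma: no cover - newer MNE renamed the montage
            montage = mne.channels.make_standard_montage("colin27_1005")
    ch_pos = montage.get_positions()["ch_pos"]
    out: dict[str, tuple[float, float]] = {}
    for name in CHANNELS_64:
        x, y, z = ch_pos[name]
        r = float(np.sqrt(x * x + y * y + z * z))
        theta = float(np.arccos(np.clip(z / r, -1.0, 1.0)))  # polar angle
        phi = float(np.arctan2(y, x))
        out[name] = (theta * np.cos(phi), theta * np.sin(phi))
    return out


def standard_layout(labels: list[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(positions, edge_flags)`` for the given EEG channel labels.

    Parameters
    ----------
    labels
        Channel names; defaults to :data:`CHANNELS_64`.  Unknown labels get
        NaN positions and are flagged as edge (conservative: they cannot win
        peak picking).

    Returns
    -------
    positions : (n, 2) float array
    edge_flags : (n,) bool array
    """
    if labels is None:
        labels = list(CHANNELS_64)
    pos2d = _standard_positions_2d()
    positions = np.full((len(labels), 2), np.nan)
    edge = np.ones(len(labels), dtype=bool)
    for i, name in enumerate(labels):
        if name in pos2d:
            positions[i] = pos2d[name]
            edge[i] = name in EDGE_CHANNELS
    return positions, edge
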