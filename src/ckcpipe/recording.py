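"""In-memory recording container and file I/O.

A :class:`Recording` holds a channels x time sample matrix together with the
sampling rate, channel labels and roles (EEG / EMG / AUX), and optionally a
2-D electrode layout with per-channel edge flags.  Three on-disk formats are
supported:

* the pipeline's own single-file HDF5 container (lossless round trip),
* delimited text (one column per channel, header row with labels) for toy
  data,
* EDF for real recordings (read through MNE; a minimal 16-bit writer is
  provided mainly so the test suite can build fixtures).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

ROLES = ("EEG", "EMG", "AUX")


@dataclass
class Recording:
    """Multichannel time series with channel metadata.

    samples are stored as a ``(n_channels, n_samples)`` float array in
    arbitrary units.  ``layout`` is an optional ``(n_channels, 2)`` array of
    2-D electrode positions (NaN for channels without a scalp position);
    ``edge_flags`` marks electrodes on the outer ring of the cap.
    """

    samples: np.ndarray
    sample_rate: float
    channel_labels: list[str]
    channel_roles: list[str]
    layout: np.ndarray | None = None
    edge_flags: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels, time) matrix")
        n = self.samples.shape[0]
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if len(self.channel_labels) != n or len(self.channel_roles) != n:
            raise ValueError("labels/roles must match the number of channels")
        if len(set(self.channel_labels)) != n:
            raise ValueError("channel labels must be unique")
        bad = set(self.channel_roles) - set(ROLES)
        if bad:
            raise ValueError(f"unknown channel roles: {sorted(bad)}")
        if self.layout is not None:
            self.layout = np.asarray(self.layout, dtype=float)
            if self.layout.shape != (n, 2):
                raise ValueError("layout must be (n_channels, 2)")
        if self.edge_flags is not None:
            self.edge_flags = np.asarray(self.edge_flags, dtype=bool)
            if self.edge_flags.shape != (n,):
                raise ValueError("edge_flags must be (n_channels,)")
        if self.edge_flags is not None and self.layout is None:
            raise ValueError("edge flags require a layout")

    # -- convenience -----------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def indices(self, role: str) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.channel_roles) if r == role],
                        dtype=int)

    @property
    def eeg_indices(self) -> np.ndarray:
        return self.indices("EEG")

    @property
    def emg_indices(self) -> np.ndarray:
        return self.indices("EMG")

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.samples[self.channel_labels.index(label)]
        except ValueError as err:
            raise KeyError(f"no channel named {label!r}") from err

    def copy(self) -> "Recording":
        return replace(
            self,
            samples=self.samples.copy(),
            channel_labels=list(self.channel_labels),
            channel_roles=list(self.channel_roles),
            layout=None if self.layout is None else self.layout.copy(),
            edge_flags=None if self.edge_flags is None else self.edge_flags.copy(),
            meta=dict(self.meta),
        )


def roles_from_labels(labels: list[str]) -> list[str]:
    """Assign roles by label prefix: ``EMG*`` -> EMG, ``AUX*`` -> AUX, else EEG."""
    out = []
    for lab in labels:
        u = lab.upper()
        if u.startswith("EMG"):
            out.append("EMG")
        elif u.startswith("AUX"):
            out.append("AUX")
        else:
            out.append("EEG")
    return out


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def save_container(rec: Recording, path) -> None:
    """Write a recording to the single-file HDF5 container."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=rec.samples)
        f.attrs["sample_rate"] = float(rec.sample_rate)
        str_dt = h5py.string_dtype(encoding="utf-8")
        f.create_dataset("channel_labels", data=np.array(rec.channel_labels, dtype=object), dtype=str_dt)
        f.create_dataset("channel_roles", data=np.array(rec.channel_roles, dtype=object), dtype=str_dt)
        if rec.layout is not None:
            f.create_dataset("layout", data=rec.layout)
        if rec.edge_flags is not None:
            f.create_dataset("edge_flags", data=rec.edge_flags.astype(np.uint8))


def load_container(path) -> Recording:
    import h5py

    with h5py.File(path, "r") as f:
        labels = [s.decode() if isinstance(s, bytes) else str(s) for s in f["channel_labels"][()]]
        roles = [s.decode() if isinstance(s, bytes) else str(s) for s in f["channel_roles"][()]]
        return Recording(
            samples=f["samples"][()],
            sample_rate=float(f.attrs["sample_rate"]),
            channel_labels=labels,
            channel_roles=roles,
            layout=f["layout"][()] if "layout" in f else None,
            edge_flags=f["edge_flags"][()].astype(bool) if "edge_flags" in f else None,
        )


# ---------------------------------------------------------------------------
# Delimited text
# ---------------------------------------------------------------------------

def read_delimited(path, sample_rate: float) -> Recording:
    """Read a delimited text file: header row of labels, one column per channel."""
    import pandas as pd

    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as err:
        raise ValueError(f"could not parse delimited recording {path!r}: {err}") from err
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise ValueError(f"delimited recording {path!r} contains no data")
    labels = [str(c) for c in df.columns]
    return Recording(
        samples=df.to_numpy(dtype=float).T,
        sample_rate=sample_rate,
        channel_labels=labels,
        channel_roles=roles_from_labels(labels),
    )


def write_delimited(rec: Recording, path) -> None:
    import pandas as pd

    pd.DataFrame(rec.samples.T, columns=rec.channel_labels).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def read_edf(path) -> Recording:
    """Read an EDF recording (roles assigned from label prefixes)."""
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as err:
        raise ValueError(f"could not read EDF file {path!r}: {err}") from err
    rates = {float(raw.info["sfreq"])}
    if len(rates) != 1:  # pragma: no cover - mne resamples mixed-rate EDF
        raise ValueError("mixed sampling rates in EDF are not supported")
    labels = list(raw.ch_names)
    return Recording(
        samples=raw.get_data(),
        sample_rate=float(raw.info["sfreq"]),
        channel_labels=labels,
        channel_roles=roles_from_labels(labels),
    )


def write_edf(rec: Recording, path, physical_max: float | None = None) -> None:
    """Write a minimal 16-bit EDF file (one data record per second).

    Intended for fixture generation and interoperability smoke tests, not as
    a clinical-grade exporter; samples are linearly quantized to the int16
    range per channel.
    """
    fs = rec.sample_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_rec = rec.n_samples // fs
    if n_rec == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    data = rec.samples[:, : n_rec * fs]
    nch = rec.n_channels

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    pmaxs = []
    digital = np.empty((nch, n_rec * fs), dtype="<i2")
    for i in range(nch):
        pm = physical_max or float(max(1e-9, np.max(np.abs(data[i])) * 1.0001))
        pmaxs.append(pm)
        digital[i] = np.clip(np.round(data[i] / pm * 32767), -32768, 32767).astype("<i2")

    header = b""
    header += pad("0", 8)                      # version
    header += pad("X X X X", 80)               # patient id
    header += pad("Startdate X", 80)           # recording id
    header += pad("01.01.00", 8) + pad("00.00.00", 8)
    header += pad(str(256 * (nch + 1)), 8)     # header bytes
    header += pad("", 44)                      # reserved
    header += pad(str(n_rec), 8)
    header += pad("1", 8)                      # record duration (s)
    header += pad(str(nch), 4)
    for lab in rec.channel_labels:
        header += pad(lab, 16)
    header += b" " * (80 * nch)                # transducer
    header += b"".join(pad("uV", 8) for _ in range(nch))
    for pm in pmaxs:
        header += pad(f"{-pm:.6g}"[:8], 8)
    for pm in pmaxs:
        header += pad(f"{pm:.6g}"[:8], 8)
    header += b"".join(pad("-32768", 8) for _ in range(nch))
    header += b"".join(pad("32767", 8) for _ in range(nch))
    header += b" " * (80 * nch)                # prefiltering
    header += b"".join(pad(str(fs), 8) for _ in range(nch))
    header += b" " * (32 * nch)                # reserved

    with open(path, "wb") as f:
        f.write(header)
        for r in range(n_rec):
            for i in range(nch):
                f.write(digital[i, r * fs:(r + 1) * fs].tobytes())


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

def read_recording(path, format: str = "auto", sample_rate: float | None = None) -> Recording:
    """Read a recording, dispatching on ``format`` or on the file extension.

    ``format`` is one of ``"container"`` (HDF5), ``"edf"``, ``"delimited"``
    or ``"auto"``.  Delimited text carries no rate and requires
    ``sample_rate``.
    """
    import os

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.getsize(path) == 0:
        raise ValueError(f"recording file {path!r} is empty")
    if format == "auto":
        ext = os.path.splitext(str(path))[1].lower()
        format = {".h5": "container", ".hdf5": "container", ".edf": "edf"}.get(ext, "delimited")
    if format == "container":
        return load_container(path)
    if format == "edf":
        return read_edf(path)
    if format == "delimited":
        if sample_rate is None:
            raise ValueError("sample_rate is required for delimited recordings")
        return read_delimited(path, sample_rate)
    raise ValueError(f"unknown recording format {format!r}")
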