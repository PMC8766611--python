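"""Recording container and file I/O.

Two interchange formats are supported for continuous EEG:

* **EDF** (European Data Format): written by a minimal in-package 16-bit
  writer (plain EDF, 1-s data records, per-channel physical scaling), read
  back through :func:`mne.io.read_raw_edf`. Event tables travel in a sidecar
  CSV (``<stem>_events.csv``) rather than EDF+ annotations.
* **Columnar text** (``.tsv``/``.txt``): ``# key: value`` header lines
  (``fs_hz``, ``channels``, optional ``reference``) followed by one
  tab-separated row per sample, amplitudes in microvolts.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


@dataclass
class ContinuousRecording:
    """Multichannel continuous EEG in microvolts.

    Attributes
    ----------
    data
        ``(n_channels, n_samples)`` array, microvolts.
    fs
        Sampling rate in Hz.
    channel_names
        Unique 10-20 system labels, one per row of ``data``.
    events
        ``(onset_sample, condition)`` stimulus events.
    reference
        Optional label of the acquisition reference electrode (stored, never
        applied: no re-referencing is performed by default).
    """

    data: np.ndarray
    fs: float
    channel_names: List[str]
    events: List[Tuple[int, str]] = field(default_factory=list)
    reference: Optional[str] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("one channel name per data row required")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        for onset, cond in self.events:
            if not 0 <= onset < self.n_samples:
                raise ValueError(
                    f"event ({onset}, {cond!r}) outside [0, {self.n_samples})"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **kw) -> "ContinuousRecording":
        out = {
            "data": self.data,
            "fs": self.fs,
            "channel_names": list(self.channel_names),
            "events": list(self.events),
            "reference": self.reference,
        }
        out.update(kw)
        return ContinuousRecording(**out)


class FormatError(ValueError):
    """Unreadable or unsupported recording file."""


# ---------------------------------------------------------------- EDF writer

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: ContinuousRecording, path) -> None:
    """Write a recording as plain EDF (16-bit, 1-second data records).

    The final record is zero-padded if ``n_samples`` is not a multiple of
    ``fs``; ``fs`` must be a positive integer number of samples per second.
    Events are written to ``<stem>_events.csv`` alongside.
    """
    path = Path(path)
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record
    if recording.n_channels == 0:
        raise FormatError("cannot write EDF with zero channels")
    n_records = int(np.ceil(recording.n_samples / spr))
    nchan = recording.n_channels

    # per-channel symmetric physical range covering the data
    phys_max = np.maximum(np.abs(recording.data).max(axis=1), 1.0)
    phys_max = np.ceil(phys_max)

    buf = _stdio.BytesIO()
    buf.write(_edf_field("0", 8))
    buf.write(_edf_field("X X X X", 80))                      # patient id
    buf.write(_edf_field("Startdate X X X X", 80))            # recording id
    buf.write(_edf_field("01.01.00", 8))
    buf.write(_edf_field("00.00.00", 8))
    buf.write(_edf_field(str(256 * (1 + nchan)), 8))
    buf.write(_edf_field("", 44))
    buf.write(_edf_field(str(n_records), 8))
    buf.write(_edf_field("1", 8))                             # record duration s
    buf.write(_edf_field(str(nchan), 4))
    for name in recording.channel_names:
        buf.write(_edf_field(name, 16))
    for _ in range(nchan):
        buf.write(_edf_field("", 80))                         # transducer
    for _ in range(nchan):
        buf.write(_edf_field("uV", 8))
    for pm in phys_max:
        buf.write(_edf_field(f"{-pm:.0f}", 8))
    for pm in phys_max:
        buf.write(_edf_field(f"{pm:.0f}", 8))
    for _ in range(nchan):
        buf.write(_edf_field(str(_EDF_DIG_MIN), 8))
    for _ in range(nchan):
        buf.write(_edf_field(str(_EDF_DIG_MAX), 8))
    for _ in range(nchan):
        buf.write(_edf_field("", 80))                         # prefiltering
    for _ in range(nchan):
        buf.write(_edf_field(str(spr), 8))
    for _ in range(nchan):
        buf.write(_edf_field("", 32))

    padded = np.zeros((nchan, n_records * spr))
    padded[:, : recording.n_samples] = recording.data
    scale = (phys_max / _EDF_DIG_MAX)[:, None]
    digital = np.clip(
        np.round(padded / scale), _EDF_DIG_MIN, _EDF_DIG_MAX
    ).astype("<i2")
    for r in range(n_records):
        buf.write(digital[:, r * spr : (r + 1) * spr].tobytes())

    path.write_bytes(buf.getvalue())
    _write_events_sidecar(recording, path)


def _events_sidecar_path(path: Path) -> Path:
    return path.with_name(path.stem + "_events.csv")


def _write_events_sidecar(recording: ContinuousRecording, path: Path) -> None:
    if recording.events:
        pd.DataFrame(
            recording.events, columns=["onset_sample", "condition"]
        ).to_csv(_events_sidecar_path(path), index=False)


def _read_events_sidecar(path: Path) -> List[Tuple[int, str]]:
    sidecar = _events_sidecar_path(path)
    if not sidecar.exists():
        return []
    df = pd.read_csv(sidecar)
    return [(int(r.onset_sample), str(r.condition)) for r in df.itertuples()]


# -------------------------------------------------------------- columnar text


def write_columnar(recording: ContinuousRecording, path) -> None:
    """Write the documented columnar text dialect (tab-separated, uV)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs_hz: {recording.fs:g}\n")
        fh.write("# channels: " + ",".join(recording.channel_names) + "\n")
        if recording.reference is not None:
            fh.write(f"# reference: {recording.reference}\n")
        np.savetxt(fh, recording.data.T, fmt="%.6f", delimiter="\t")
    _write_events_sidecar(recording, path)


def _load_columnar(path: Path) -> ContinuousRecording:
    meta = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
    if "fs_hz" not in meta or "channels" not in meta:
        raise FormatError(
            f"{path}: missing 'fs_hz'/'channels' header; found keys {sorted(meta)}"
        )
    channels = [c for c in meta["channels"].split(",") if c]
    if not channels:
        raise FormatError(f"{path}: empty channel list")
    data = np.loadtxt(path, skiprows=n_header, delimiter="\t", ndmin=2)
    if data.shape[1] != len(channels):
        raise FormatError(
            f"{path}: {data.shape[1]} columns but {len(channels)} channel labels"
        )
    return ContinuousRecording(
        data=data.T,
        fs=float(meta["fs_hz"]),
        channel_names=channels,
        events=_read_events_sidecar(path),
        reference=meta.get("reference"),
    )


def _load_edf(path: Path) -> ContinuousRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if len(raw.ch_names) == 0:
        raise FormatError(f"{path}: no channels")
    return ContinuousRecording(
        data=raw.get_data() * 1e6,  # volts -> microvolts
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        events=_read_events_sidecar(path),
    )


def load_recording(path) -> ContinuousRecording:
    """Load a recording from EDF or the columnar text dialect.

    The format is chosen by extension: ``.edf`` for EDF, ``.tsv``/``.txt``
    for columnar text. Amplitudes are returned in microvolts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ext = path.suffix.lower()
    if ext == ".edf":
        return _load_edf(path)
    if ext in (".tsv", ".txt"):
        return _load_columnar(path)
    raise FormatError(f"unknown recording extension {ext!r} for {path}")


def save_recording(recording: ContinuousRecording, path) -> None:
    """Write a recording; format chosen by extension (see load_recording)."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".edf":
        write_edf(recording, path)
    elif ext in (".tsv", ".txt"):
        write_columnar(recording, path)
    else:
        raise FormatError(f"unknown recording extension {ext!r} for {path}")
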