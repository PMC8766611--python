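"""Filtering, epoching, baseline correction, and artifact rejection.

The chain mirrors the study's preprocessing: a fourth-order Butterworth
band-pass (0.5-70 Hz) applied forward-backward (zero phase), a 50 Hz notch,
3000 ms epochs relative to stimulus onset, baseline correction to the
pre-stimulus mean, and threshold-based rejection (any sample beyond 100 uV)
plus an automated EMG criterion (50-200 Hz component with 1-10 mV amplitude,
evaluated on the raw, pre-band-pass signal since the band of interest lies
above the band-pass edge).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, NamedTuple, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import signal

from .config import FilterConfig, PipelineConfig, RejectionConfig
from .io import ContinuousRecording


@dataclass
class EpochSet:
    """Trials x channels x samples, with labels and provenance.

    ``window`` is ``(start_s, end_s)`` relative to stimulus onset, half-open:
    sample ``k`` of an epoch sits at ``start_s + k / fs``.
    """

    data: np.ndarray
    fs: float
    labels: np.ndarray
    parent_ids: np.ndarray
    channel_names: List[str]
    window: Tuple[float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        self.parent_ids = np.asarray(self.parent_ids, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")
        n = self.data.shape[0]
        if not (len(self.labels) == len(self.parent_ids) == n):
            raise ValueError("labels/parent_ids must match trial count")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def select(self, idx) -> "EpochSet":
        idx = np.asarray(idx)
        return EpochSet(
            self.data[idx], self.fs, self.labels[idx], self.parent_ids[idx],
            list(self.channel_names), self.window,
        )

    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.n_samples) / self.fs


KEPT = "kept"
REJECTED_AMPLITUDE = "rejected-amplitude"
FLAGGED_EMG = "flagged-emg"


@dataclass
class RejectionLog:
    """Exhaustive per-epoch rejection decisions plus the thresholds used."""

    decisions: List[str]
    amp_threshold_uv: float
    emg_band_hz: Tuple[float, float]
    emg_amp_mv: Tuple[float, float]

    def __post_init__(self) -> None:
        bad = set(self.decisions) - {KEPT, REJECTED_AMPLITUDE, FLAGGED_EMG}
        if bad:
            raise ValueError(f"unknown decisions {bad}")

    @property
    def n_kept(self) -> int:
        return self.decisions.count(KEPT)

    @property
    def n_rejected(self) -> int:
        return len(self.decisions) - self.n_kept

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"epoch": np.arange(len(self.decisions)), "decision": self.decisions}
        )


class Cutoffs(NamedTuple):
    low: float
    high: float


def normalized_cutoffs(low_hz: float, high_hz: float, fs: float) -> Cutoffs:
    """Band-pass corner frequencies as exact fractions of the Nyquist rate."""
    nyq = fs / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(
            f"need 0 < low ({low_hz}) < high ({high_hz}) < Nyquist ({nyq})"
        )
    return Cutoffs(low_hz / nyq, high_hz / nyq)


def reported_cutoffs(low_hz: float, high_hz: float, fs: float) -> Cutoffs:
    """Normalized cutoffs under the reporting convention: the low corner is
    truncated to 4 decimal places and the high corner to 3."""
    c = normalized_cutoffs(low_hz, high_hz, fs)
    return Cutoffs(np.floor(c.low * 1e4) / 1e4, np.floor(c.high * 1e3) / 1e3)


def _bandpass_sos(low_hz: float, high_hz: float, order: int, fs: float):
    wn = normalized_cutoffs(low_hz, high_hz, fs)
    return signal.butter(order, [wn.low, wn.high], btype="bandpass", output="sos")


def apply_filters(
    recording: ContinuousRecording, config: Union[PipelineConfig, FilterConfig]
) -> ContinuousRecording:
    """Band-pass then notch filter a recording, preserving its shape.

    Zero-phase (forward-backward) application is the default so that peak
    latencies are unbiased; a causal single-pass variant is available through
    ``FilterConfig(zero_phase=False)``.
    """
    fc = config.filter if isinstance(config, PipelineConfig) else config
    data = recording.data
    finite = np.isfinite(data).all(axis=1)
    if not finite.all():
        bad = int(np.flatnonzero(~finite)[0])
        raise ValueError(
            f"non-finite samples in channel {bad} ({recording.channel_names[bad]})"
        )
    sos = _bandpass_sos(fc.low_hz, fc.high_hz, fc.order, recording.fs)
    if fc.zero_phase:
        out = signal.sosfiltfilt(sos, data, axis=1)
    else:
        out = signal.sosfilt(sos, data, axis=1)
    b, a = signal.iirnotch(fc.notch_hz, fc.notch_q, fs=recording.fs)
    if fc.zero_phase:
        out = signal.filtfilt(b, a, out, axis=1)
    else:
        out = signal.lfilter(b, a, out, axis=1)
    return recording.copy_with(data=out)


def extract_epochs(
    recording: ContinuousRecording,
    window: Tuple[float, float],
    events: Optional[Sequence[Tuple[int, str]]] = None,
) -> EpochSet:
    """Cut one epoch per event over a half-open window around stimulus onset.

    ``window=(0, 3.0)`` extracts the first 3 s of stimulation;
    ``window=(-3.0, 0)`` extracts the 3-s pre-stimulus baseline with the
    same operation. Epoch length is ``round((end - start) * fs)`` samples.
    """
    start_s, end_s = window
    if end_s <= start_s:
        raise ValueError(f"empty window {window}")
    events = list(recording.events if events is None else events)
    if not events:
        raise ValueError("no events to epoch")
    fs = recording.fs
    n_win = int(round((end_s - start_s) * fs))
    offset = int(round(start_s * fs))
    chunks, labels = [], []
    for k, (onset, cond) in enumerate(events):
        i0 = onset + offset
        i1 = i0 + n_win
        if i0 < 0 or i1 > recording.n_samples:
            raise ValueError(
                f"event {k} ({cond!r} at sample {onset}) window "
                f"[{i0}, {i1}) outside recording [0, {recording.n_samples})"
            )
        chunks.append(recording.data[:, i0:i1])
        labels.append(cond)
    return EpochSet(
        data=np.stack(chunks),
        fs=fs,
        labels=np.array(labels),
        parent_ids=np.arange(len(events)),
        channel_names=list(recording.channel_names),
        window=(start_s, end_s),
    )


def baseline_correct(
    epochs: EpochSet, baseline: Union[EpochSet, Tuple[float, float]]
) -> EpochSet:
    """Subtract the pre-stimulus mean, per trial and channel.

    ``baseline`` is either a trial-matched EpochSet (e.g. the ``[-3, 0)``
    extraction) or a window in seconds within ``epochs`` itself.
    """
    if isinstance(baseline, EpochSet):
        if baseline.n_epochs != epochs.n_epochs:
            raise ValueError(
                f"baseline has {baseline.n_epochs} trials, epochs "
                f"{epochs.n_epochs}"
            )
        if baseline.channel_names != epochs.channel_names:
            raise ValueError("baseline/epoch channel mismatch")
        means = baseline.data.mean(axis=2, keepdims=True)
    else:
        t = epochs.times()
        mask = (t >= baseline[0]) & (t < baseline[1])
        if not mask.any():
            raise ValueError(f"baseline window {baseline} selects no samples")
        means = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return replace(epochs, data=epochs.data - means)


def save_epochs(epochs: EpochSet, directory) -> None:
    """Write an EpochSet as per-trial CSV files plus a JSON manifest."""
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for k in range(epochs.n_epochs):
        pd.DataFrame(
            epochs.data[k].T, columns=epochs.channel_names
        ).to_csv(directory / f"trial_{k:04d}.csv", index=False)
    manifest = {
        "fs": epochs.fs,
        "window": list(epochs.window),
        "channel_names": list(epochs.channel_names),
        "labels": [str(x) for x in epochs.labels],
        "parent_ids": epochs.parent_ids.tolist(),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_epochs(directory) -> EpochSet:
    """Read an EpochSet written by :func:`save_epochs`."""
    import json
    from pathlib import Path

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    data = [
        pd.read_csv(directory / f"trial_{k:04d}.csv").to_numpy().T
        for k in range(len(manifest["labels"]))
    ]
    return EpochSet(
        data=np.stack(data),
        fs=manifest["fs"],
        labels=np.array(manifest["labels"]),
        parent_ids=np.array(manifest["parent_ids"]),
        channel_names=manifest["channel_names"],
        window=tuple(manifest["window"]),
    )


def _emg_amplitude_uv(raw: np.ndarray, fs: float, band: Tuple[float, float]) -> float:
    """Peak absolute amplitude of the band-limited (EMG band) component."""
    high = min(band[1], 0.999 * fs / 2)
    sos = signal.butter(4, [band[0], high], btype="bandpass", fs=fs, output="sos")
    return float(np.abs(signal.sosfiltfilt(sos, raw, axis=-1)).max())


def reject_artifacts(
    epochs: EpochSet,
    raw_epochs: Optional[EpochSet] = None,
    config: Optional[Union[PipelineConfig, RejectionConfig]] = None,
) -> Tuple[EpochSet, RejectionLog]:
    """Drop epochs with high-amplitude artifacts or EMG contamination.

    An epoch is *rejected-amplitude* if any absolute sample exceeds the
    threshold (default 100 uV) in the filtered data; otherwise it is
    *flagged-emg* (and dropped) if the 50-200 Hz component of the matching
    raw epoch has peak amplitude within 1-10 mV. The EMG criterion needs
    ``raw_epochs`` (pre-band-pass) because the EMG band lies above the
    band-pass edge; without them it is skipped.
    """
    if config is None:
        config = RejectionConfig()
    rc = config.rejection if isinstance(config, PipelineConfig) else config
    if rc.amp_threshold_uv <= 0:
        raise ValueError("amplitude threshold must be positive")
    if raw_epochs is not None and raw_epochs.n_epochs != epochs.n_epochs:
        raise ValueError("raw_epochs must match epochs trial-for-trial")
    lo_uv, hi_uv = (1000.0 * m for m in rc.emg_amp_mv)
    decisions: List[str] = []
    for k in range(epochs.n_epochs):
        if np.abs(epochs.data[k]).max() > rc.amp_threshold_uv:
            decisions.append(REJECTED_AMPLITUDE)
        elif raw_epochs is not None:
            amp = _emg_amplitude_uv(raw_epochs.data[k], raw_epochs.fs, rc.emg_band_hz)
            decisions.append(FLAGGED_EMG if lo_uv <= amp <= hi_uv else KEPT)
        else:
            decisions.append(KEPT)
    keep = [k for k, d in enumerate(decisions) if d == KEPT]
    log = RejectionLog(
        decisions=decisions,
        amp_threshold_uv=rc.amp_threshold_uv,
        emg_band_hz=tuple(rc.emg_band_hz),
        emg_amp_mv=tuple(rc.emg_amp_mv),
    )
    return epochs.select(keep), log
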