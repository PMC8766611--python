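"""Band power, ERD index, global field power, peak detection, correlation.

* Band power: per-channel integrated Welch power spectral density over a
  frequency band (default Welch settings: 1-s Hann segments, 50% overlap),
  averaged over trials. Units uV^2.
* ERD index: relative band-power decrease (baseline - stimulation) /
  baseline; positive values indicate desynchronization.
* GFP: the instantaneous population standard deviation of the potentials
  across all electrodes -- a reference-free measure of global field
  strength.
* Peak detection: the (channel, latency) maximizing absolute amplitude of a
  trial-averaged response within a search window.
* Pearson correlation between per-trial alpha power and discomfort ratings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as _signal
from scipy import stats as _stats

from .config import SpectralConfig
from .preprocessing import EpochSet


@dataclass
class BandPowerMap:
    """Trial-averaged per-channel band power (uV^2)."""

    power: np.ndarray
    channel_names: List[str]
    band: Tuple[float, float]
    condition: Optional[str] = None
    n_trials: int = 0

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        if len(self.power) != len(self.channel_names):
            raise ValueError("one power value per channel required")

    def __getitem__(self, channel: str) -> float:
        return float(self.power[self.channel_names.index(channel)])


@dataclass
class GFPSeries:
    """Global field power over time (uV)."""

    values: np.ndarray
    fs: float

    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.fs


@dataclass(frozen=True)
class PeakResult:
    channel: str
    latency_s: float
    amplitude_uv: float


def band_power(
    epochs: EpochSet,
    band: Tuple[float, float],
    config: Optional[SpectralConfig] = None,
    condition: Optional[str] = None,
) -> BandPowerMap:
    """Mean over trials of the integrated Welch PSD over ``band`` per channel."""
    cfg = config or SpectralConfig()
    low, high = band
    nyq = epochs.fs / 2
    if not 0 <= low < high <= nyq:
        raise ValueError(f"band {band} outside (0, Nyquist={nyq}]")
    if epochs.n_epochs < 1:
        raise ValueError("need at least one epoch")
    nperseg = min(int(round(cfg.welch_segment_s * epochs.fs)), epochs.n_samples)
    noverlap = int(round(nperseg * cfg.welch_overlap))
    freqs, psd = _signal.welch(
        epochs.data, fs=epochs.fs, nperseg=nperseg, noverlap=noverlap,
        window="hann", axis=-1,
    )
    mask = (freqs >= low) & (freqs <= high)
    if mask.sum() < 2:
        raise ValueError(f"band {band} narrower than spectral resolution")
    power = np.trapezoid(psd[..., mask], freqs[mask], axis=-1)
    return BandPowerMap(
        power=power.mean(axis=0),
        channel_names=list(epochs.channel_names),
        band=(low, high),
        condition=condition,
        n_trials=epochs.n_epochs,
    )


def erd_index(stim_power: BandPowerMap, base_power: BandPowerMap) -> np.ndarray:
    """Per-channel ERD fraction (base - stim) / base; NaN where base is 0."""
    if stim_power.channel_names != base_power.channel_names:
        raise ValueError("channel mismatch between stimulation and baseline maps")
    if stim_power.band != base_power.band:
        raise ValueError("band mismatch between stimulation and baseline maps")
    base = base_power.power
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (base - stim_power.power) / base
    return np.where(base > 0, out, np.nan)


def average_epochs(epochs: EpochSet, condition: Optional[str] = None) -> np.ndarray:
    """Trial-averaged evoked response (channels x samples)."""
    data = epochs.data
    if condition is not None:
        sel = epochs.labels == condition
        if not sel.any():
            raise ValueError(f"no epochs labelled {condition!r}")
        data = data[sel]
    return data.mean(axis=0)


def compute_gfp(evoked: np.ndarray, fs: float) -> GFPSeries:
    """GFP: population standard deviation across electrodes per timepoint."""
    evoked = np.asarray(evoked, dtype=float)
    if evoked.ndim != 2 or evoked.shape[0] < 2:
        raise ValueError("evoked must be (>=2 channels) x samples")
    return GFPSeries(values=evoked.std(axis=0, ddof=0), fs=fs)


def detect_peak(
    evoked: np.ndarray,
    fs: float,
    window: Tuple[float, float],
    channel_names: Sequence[str],
    t0: float = 0.0,
) -> PeakResult:
    """Largest absolute deflection of a trial-averaged response.

    Searches ``window`` (seconds, half-open, relative to the same origin as
    ``t0``, the time of the first sample). Ties are broken by earliest
    latency and then by channel order. The returned amplitude is signed.
    """
    evoked = np.asarray(evoked, dtype=float)
    if evoked.ndim != 2:
        raise ValueError("evoked must be channels x samples")
    i0 = max(int(round((window[0] - t0) * fs)), 0)
    i1 = min(int(round((window[1] - t0) * fs)), evoked.shape[1])
    if i1 <= i0:
        raise ValueError(f"window {window} selects no samples")
    sub = np.abs(evoked[:, i0:i1])
    peak = sub.max()
    # earliest timepoint attaining the max, then lowest channel index
    cols = sub.max(axis=0)
    j = int(np.flatnonzero(cols == peak)[0])
    c = int(np.flatnonzero(sub[:, j] == peak)[0])
    sample = i0 + j
    return PeakResult(
        channel=channel_names[c],
        latency_s=t0 + sample / fs,
        amplitude_uv=float(evoked[c, sample]),
    )


def alpha_discomfort_correlation(
    alpha_powers: Sequence[float], ratings: Sequence[float]
) -> float:
    """Pearson r between per-trial alpha power and discomfort ratings.

    Returns NaN when either variable has zero variance.
    """
    x = np.asarray(alpha_powers, dtype=float)
    y = np.asarray(ratings, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired 1-D samples required")
    if len(x) < 3:
        raise ValueError("need at least 3 paired samples")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(_stats.pearsonr(x, y).statistic)
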