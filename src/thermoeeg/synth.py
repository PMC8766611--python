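"""Synthetic EEG sessions, behavioral ratings, and robot-skin profiles.

The generator emulates the statistical structure the downstream analyses
assume, so that every stage of the pipeline can be verified against known
ground truth:

* background: 1/f (pink) noise per channel plus an ongoing 8-12 Hz alpha
  rhythm weighted toward posterior/central electrodes;
* condition-scaled alpha desynchronization during stimulation, strongest at
  contralateral-central channels (right-hand stimulation, left hemisphere):
  the alpha amplitude is multiplied by ``sqrt(1 - f * w)`` so that the
  measured *power* ERD ``(base - stim)/base`` at a unit-weight channel
  recovers the injected fraction ``f`` exactly;
* a Gaussian-windowed biphasic evoked transient per stimulus onset with
  condition-specific latency and a Cz-peaked amplitude ordered by
  discomfort;
* injected artifacts (high-amplitude excursions beyond 100 uV; 120-180 Hz
  EMG bursts of 1.5-5 mV) with a complete ground-truth table;
* 0-9 discomfort ratings drawn from a truncated normal with the published
  per-condition mean/SD, rounded to integers;
* exponential skin-contact temperature profiles (two sensors at 250 Hz)
  relaxing from a 28 C ambient toward the object temperature.

Identical (config, seed) pairs reproduce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy import stats as _stats

from .conditions import CONDITIONS, CONTRALATERAL_CENTRAL, condition
from .io import ContinuousRecording
from .paradigm import StimulusParadigm
from .skin import SKIN_FS, TEMP_BINS, SkinProfile

#: Default injected power-ERD fraction per condition (strictly increasing
#: with discomfort: warm < hot < cold < very_hot < very_cold).
DEFAULT_ERD_FRACTIONS = {
    "warm": 0.05, "hot": 0.25, "cold": 0.35, "very_hot": 0.55, "very_cold": 0.65,
}

#: Default evoked peak latency per condition, seconds after stimulus onset.
DEFAULT_PEAK_LATENCIES = {
    "very_cold": 0.30, "very_hot": 0.45, "hot": 0.65, "cold": 0.95, "warm": 0.80,
}

#: Default evoked peak amplitude at Cz, uV, ordered by discomfort.
DEFAULT_PEAK_AMPLITUDES = {
    "warm": 2.5, "hot": 4.0, "cold": 5.0, "very_hot": 7.0, "very_cold": 8.0,
}


def _default_alpha_weights(channel_names: Sequence[str]) -> Dict[str, float]:
    """Ongoing-alpha amplitude weight by scalp region (posterior dominant)."""
    out = {}
    for name in channel_names:
        if name.startswith(("O", "PO", "I")):
            out[name] = 1.0
        elif name.startswith(("P", "TP")):
            out[name] = 0.8
        elif name.startswith(("C", "T", "FC", "FT")):
            out[name] = 0.6
        else:
            out[name] = 0.15
    return out


def _default_erd_weights(channel_names: Sequence[str]) -> Dict[str, float]:
    """ERD site weight: contralateral-central dominant, milder elsewhere."""
    out = {}
    for name in channel_names:
        if name in CONTRALATERAL_CENTRAL:
            out[name] = 1.0
        elif name.startswith(("C", "FC")):
            out[name] = 0.4
        elif name.startswith(("P", "PO", "O")):
            out[name] = 0.2
        else:
            out[name] = 0.0
    return out


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth effect sizes injected by the EEG generator.

    ``alpha_erd_fraction`` is the power-ERD fraction per condition at a
    unit-weight channel; ``erd_channel_weights`` scales it across the scalp.
    Conditions missing from a mapping take no effect. Setting
    ``noise_amplitude_uv`` and ``alpha_amplitude_uv`` to zero gives a
    noise-free record carrying only the evoked transients.
    """

    alpha_erd_fraction: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ERD_FRACTIONS)
    )
    erd_channel_weights: Optional[Dict[str, float]] = None  # None -> default map
    peak_latency_s: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PEAK_LATENCIES)
    )
    peak_channel: Dict[str, str] = field(
        default_factory=lambda: {c: "Cz" for c in DEFAULT_PEAK_LATENCIES}
    )
    peak_amplitude_uv: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PEAK_AMPLITUDES)
    )
    noise_exponent: float = 1.0
    noise_amplitude_uv: float = 5.0     # broadband RMS of the pink noise
    alpha_amplitude_uv: float = 15.0    # RMS of the alpha rhythm at weight 1
    alpha_channel_weights: Optional[Dict[str, float]] = None
    artifact_rate_amplitude: float = 0.1  # expected events per trial
    artifact_rate_emg: float = 0.1
    evoked_sigma_s: float = 0.08
    evoked_carrier_hz: float = 4.0

    def for_montage(self, channel_names: Sequence[str]):
        """Resolve weight maps against a montage, validating channel names."""
        erd = (
            dict(self.erd_channel_weights)
            if self.erd_channel_weights is not None
            else _default_erd_weights(channel_names)
        )
        alpha = (
            dict(self.alpha_channel_weights)
            if self.alpha_channel_weights is not None
            else _default_alpha_weights(channel_names)
        )
        known = set(channel_names)
        for mapping, what in (
            (erd, "ERD weight"), (alpha, "alpha weight"),
            ({ch: 1 for ch in self.peak_channel.values()}, "peak channel"),
        ):
            for ch in mapping:
                if ch not in known:
                    raise ValueError(f"{what} channel {ch!r} not in montage")
        return erd, alpha


def noiseless_effects(**overrides) -> EffectSpec:
    """EffectSpec carrying evoked transients only (no noise, alpha, artifacts)."""
    base = dict(
        noise_amplitude_uv=0.0, alpha_amplitude_uv=0.0,
        artifact_rate_amplitude=0.0, artifact_rate_emg=0.0,
    )
    base.update(overrides)
    return EffectSpec(**base)


@dataclass
class SessionData:
    """One generated session: the recording plus its ground truth."""

    recording: ContinuousRecording
    events: pd.DataFrame     # trial, onset_s, stim_onset_s, condition, session, rating
    artifacts: pd.DataFrame  # trial, time_s, kind, channel, amplitude_uv, duration_s
    seed: int


def _pink_noise(rng: np.random.Generator, shape: Tuple[int, int], exponent: float):
    """Unit-RMS 1/f^exponent noise per row, via spectral shaping."""
    n_ch, n = shape
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (
        rng.standard_normal((n_ch, len(freqs)))
        + 1j * rng.standard_normal((n_ch, len(freqs)))
    ) * amp
    x = np.fft.irfft(spec, n=n, axis=1)
    rms = x.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return x / rms


def _alpha_rhythm(rng: np.random.Generator, shape: Tuple[int, int], fs: float):
    """Unit-RMS narrowband (8-12 Hz) Gaussian noise per row."""
    white = rng.standard_normal(shape)
    sos = _signal.butter(4, [8.0, 12.0], btype="bandpass", fs=fs, output="sos")
    x = _signal.sosfiltfilt(sos, white, axis=1)
    rms = x.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return x / rms


def _evoked_profile(peak_channel: str, channel_names: Sequence[str]) -> np.ndarray:
    """Spatial spread of the evoked transient: peak 1.0, same electrode row
    0.45, elsewhere 0.15."""
    row = "".join(c for c in peak_channel if not (c.isdigit() or c == "z"))
    prof = np.empty(len(channel_names))
    for i, name in enumerate(channel_names):
        if name == peak_channel:
            prof[i] = 1.0
        else:
            this_row = "".join(c for c in name if not (c.isdigit() or c == "z"))
            prof[i] = 0.45 if this_row == row else 0.15
    return prof


def generate_eeg_session(
    paradigm: StimulusParadigm, effects: EffectSpec, seed: int
) -> SessionData:
    """Generate a continuous EEG session with full ground truth.

    Requires a paradigm with a concrete schedule (see
    :func:`thermoeeg.paradigm.generate_paradigm`). The recording spans the
    scheduled trials back-to-back (40 s each); events mark stimulation
    onsets. Identical (paradigm, effects, seed) give bit-identical output.
    """
    if not paradigm.schedule:
        raise ValueError("paradigm has no schedule; run generate_paradigm first")
    channel_names = list(paradigm.channel_names)
    erd_w, alpha_w = effects.for_montage(channel_names)
    fs = paradigm.fs
    layout = paradigm.trial_layout
    trial_len = layout.duration_s
    n_trials = len(paradigm.schedule)
    n = int(round(n_trials * trial_len * fs))
    n_ch = len(channel_names)

    ss = np.random.SeedSequence(seed)
    rng_noise, rng_alpha, rng_art, rng_rate = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    data = np.zeros((n_ch, n))
    if effects.noise_amplitude_uv > 0:
        data += effects.noise_amplitude_uv * _pink_noise(
            rng_noise, (n_ch, n), effects.noise_exponent
        )

    # ongoing alpha rhythm with per-trial stimulation-window desynchronization
    if effects.alpha_amplitude_uv > 0:
        alpha_idx = [i for i, ch in enumerate(channel_names) if alpha_w.get(ch, 0) > 0]
        alpha = _alpha_rhythm(rng_alpha, (len(alpha_idx), n), fs)
        weights = np.array(
            [effects.alpha_amplitude_uv * alpha_w.get(channel_names[i], 0.0) for i in alpha_idx]
        )
        alpha *= weights[:, None]
        erd_vec = np.array([erd_w.get(channel_names[i], 0.0) for i in alpha_idx])
        for k, (onset_s, cond, _sess) in enumerate(paradigm.schedule):
            f = effects.alpha_erd_fraction.get(cond, 0.0)
            if f <= 0:
                continue
            i0 = int(round((onset_s + layout.baseline_s) * fs))
            i1 = int(round((onset_s + trial_len) * fs))
            scale = np.sqrt(np.clip(1.0 - f * erd_vec, 0.0, None))
            alpha[:, i0:i1] *= scale[:, None]
        data[alpha_idx] += alpha

    # evoked transients: Gaussian-windowed biphasic pulse at nearest sample
    sigma = effects.evoked_sigma_s
    half = int(round(4 * sigma * fs))
    events: List[Tuple[int, str]] = []
    rows = []
    for k, (onset_s, cond, sess) in enumerate(paradigm.schedule):
        stim_sample = int(round((onset_s + layout.baseline_s) * fs))
        events.append((stim_sample, cond))
        amp = effects.peak_amplitude_uv.get(cond, 0.0)
        lat = effects.peak_latency_s.get(cond)
        if amp != 0 and lat is not None:
            center = stim_sample + int(round(lat * fs))
            i0, i1 = max(center - half, 0), min(center + half + 1, n)
            t = (np.arange(i0, i1) - center) / fs
            wave = amp * np.exp(-(t**2) / (2 * sigma**2)) * np.cos(
                2 * np.pi * effects.evoked_carrier_hz * t
            )
            prof = _evoked_profile(effects.peak_channel.get(cond, "Cz"), channel_names)
            data[:, i0:i1] += prof[:, None] * wave[None, :]
        rows.append(
            {"trial": k, "onset_s": onset_s,
             "stim_onset_s": onset_s + layout.baseline_s,
             "condition": cond, "session": sess}
        )
    events_df = pd.DataFrame(rows)

    # ratings: one per trial, truncated-normal around the condition mean
    ratings = []
    for cond in events_df["condition"]:
        ratings.append(
            float(generate_ratings(cond, 1, rng_rate, integer=True)[0])
        )
    events_df["rating"] = ratings

    # injected artifacts, with complete bookkeeping
    art_rows = []
    for k, (onset_s, cond, _sess) in enumerate(paradigm.schedule):
        lo = onset_s + 0.3
        hi = onset_s + trial_len - 0.3
        for _ in range(rng_art.poisson(effects.artifact_rate_amplitude)):
            t0 = rng_art.uniform(lo, hi)
            ch = int(rng_art.integers(n_ch))
            amp = rng_art.uniform(150.0, 300.0) * rng_art.choice([-1.0, 1.0])
            center = int(round(t0 * fs))
            s = 0.02
            w = int(round(4 * s * fs))
            i0, i1 = max(center - w, 0), min(center + w + 1, n)
            t = (np.arange(i0, i1) - center) / fs
            data[ch, i0:i1] += amp * np.exp(-(t**2) / (2 * s**2))
            art_rows.append(
                {"trial": k, "time_s": t0, "kind": "amplitude",
                 "channel": channel_names[ch], "amplitude_uv": amp,
                 "duration_s": 8 * s}
            )
        for _ in range(rng_art.poisson(effects.artifact_rate_emg)):
            t0 = rng_art.uniform(lo, hi)
            ch = int(rng_art.integers(n_ch))
            amp = rng_art.uniform(1500.0, 5000.0)
            freq = rng_art.uniform(120.0, 180.0)
            center = int(round(t0 * fs))
            s = 0.05
            w = int(round(4 * s * fs))
            i0, i1 = max(center - w, 0), min(center + w + 1, n)
            t = (np.arange(i0, i1) - center) / fs
            data[ch, i0:i1] += (
                amp * np.exp(-(t**2) / (2 * s**2)) * np.sin(2 * np.pi * freq * t)
            )
            art_rows.append(
                {"trial": k, "time_s": t0, "kind": "emg",
                 "channel": channel_names[ch], "amplitude_uv": amp,
                 "duration_s": 8 * s}
            )
    artifacts_df = pd.DataFrame(
        art_rows,
        columns=["trial", "time_s", "kind", "channel", "amplitude_uv", "duration_s"],
    )

    recording = ContinuousRecording(
        data=data, fs=fs, channel_names=channel_names, events=events,
    )
    return SessionData(
        recording=recording, events=events_df, artifacts=artifacts_df, seed=seed
    )


def generate_ratings(
    condition_name: str,
    n: int,
    seed,
    integer: bool = True,
) -> np.ndarray:
    """Draw 0-9 discomfort ratings for a condition.

    Samples a normal with the condition's published mean/SD truncated to
    [0, 9] (degenerate at the mean when SD is 0), optionally rounded to
    integer scores. ``seed`` may be an int or a Generator.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cond = condition(condition_name)
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    mu, sd = cond.discomfort_mean, cond.discomfort_sd
    if sd == 0:
        x = np.full(n, np.clip(mu, 0.0, 9.0))
    else:
        a, b = (0.0 - mu) / sd, (9.0 - mu) / sd
        x = _stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=n, random_state=rng)
    if integer:
        x = np.clip(np.round(x), 0, 9)
    return x


def generate_skin_profile(
    object_temp_c: float,
    duration_s: float,
    seed,
    ambient_c: float = 28.0,
    tau_s: float = 0.8,
    sensor_tau_ratio: float = 1.15,
    noise_sd_c: float = 0.05,
    fs: float = SKIN_FS,
    label: Optional[str] = None,
) -> SkinProfile:
    """Two-sensor contact-temperature profile at 250 Hz.

    Each sensor starts at ambient (28 C default) and relaxes exponentially
    toward the object temperature; the second sensor is slightly slower
    (``tau * sensor_tau_ratio``). ``tau_s <= 0`` means instantaneous
    equilibration. Gaussian sensor noise with SD ``noise_sd_c`` is added.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n = int(round(duration_s * fs))
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    t = np.arange(n) / fs
    taus = (tau_s, tau_s * sensor_tau_ratio)
    data = np.empty((2, n))
    for i, tau in enumerate(taus):
        if tau <= 0:
            data[i] = object_temp_c
        else:
            data[i] = object_temp_c + (ambient_c - object_temp_c) * np.exp(-t / tau)
    if noise_sd_c > 0:
        data += rng.normal(0.0, noise_sd_c, size=data.shape)
    return SkinProfile(data=data, fs=fs, label=label, object_temp_c=object_temp_c)


def generate_skin_dataset(
    n_per_class: int,
    seed: int,
    duration_s: float = 3.0,
    drift_to_ambient: float = 0.0,
    ambient_c: float = 28.0,
    **profile_kw,
) -> List[SkinProfile]:
    """Labelled skin profiles, object temperatures uniform within each bin.

    ``drift_to_ambient`` emulates objects equilibrating with the room over a
    long recording session: profile ``k`` (in recording order) uses an
    object temperature pulled toward ambient by ``1 - exp(-drift * k)``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    order = []
    for name, low, high in TEMP_BINS:
        for _ in range(n_per_class):
            order.append((name, rng.uniform(low, high)))
    rng.shuffle(order)
    profiles = []
    for k, (name, temp) in enumerate(order):
        if drift_to_ambient > 0:
            temp = ambient_c + (temp - ambient_c) * np.exp(-drift_to_ambient * k)
        profiles.append(
            generate_skin_profile(
                temp, duration_s, rng, ambient_c=ambient_c, label=name, **profile_kw
            )
        )
    return profiles
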