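"""Filtering, epoching, baseline correction, artifact rejection."""

import numpy as np
import pytest

import thermoeeg as te
from thermoeeg.config import PipelineConfig, FilterConfig
from thermoeeg.io import ContinuousRecording
from thermoeeg.preprocessing import (
    FLAGGED_EMG,
    KEPT,
    REJECTED_AMPLITUDE,
    apply_filters,
    baseline_correct,
    extract_epochs,
    load_epochs,
    normalized_cutoffs,
    reject_artifacts,
    reported_cutoffs,
    save_epochs,
)
from thermoeeg.synth import EffectSpec, generate_eeg_session, noiseless_effects
from thermoeeg.paradigm import SessionSpec, StimulusParadigm, generate_paradigm

FS = 512.0


def _rec(data, names=None, events=None):
    names = names or [f"ch{i}" for i in range(data.shape[0])]
    return ContinuousRecording(data, FS, names, events or [])


def _sine(freq, n=8192, amp=1.0):
    t = np.arange(n) / FS
    return amp * np.sin(2 * np.pi * freq * t)


class TestCutoffs:
    def test_reported_convention_matches_printed_values(self):
        low, high = reported_cutoffs(0.5, 70.0, FS)
        assert low == pytest.approx(0.0019, abs=0)
        assert high == pytest.approx(0.273, abs=0)

    def test_exact_fractions(self):
        low, high = normalized_cutoffs(8.0, 12.0, FS)
        assert low == 8 / 256 == 0.03125
        assert high == 12 / 256 == 0.046875

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            normalized_cutoffs(0.5, 300.0, FS)


class TestFilters:
    def test_notch_kills_50hz(self, cfg):
        rec = _rec(_sine(50.0)[None, :])
        out = apply_filters(rec, cfg)
        mid = slice(1024, -1024)  # ignore edge transients
        assert np.std(out.data[0, mid]) < 0.05 * np.std(rec.data[0, mid])

    def test_dc_offset_removed(self, cfg):
        rec = _rec(np.full((1, 8192), 100.0))
        out = apply_filters(rec, cfg)
        assert abs(out.data[0, 2048:-2048].mean()) < 1.0

    def test_passband_10hz_preserved(self, cfg):
        rec = _rec(_sine(10.0)[None, :])
        out = apply_filters(rec, cfg)
        mid = slice(1024, -1024)
        ratio = np.std(out.data[0, mid]) / np.std(rec.data[0, mid])
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_linearity(self, cfg, rng):
        x = rng.normal(0, 10, (2, 4096))
        y = rng.normal(0, 10, (2, 4096))
        fx = apply_filters(_rec(x), cfg).data
        fy = apply_filters(_rec(y), cfg).data
        fxy = apply_filters(_rec(3 * x - 2 * y), cfg).data
        assert np.allclose(fxy, 3 * fx - 2 * fy, atol=1e-8)

    def test_zero_phase_keeps_peak_latency(self, cfg):
        n = 8192
        t = (np.arange(n) - 4096) / FS
        transient = 50 * np.exp(-(t**2) / (2 * 0.05**2))
        out = apply_filters(_rec(transient[None, :]), cfg)
        assert abs(int(np.argmax(out.data[0])) - 4096) <= 1

    def test_causal_option_differs_from_zero_phase(self):
        n = 8192
        t = (np.arange(n) - 4096) / FS
        transient = 50 * np.exp(-(t**2) / (2 * 0.05**2))
        causal = apply_filters(
            _rec(transient[None, :]), FilterConfig(zero_phase=False)
        )
        zero_phase = apply_filters(_rec(transient[None, :]), FilterConfig())
        # zero-phase output stays symmetric about the transient; causal does not
        sym_err = lambda y: np.abs(y[4096 + 1 : 4096 + 512]
                                   - y[4096 - 511 : 4096][::-1]).max()
        assert sym_err(zero_phase.data[0]) < 0.1
        assert sym_err(causal.data[0]) > 1.0

    def test_nonfinite_sample_names_channel(self, cfg):
        data = np.zeros((2, 1024))
        data[1, 5] = np.nan
        with pytest.raises(ValueError, match="channel 1"):
            apply_filters(_rec(data), cfg)


class TestEpoching:
    def test_window_sample_count(self):
        rec = _rec(np.zeros((2, 20480)), events=[(5120, "warm")])
        ep = extract_epochs(rec, (0.0, 3.0))
        assert ep.data.shape == (1, 2, 1536)

    def test_one_epoch_per_event_labels_aligned(self):
        events = [(2048, "warm"), (6144, "hot"), (10240, "cold")]
        rec = _rec(np.zeros((1, 20480)), events=events)
        ep = extract_epochs(rec, (-1.0, 1.0))
        assert ep.n_epochs == 3
        assert list(ep.labels) == ["warm", "hot", "cold"]

    def test_out_of_bounds_event_named(self):
        rec = _rec(np.zeros((1, 4096)), events=[(0, "warm")])
        with pytest.raises(ValueError, match="event 0"):
            extract_epochs(rec, (-3.0, 0.0))

    def test_epoch_dir_round_trip(self, tmp_path):
        rec = _rec(np.arange(4096.0).reshape(2, 2048), events=[(512, "hot")])
        ep = extract_epochs(rec, (0.0, 1.0))
        save_epochs(ep, tmp_path / "ep")
        back = load_epochs(tmp_path / "ep")
        assert np.allclose(back.data, ep.data)
        assert list(back.labels) == list(ep.labels)


class TestBaseline:
    def _epochs(self, data, **kw):
        rec = _rec(data, events=kw.pop("events"))
        return extract_epochs(rec, kw.pop("window"))

    def test_constant_offset_cancels(self):
        data = np.full((1, 8192), 7.5)
        rec = _rec(data, events=[(4096, "warm")])
        stim = extract_epochs(rec, (0.0, 3.0))
        base = extract_epochs(rec, (-3.0, 0.0))
        out = baseline_correct(stim, base)
        assert np.allclose(out.data, 0.0)

    def test_shift_invariance(self, rng):
        raw = rng.normal(0, 5, (1, 8192))
        e1 = extract_epochs(_rec(raw), (0.0, 2.0), events=[(4096, "w")])
        b1 = extract_epochs(_rec(raw), (-2.0, 0.0), events=[(4096, "w")])
        e2 = extract_epochs(_rec(raw + 42.0), (0.0, 2.0), events=[(4096, "w")])
        b2 = extract_epochs(_rec(raw + 42.0), (-2.0, 0.0), events=[(4096, "w")])
        assert np.allclose(
            baseline_correct(e1, b1).data, baseline_correct(e2, b2).data
        )

    def test_ramp_mean_subtraction(self):
        ramp = np.arange(8192.0)[None, :]
        rec = _rec(ramp, events=[(1536, "w")])
        stim = extract_epochs(rec, (0.0, 3.0))
        base = extract_epochs(rec, (-3.0, 0.0))
        out = baseline_correct(stim, base)
        # baseline covers samples 0..1535: mean 767.5
        assert out.data[0, 0, 0] == pytest.approx(1536 - 767.5)

    def test_trial_count_mismatch_rejected(self):
        rec = _rec(np.zeros((1, 8192)), events=[(2048, "w"), (4096, "w")])
        stim = extract_epochs(rec, (0.0, 1.0))
        base = extract_epochs(rec, (-1.0, 0.0)).select([0])
        with pytest.raises(ValueError, match="trials"):
            baseline_correct(stim, base)


class TestRejection:
    def _epochs_from(self, data, events):
        return extract_epochs(_rec(data, events=events), (0.0, 1.0))

    def test_clean_epochs_kept(self, rng):
        data = rng.uniform(-50, 50, (2, 4096))
        ep = self._epochs_from(data, [(512, "w"), (2048, "h")])
        kept, log = reject_artifacts(ep, ep)
        assert kept.n_epochs == 2
        assert log.decisions == [KEPT, KEPT]

    def test_amplitude_excursion_rejected(self):
        data = np.zeros((1, 4096))
        data[0, 2100] = 150.0
        ep = self._epochs_from(data, [(512, "w"), (2048, "h")])
        kept, log = reject_artifacts(ep, ep)
        assert log.decisions == [KEPT, REJECTED_AMPLITUDE]
        assert list(kept.labels) == ["w"]

    def test_emg_burst_flagged_from_raw(self):
        t = np.arange(4096) / FS
        raw = np.zeros((1, 4096))
        burst = 2000.0 * np.sin(2 * np.pi * 120 * t)  # 2 mV at 120 Hz
        env = np.exp(-((t - 4.5) ** 2) / (2 * 0.05**2))
        raw[0] = burst * env
        filtered = np.zeros((1, 4096))  # band-passed data is quiet
        events = [(512, "w"), (2048, "h")]
        ep = self._epochs_from(filtered, events)
        raw_ep = self._epochs_from(raw, events)
        kept, log = reject_artifacts(ep, raw_ep)
        assert log.decisions == [KEPT, FLAGGED_EMG]

    def test_rejection_idempotent(self, rng):
        data = rng.uniform(-80, 80, (2, 8192))
        data[0, 600] = 400.0
        events = [(512, "a"), (2048, "b"), (4096, "c")]
        ep = self._epochs_from(data, events)
        kept, log = reject_artifacts(ep, ep)
        kept2, log2 = reject_artifacts(kept, kept)
        assert kept2.n_epochs == kept.n_epochs
        assert np.array_equal(kept2.data, kept.data)
        assert set(log2.decisions) <= {KEPT}

    def test_generator_ground_truth_bookkeeping(self):
        """On a noise-free background every epoch overlapping an injected
        artifact is rejected with the right criterion, and artifact-free
        epochs are all kept."""
        spec = StimulusParadigm(
            sessions=(SessionSpec("s", tuple(te.CONDITIONS), 4),)
        )
        paradigm = generate_paradigm(spec, 21)
        eff = noiseless_effects(
            peak_amplitude_uv={}, artifact_rate_amplitude=1.0,
            artifact_rate_emg=1.0,
        )
        sess = generate_eeg_session(paradigm, eff, 21)
        window = (0.0, 3.0)
        filtered = apply_filters(sess.recording, PipelineConfig())
        ep = extract_epochs(filtered, window)
        raw_ep = extract_epochs(sess.recording, window)
        kept, log = reject_artifacts(ep, raw_ep, PipelineConfig())
        stim_onsets = sess.events["stim_onset_s"].to_numpy()
        for k, decision in enumerate(log.decisions):
            start, end = stim_onsets[k] + window[0], stim_onsets[k] + window[1]
            inside = sess.artifacts[
                (sess.artifacts.time_s > start + 0.2)
                & (sess.artifacts.time_s < end - 0.2)
            ]
            nearby = sess.artifacts[
                (sess.artifacts.time_s > start - 0.3)
                & (sess.artifacts.time_s < end + 0.3)
            ]
            if len(nearby) == 0:
                assert decision == KEPT
            elif (inside.kind == "amplitude").any():
                assert decision == REJECTED_AMPLITUDE
            elif len(inside) and (inside.kind == "emg").all() and len(nearby) == len(inside):
                assert decision == FLAGGED_EMG
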