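"""End-to-end orchestration: simulate -> preprocess -> spectra -> classify -> stats.

Every stage writes its artifacts as CSV/JSON stamped with the configuration
hash and the seeds used; numbers are serialized with fixed 9-significant-
digit formatting, so re-running with identical inputs and configuration
reproduces byte-identical JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import classification as cls
from . import preprocessing as pre
from . import spectral as spec
from . import stats as st
from .conditions import CONTRALATERAL_CENTRAL, CONDITIONS, Group
from .config import PipelineConfig
from .io import ContinuousRecording, load_recording, save_recording
from .paradigm import StimulusParadigm, day1_paradigm, day2_paradigm, generate_paradigm
from .synth import EffectSpec, SessionData, generate_eeg_session

log = logging.getLogger("thermoeeg")

#: The binary decoding tasks evaluated by default.
DEFAULT_PAIRS: List[Tuple[str, str]] = [
    ("very_hot", "hot"),
    ("very_cold", "cold"),
    ("warm", "cold"),
    ("warm", "hot"),
    ("very_hot", "very_cold"),
]


def _fmt(obj):
    """Recursively normalize floats to 9 significant digits for stable JSON."""
    if isinstance(obj, dict):
        return {k: _fmt(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_fmt(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(f"{float(obj):.9g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _fmt(obj.tolist())
    return obj


def write_result_json(payload: dict, path) -> None:
    """Serialize a result bundle deterministically (sorted keys, fixed floats)."""
    Path(path).write_text(json.dumps(_fmt(payload), indent=1, sort_keys=True) + "\n")


def simulate_sessions(
    outdir,
    seed: int,
    trials_per_condition: int = 10,
    effects: Optional[EffectSpec] = None,
    fmt: str = "edf",
    n_channels: int = 64,
    channel_names: Optional[Sequence[str]] = None,
) -> List[Path]:
    """Generate and write the two-session design; returns recording paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    effects = effects or EffectSpec()
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
    paths = []
    kw = {}
    if channel_names is not None:
        kw = {"n_channels": len(channel_names), "channel_names": tuple(channel_names)}
    elif n_channels != 64:
        raise ValueError("custom n_channels requires channel_names")
    for maker, name, s in (
        (day1_paradigm, "day1", child_seeds[0]),
        (day2_paradigm, "day2", child_seeds[1]),
    ):
        paradigm = generate_paradigm(maker(trials_per_condition, **kw), s)
        session = generate_eeg_session(paradigm, effects, s)
        path = outdir / f"{name}.{fmt}"
        save_recording(session.recording, path)
        session.events.to_csv(outdir / f"{name}_trials.csv", index=False)
        session.artifacts.to_csv(outdir / f"{name}_artifacts.csv", index=False)
        log.info(
            "simulate %s: %d trials, %d channels, seed %d",
            name, len(session.events), session.recording.n_channels, s,
        )
        paths.append(path)
    return paths


def _load_session(path) -> Tuple[ContinuousRecording, Optional[pd.DataFrame]]:
    rec = load_recording(path)
    trials = Path(path).with_name(Path(path).stem + "_trials.csv")
    table = pd.read_csv(trials) if trials.exists() else None
    return rec, table


def preprocess_recording(
    recording: ContinuousRecording, config: PipelineConfig
) -> Dict[str, pre.EpochSet]:
    """Filter and epoch one recording.

    Returns stimulation epochs (first ``epoch.length_ms``), trial-matched
    baseline epochs, baseline-corrected stimulation epochs after artifact
    rejection, the full 30-s stimulation epochs (for crop augmentation),
    and the matching raw (unfiltered) epochs used by the EMG criterion.
    """
    filtered = pre.apply_filters(recording, config)
    length_s = config.epoch.length_ms / 1000.0
    stim = pre.extract_epochs(filtered, (0.0, length_s))
    base = pre.extract_epochs(filtered, config.epoch.baseline)
    raw_stim = pre.extract_epochs(recording, (0.0, length_s))
    corrected = pre.baseline_correct(stim, base)
    kept, rej_log = pre.reject_artifacts(corrected, raw_stim, config)
    log.info(
        "preprocess: %d epochs in, %d kept (%s)",
        corrected.n_epochs, kept.n_epochs,
        {d: rej_log.decisions.count(d) for d in set(rej_log.decisions)},
    )
    full_stim = pre.extract_epochs(filtered, (0.0, 30.0))
    raw_full = pre.extract_epochs(recording, (0.0, 30.0))
    return {
        "stim": stim, "baseline": base, "corrected": corrected,
        "kept": kept, "rejection": rej_log,
        "full_stim": full_stim, "raw_full_stim": raw_full,
    }


def spectral_stage(
    bundle: Dict[str, pre.EpochSet], config: PipelineConfig
) -> Dict[str, object]:
    """Alpha band power, ERD, GFP and peak per condition."""
    stim, base = bundle["stim"], bundle["baseline"]
    band = config.spectral.alpha_band_hz
    out: Dict[str, object] = {"band_hz": list(band)}
    conditions = sorted(set(stim.labels.tolist()))
    per_cond = {}
    for cond in conditions:
        sel = np.flatnonzero(stim.labels == cond)
        s_map = spec.band_power(stim.select(sel), band, config.spectral, cond)
        b_map = spec.band_power(base.select(sel), band, config.spectral, cond)
        erd = spec.erd_index(s_map, b_map)
        evoked = spec.average_epochs(bundle["corrected"], cond) \
            if (bundle["corrected"].labels == cond).any() else None
        entry = {
            "alpha_power": dict(zip(s_map.channel_names, s_map.power)),
            "baseline_power": dict(zip(b_map.channel_names, b_map.power)),
            "erd": dict(zip(s_map.channel_names, erd)),
        }
        if evoked is not None:
            gfp = spec.compute_gfp(evoked, stim.fs)
            peak = spec.detect_peak(
                evoked, stim.fs, (0.0, 1.5), stim.channel_names, t0=stim.window[0]
            )
            entry["gfp_max"] = float(gfp.values.max())
            entry["peak"] = {
                "channel": peak.channel,
                "latency_s": peak.latency_s,
                "amplitude_uv": peak.amplitude_uv,
            }
        per_cond[cond] = entry
    out["conditions"] = per_cond
    return out


def trial_alpha_powers(
    bundle: Dict[str, pre.EpochSet],
    config: PipelineConfig,
    channels: Sequence[str] = tuple(CONTRALATERAL_CENTRAL),
) -> np.ndarray:
    """Per-trial stimulation alpha power averaged over the chosen channels."""
    stim = bundle["stim"]
    chan_idx = [stim.channel_names.index(c) for c in channels]
    vals = []
    for k in range(stim.n_epochs):
        m = spec.band_power(
            stim.select([k]), config.spectral.alpha_band_hz, config.spectral
        )
        vals.append(m.power[chan_idx].mean())
    return np.asarray(vals)


def classify_stage(
    bundles: Sequence[Dict[str, pre.EpochSet]],
    config: PipelineConfig,
    seed: int,
    pairs: Optional[Sequence[Tuple[str, str]]] = None,
) -> Dict[str, object]:
    """Crop-augment 30-s stimulation epochs and decode each class pair."""
    full = _concat_epochs([b["full_stim"] for b in bundles])
    crops = cls.crop_augment(
        full, config.augmentation.window_s, config.augmentation.stride_s
    )
    results = {}
    for pair in pairs or DEFAULT_PAIRS:
        sel = np.flatnonzero(np.isin(crops.labels, pair))
        if len(set(crops.labels[sel].tolist())) < 2:
            continue
        sub = cls.CropSet(
            crops.data[sel], crops.fs, crops.labels[sel], crops.parent_ids[sel],
            crops.offsets[sel], crops.channel_names,
        )
        report = cls.decode_crops(sub, config.classification, seed)
        results[f"{pair[0]}|{pair[1]}"] = {
            "confusion": report.confusion.tolist(),
            "classes": report.classes,
            "fold_baccs": report.fold_baccs,
            "validation_bacc": report.validation_bacc,
            "test_bacc": report.test_bacc,
            "group_aware": report.group_aware,
            "seed": seed,
        }
        log.info(
            "classify %s: val %.3f test %.3f",
            pair, report.validation_bacc, report.test_bacc,
        )
    return results


def _concat_epochs(parts: Sequence[pre.EpochSet]) -> pre.EpochSet:
    offset = 0
    data, labels, parents = [], [], []
    for p in parts:
        data.append(p.data)
        labels.append(p.labels)
        parents.append(p.parent_ids + offset)
        offset += p.n_epochs
    first = parts[0]
    return pre.EpochSet(
        np.concatenate(data), first.fs, np.concatenate(labels),
        np.concatenate(parents), list(first.channel_names), first.window,
    )


def stats_stage(
    alpha_by_condition: Dict[str, np.ndarray],
    ratings_by_condition: Dict[str, np.ndarray],
) -> Dict[str, object]:
    """Normality per condition, NOX-vs-INNO independence, omnibus + post-hoc."""
    out: Dict[str, object] = {"normality": {}}
    for cond, vals in alpha_by_condition.items():
        if len(vals) >= 3 and np.ptp(vals) > 0:
            r = st.normality_test(vals)
            out["normality"][cond] = {"statistic": r.statistic, "pvalue": r.pvalue}
    nox = np.concatenate(
        [v for c, v in alpha_by_condition.items()
         if CONDITIONS[c].group == Group.NOX] or [[]]
    )
    inno = np.concatenate(
        [v for c, v in alpha_by_condition.items()
         if CONDITIONS[c].group == Group.INNO] or [[]]
    )
    if len(nox) >= 2 and len(inno) >= 2:
        r = st.independence_test(nox, inno)
        out["nox_vs_inno"] = {"statistic": r.statistic, "pvalue": r.pvalue}
    names = sorted(alpha_by_condition)
    if len(names) >= 3:
        r = st.kruskal_posthoc([alpha_by_condition[c] for c in names], names)
        out["kruskal"] = {
            "H": r.statistic, "pvalue": r.pvalue,
            "pairwise": {
                f"{a}|{b}": float(r.pairwise.loc[a, b])
                for i, a in enumerate(names) for b in names[i + 1:]
            },
        }
    powers = np.concatenate([alpha_by_condition[c] for c in names])
    rates = np.concatenate([ratings_by_condition[c] for c in names])
    if len(powers) == len(rates) and len(powers) >= 3:
        out["alpha_discomfort_r"] = spec.alpha_discomfort_correlation(powers, rates)
    return out


def run_pipeline(
    config: PipelineConfig,
    inputs: Optional[Sequence] = None,
    outdir=".",
    seed: int = 0,
    trials_per_condition: int = 10,
    effects: Optional[EffectSpec] = None,
    pairs: Optional[Sequence[Tuple[str, str]]] = None,
) -> dict:
    """Run every stage and write the result bundle to ``outdir``.

    ``inputs`` is a list of recording paths (EDF or columnar text, with the
    ``*_trials.csv`` ground-truth tables alongside when available); when
    omitted, the two-session design is simulated first. Returns the result
    dictionary also written to ``results.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if inputs is None:
        inputs = simulate_sessions(
            outdir, seed, trials_per_condition, effects=effects
        )
    bundles, alpha_by_cond, ratings_by_cond = [], {}, {}
    spectral_results = {}
    for path in inputs:
        rec, trials = _load_session(path)
        bundle = preprocess_recording(rec, config)
        bundles.append(bundle)
        spectral_results[Path(path).stem] = spectral_stage(bundle, config)
        powers = trial_alpha_powers(bundle, config)
        labels = bundle["stim"].labels
        for cond in sorted(set(labels.tolist())):
            sel = labels == cond
            alpha_by_cond.setdefault(cond, []).append(powers[sel])
            if trials is not None:
                ratings_by_cond.setdefault(cond, []).append(
                    trials.loc[sel, "rating"].to_numpy(dtype=float)
                )
    alpha_by_cond = {c: np.concatenate(v) for c, v in alpha_by_cond.items()}
    ratings_by_cond = {c: np.concatenate(v) for c, v in ratings_by_cond.items()}

    results = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": seed,
        "inputs": [str(p) for p in inputs],
        "spectral": spectral_results,
        "classification": classify_stage(bundles, config, seed, pairs),
    }
    if ratings_by_cond:
        results["stats"] = stats_stage(alpha_by_cond, ratings_by_cond)
    write_result_json(results, outdir / "results.json")
    for i, b in enumerate(bundles):
        b["rejection"].to_frame().assign(config_hash=config.hash()).to_csv(
            outdir / f"rejection_{Path(inputs[i]).stem}.csv", index=False
        )
    return results


def verify_config_hash(result_path, config: PipelineConfig) -> bool:
    """True when the embedded config hash matches the supplied config."""
    payload = json.loads(Path(result_path).read_text())
    return payload.get("config_hash") == config.hash()
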