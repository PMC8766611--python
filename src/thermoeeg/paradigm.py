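"""Stimulation paradigm: session layout and seeded trial scheduling.

A session delivers a fixed set of conditions, ``trials_per_condition`` trials
each, in pseudorandom order (seeded discrete-uniform draw without replacement
from the multiset of required trials). Every trial is 10 s baseline followed
by 30 s stimulation; recovery breaks separate trials but are not simulated in
the recording, so consecutive trial blocks abut and stimulus onsets fall 10 s
into each 40 s block.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .conditions import CONDITIONS, DAY1_CONDITIONS, DAY2_CONDITIONS, MONTAGE_64


@dataclass(frozen=True)
class TrialLayout:
    """Per-trial timing in seconds."""

    baseline_s: float = 10.0
    stimulation_s: float = 30.0
    recovery_s: float = 120.0
    beep_lead_s: float = 5.0

    @property
    def duration_s(self) -> float:
        """Recorded duration of one trial (baseline + stimulation)."""
        return self.baseline_s + self.stimulation_s


@dataclass(frozen=True)
class SessionSpec:
    session_id: str
    conditions: Tuple[str, ...]
    trials_per_condition: int = 10


@dataclass(frozen=True)
class StimulusParadigm:
    """Experiment layout plus (after scheduling) the concrete trial order.

    ``schedule`` is empty until :func:`generate_paradigm` fills it with one
    ``(onset_s, condition, session_id)`` entry per trial, where ``onset_s`` is
    the trial-block onset within the session recording; stimulation starts
    ``trial_layout.baseline_s`` later.
    """

    sessions: Tuple[SessionSpec, ...]
    trial_layout: TrialLayout = TrialLayout()
    fs: float = 512.0
    n_channels: int = 64
    channel_names: Tuple[str, ...] = tuple(MONTAGE_64)
    schedule: Tuple[Tuple[float, str, str], ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.channel_names) != self.n_channels:
            raise ValueError(
                f"{self.n_channels} channels declared but "
                f"{len(self.channel_names)} names given"
            )
        for sess in self.sessions:
            if not sess.conditions:
                raise ValueError(f"session {sess.session_id!r} has no conditions")
            if sess.trials_per_condition < 1:
                raise ValueError("trials_per_condition must be >= 1")
            for c in sess.conditions:
                if c not in CONDITIONS:
                    raise ValueError(f"unknown condition {c!r}")

    @property
    def n_trials(self) -> int:
        return sum(len(s.conditions) * s.trials_per_condition for s in self.sessions)

    def schedule_frame(self) -> pd.DataFrame:
        """Schedule as a DataFrame (onset_s, condition, session)."""
        return pd.DataFrame(
            list(self.schedule), columns=["onset_s", "condition", "session"]
        )


def day1_paradigm(trials_per_condition: int = 10, **kw) -> StimulusParadigm:
    """First recording session: very hot, hot, warm (30 trials by default)."""
    return StimulusParadigm(
        sessions=(SessionSpec("day1", tuple(DAY1_CONDITIONS), trials_per_condition),),
        **kw,
    )


def day2_paradigm(trials_per_condition: int = 10, **kw) -> StimulusParadigm:
    """Second recording session: very cold, cold (20 trials by default)."""
    return StimulusParadigm(
        sessions=(SessionSpec("day2", tuple(DAY2_CONDITIONS), trials_per_condition),),
        **kw,
    )


def generate_paradigm(config: StimulusParadigm, seed: int) -> StimulusParadigm:
    """Draw the concrete pseudorandom trial schedule for every session.

    Each session's trial order is a seeded uniform shuffle of the multiset
    {condition x trials_per_condition}; trial onsets are spaced one trial
    duration apart starting at 0, with stimulation ``baseline_s`` into each
    block.

    Parameters
    ----------
    config
        Paradigm with at least one session; an existing schedule is replaced.
    seed
        Seed for the shuffle (identical seeds give identical schedules).
    """
    if not config.sessions:
        raise ValueError("paradigm has no sessions")
    rng = np.random.default_rng(seed)
    layout = config.trial_layout
    schedule: List[Tuple[float, str, str]] = []
    for sess in config.sessions:
        order = np.repeat(
            np.arange(len(sess.conditions)), sess.trials_per_condition
        )
        rng.shuffle(order)
        for i, cond_idx in enumerate(order):
            onset = i * layout.duration_s
            schedule.append((onset, sess.conditions[int(cond_idx)], sess.session_id))
    return replace(config, schedule=tuple(schedule))
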