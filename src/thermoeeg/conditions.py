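"""Thermal stimulation conditions, intensity groups, and the electrode montage.

Five thermal stimuli (very cold, cold, warm, hot, very hot) are delivered to
the right hand and cluster behaviorally into three intensity groups:

* ``NOX``  — very intense (very cold, very hot),
* ``MOD``  — moderately intense (cold, hot),
* ``INNO`` — innocuous (warm; room temperature).

Each condition carries the published subjective-discomfort statistics
(0-9 thermal sensation scale, mean +/- SD across subjects) and the stimulator
temperature bin in degrees Celsius. The discomfort ordering
``warm < hot < cold < very_hot < very_cold`` drives every condition-scaled
effect in the synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Tuple


class Group(str, Enum):
    """Stimulus intensity group."""

    NOX = "NOX"
    MOD = "MOD"
    INNO = "INNO"


@dataclass(frozen=True)
class ConditionLabel:
    """One thermal stimulation condition.

    Parameters
    ----------
    name
        One of ``very_cold, cold, warm, hot, very_hot``.
    group
        Intensity group (NOX / MOD / INNO).
    discomfort_mean, discomfort_sd
        Subjective responsivity on the 0-9 thermal sensation scale.
    temp_range_c
        ``(low, high)`` stimulator temperature bin in degrees Celsius.
    """

    name: str
    group: Group
    discomfort_mean: float
    discomfort_sd: float
    temp_range_c: Tuple[float, float]


CONDITIONS: dict[str, ConditionLabel] = {
    "very_cold": ConditionLabel("very_cold", Group.NOX, 6.6, 0.48, (10.0, 14.99)),
    "cold": ConditionLabel("cold", Group.MOD, 4.5, 0.50, (16.0, 24.99)),
    "warm": ConditionLabel("warm", Group.INNO, 2.6, 0.48, (25.0, 33.0)),
    "hot": ConditionLabel("hot", Group.MOD, 3.9, 0.30, (35.0, 40.0)),
    "very_hot": ConditionLabel("very_hot", Group.NOX, 5.9, 0.83, (40.99, 44.99)),
}

#: Conditions ordered cold -> hot (the temperature axis).
ORDER_COLD_TO_HOT = ["very_cold", "cold", "warm", "hot", "very_hot"]

#: Conditions ordered by increasing subjective discomfort.
ORDER_BY_DISCOMFORT = ["warm", "hot", "cold", "very_hot", "very_cold"]

#: Day-1 / day-2 session condition sets of the two-session design.
DAY1_CONDITIONS = ["very_hot", "hot", "warm"]
DAY2_CONDITIONS = ["very_cold", "cold"]

# 64-channel montage, 5% (10-10) system labels, left -> right, front -> back.
MONTAGE_64 = [
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P9", "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8", "P10",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2", "Iz",
]

#: Contralateral-central electrodes (right-hand stimulation -> left hemisphere);
#: the default site of the alpha desynchronization effect.
CONTRALATERAL_CENTRAL = ["C3", "C5", "C1", "CP3", "CP5"]


def condition(name: str) -> ConditionLabel:
    """Look up a condition by name, raising ``KeyError`` with options listed."""
    try:
        return CONDITIONS[name]
    except KeyError:
        raise KeyError(
            f"unknown condition {name!r}; options: {sorted(CONDITIONS)}"
        ) from None
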