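"""Amplitude-threshold pre-identification of maternal artifacts and FM candidates.

Empirically, maternal body movement / laughter / coughing produces peak
amplitudes above 0.1 g, respiration stays below 0.015 g, miscellaneous
background noise sits between 0.06 g and 0.1 g, and fetal-movement
transients fall roughly between 0.015 g and 0.06 g. The gate applies that
taxonomy per window:

* if any of the six axes peaks above A3 = 0.1 g, the whole window is vetoed
  as a characteristic maternal artifact and classification is skipped;
* otherwise each axis is a classifier CANDIDATE iff its peak lies strictly
  inside (A1, A2) = (0.015, 0.06) g; peaks below A1 (breathing) or in
  [A2, A3] (background) contribute a forced 0 bit to the mask fuser.

Peaks equal to a threshold fall into the non-candidate branch (strict
inequalities throughout); these are measure-zero events in practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import ParameterError


class AxisState(str, Enum):
    CANDIDATE = "CANDIDATE"
    SUPPRESSED = "SUPPRESSED"


class GateFlag(str, Enum):
    ARTIFACT = "ARTIFACT"
    PASS = "PASS"


@dataclass(frozen=True)
class GateThresholds:
    """Amplitude bands in g: FM candidates in (a1, a2), artifact veto above a3."""

    a1: float = 0.015
    a2: float = 0.06
    a3: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 < self.a1 < self.a2 < self.a3):
            raise ParameterError(
                f"thresholds must satisfy 0 < A1 < A2 < A3, got "
                f"({self.a1}, {self.a2}, {self.a3})"
            )


@dataclass
class GateOutcome:
    """Per-window gate decision: one flag plus six per-axis states."""

    window_index: int
    per_axis: tuple[AxisState, ...]
    window_flag: GateFlag

    def __post_init__(self) -> None:
        if len(self.per_axis) != 6:
            raise ValueError("per_axis must hold exactly 6 states")
        if self.window_flag is GateFlag.ARTIFACT and any(
            s is not AxisState.SUPPRESSED for s in self.per_axis
        ):
            raise ValueError("an ARTIFACT window must suppress every axis")

    @property
    def candidate_axes(self) -> list[int]:
        return [i for i, s in enumerate(self.per_axis) if s is AxisState.CANDIDATE]


def peak_amplitude(samples: np.ndarray) -> float:
    """Peak absolute amplitude of a (preprocessed) window, in g."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        return 0.0
    return float(np.max(np.abs(x)))


def gate_window(peaks, th: GateThresholds = GateThresholds(),
                window_index: int = 0) -> GateOutcome:
    """Apply the amplitude taxonomy to the six per-axis peak amplitudes.

    Any peak above ``th.a3`` vetoes the whole window (ARTIFACT, all axes
    suppressed). Otherwise the window passes and an axis is CANDIDATE iff
    its peak lies strictly inside (a1, a2).
    """
    p = np.asarray(peaks, dtype=float)
    if p.shape != (6,):
        raise ParameterError(f"expected 6 per-axis peaks, got shape {p.shape}")
    if np.any(p < 0):
        raise ParameterError("peak amplitudes must be non-negative")
    if np.any(p > th.a3):
        return GateOutcome(window_index, (AxisState.SUPPRESSED,) * 6, GateFlag.ARTIFACT)
    states = tuple(
        AxisState.CANDIDATE if th.a1 < v < th.a2 else AxisState.SUPPRESSED
        for v in p
    )
    return GateOutcome(window_index, states, GateFlag.PASS)
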