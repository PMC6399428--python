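"""Shared domain containers for the sleep-state FC pipeline.

The unit of analysis is a subject's ROI-by-time BOLD matrix together with
its six realignment (motion) parameters, a respiration trace, and a
per-volume sleep-state labeling derived from breathing rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class State(str, Enum):
    """Sleep-like brain state under urethane anesthesia."""

    REM_LIKE = "REM_LIKE"
    NREM_LIKE = "NREM_LIKE"
    UNLABELED = "UNLABELED"
    WHOLE_SCAN = "WHOLE_SCAN"  # tag for state-agnostic connectivity


# integer codes used in label vectors
NREM_CODE = 0
REM_CODE = 1
UNLABELED_CODE = -1

_STATE_TO_CODE = {State.NREM_LIKE: NREM_CODE, State.REM_LIKE: REM_CODE,
                  State.UNLABELED: UNLABELED_CODE}
_CODE_TO_STATE = {v: k for k, v in _STATE_TO_CODE.items()}


def state_to_code(state: State) -> int:
    return _STATE_TO_CODE[State(state)]


def code_to_state(code: int) -> State:
    return _CODE_TO_STATE[int(code)]


@dataclass
class RoiTimeSeriesSet:
    """T x R matrix of BOLD values with repetition time and ROI names."""

    values: np.ndarray          # shape (T, R)
    tr_seconds: float
    roi_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ROI time series must be a 2-D (T x R) matrix")
        t, r = self.values.shape
        if t < 2 or r < 2:
            raise ValueError(f"need T >= 2 and R >= 2, got T={t}, R={r}")
        if len(self.roi_labels) != r:
            raise ValueError(
                f"{len(self.roi_labels)} ROI labels for {r} columns")
        if not np.isfinite(self.values).all():
            raise ValueError("ROI time series contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass
class MotionParams:
    """T x 6 realignment parameters (3 translations, 3 rotations)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 6:
            raise ValueError(
                f"motion parameters must have exactly 6 columns, got shape "
                f"{self.values.shape}")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]


@dataclass
class RespirationTrace:
    """Respiration waveform sampled at a fixed rate (arbitrary units)."""

    time_s: np.ndarray
    signal: np.ndarray
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_s.shape != self.signal.shape or self.time_s.ndim != 1:
            raise ValueError("time and signal must be 1-D and equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("sample times must be strictly increasing")

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])


@dataclass
class BreathingRateSeries:
    """Per-BOLD-volume breathing rate in breaths/min."""

    rates_bpm: np.ndarray
    tr_seconds: float
    window_s: float

    def __post_init__(self) -> None:
        self.rates_bpm = np.asarray(self.rates_bpm, dtype=float)
        if self.rates_bpm.ndim != 1:
            raise ValueError("rates must be 1-D")
        if np.any(~np.isfinite(self.rates_bpm)):
            raise ValueError("rates contain non-finite values")
        if np.any(self.rates_bpm <= 0) or np.any(self.rates_bpm >= 300):
            raise ValueError("rates must lie in (0, 300) breaths/min")

    @property
    def n_volumes(self) -> int:
        return self.rates_bpm.size


@dataclass
class StateLabels:
    """Per-volume state assignment driving windowed connectivity."""

    codes: np.ndarray           # int8, values in {-1, 0, 1}
    tr_seconds: float

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 1:
            raise ValueError("labels must be 1-D")
        bad = set(np.unique(self.codes)) - {NREM_CODE, REM_CODE,
                                            UNLABELED_CODE}
        if bad:
            raise ValueError(f"unknown label codes: {sorted(bad)}")

    @property
    def n_volumes(self) -> int:
        return self.codes.size

    def count(self, state: State) -> int:
        return int(np.sum(self.codes == state_to_code(state)))

    @property
    def n_transitions(self) -> int:
        """Number of REM<->NREM switches (unlabeled stretches ignored)."""
        labeled = self.codes[self.codes != UNLABELED_CODE]
        if labeled.size < 2:
            return 0
        return int(np.sum(np.diff(labeled.astype(int)) != 0))

    def runs(self) -> list[tuple[int, int, State]]:
        """Maximal same-label runs as (start, length, state) triples."""
        out: list[tuple[int, int, State]] = []
        if self.codes.size == 0:
            return out
        change = np.flatnonzero(np.diff(self.codes.astype(int)) != 0)
        starts = np.concatenate([[0], change + 1])
        ends = np.concatenate([change + 1, [self.codes.size]])
        for s, e in zip(starts, ends):
            out.append((int(s), int(e - s), code_to_state(self.codes[s])))
        return out


@dataclass
class SubjectRecord:
    """One cohort member: identifiers plus in-memory data."""

    subject_id: str
    group: str                  # "control" | "lesion"
    roi_ts: RoiTimeSeriesSet | None = None
    motion: MotionParams | None = None
    respiration: RespirationTrace | None = None
    labels: StateLabels | None = None
    extra: dict = field(default_factory=dict)
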