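"""Core in-memory containers shared across the pipeline.

Continuous multichannel recordings and epoched data are kept as plain
NumPy arrays with explicit channel-label and time-axis metadata, so every
processing step can state its contract in physical units (microvolts,
milliseconds) rather than array indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

Side = Literal["left", "right"]
Task = Literal["atb", "viewing"]

#: The three emotional-pair conditions of the attentional-bias task.
COMBINATIONS = ("angry-neutral", "angry-happy", "happy-neutral")

#: Passive-viewing expressions.
EXPRESSIONS = ("angry", "happy", "neutral")

#: Which member of each pair carries the higher arousal rating.
HIGH_AROUSAL = {
    "angry-neutral": "angry",
    "angry-happy": "angry",
    "happy-neutral": "happy",
}
LOW_AROUSAL = {
    "angry-neutral": "neutral",
    "angry-happy": "happy",
    "happy-neutral": "neutral",
}


def hemisphere_of(label: str) -> str:
    """Hemisphere of a 10-20 electrode label.

    Odd trailing numbers are left-hemisphere sites, even numbers right,
    'z' labels midline.
    """
    tail = label.strip()
    if tail[-1].lower() == "z":
        return "midline"
    digits = ""
    for ch in reversed(tail):
        if ch.isdigit():
            digits = ch + digits
        else:
            break
    if not digits:
        raise ValueError(f"cannot parse hemisphere from label {label!r}")
    return "left" if int(digits) % 2 == 1 else "right"


@dataclass
class TrialCondition:
    """Condition metadata for one trial.

    For attentional-bias (atb) trials, ``freq_assignment`` maps each
    hemifield to its flicker frequency and ``side_of_higher_arousal``
    names the hemifield showing the higher-arousal face of the pair.
    Viewing trials carry a single ``expression``.
    """

    task: Task
    trial_id: int
    onset_sample: int
    combination: str | None = None
    side_of_higher_arousal: Side | None = None
    freq_assignment: dict[str, float] | None = None
    expression: str | None = None

    def __post_init__(self) -> None:
        if self.task == "atb":
            if self.combination not in COMBINATIONS:
                raise ValueError(f"unknown combination {self.combination!r}")
            if self.side_of_higher_arousal not in ("left", "right"):
                raise ValueError("atb trial needs side_of_higher_arousal")
            fa = self.freq_assignment
            if fa is None or set(fa) != {"left", "right"} or fa["left"] == fa["right"]:
                raise ValueError(
                    "atb trial needs freq_assignment mapping the two sides "
                    "to two distinct frequencies"
                )
        elif self.task == "viewing":
            if self.expression not in EXPRESSIONS:
                raise ValueError(f"unknown expression {self.expression!r}")
        else:
            raise ValueError(f"unknown task {self.task!r}")


@dataclass
class ContinuousRecording:
    """Continuous multichannel EEG in microvolts.

    ``data`` is channels x samples; ``events`` holds (onset_sample,
    trial_id) pairs in temporal order.
    """

    channel_labels: list[str]
    sample_rate: float
    data: np.ndarray
    events: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("duplicate channel labels")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ValueError("data must be channels x samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite samples in recording")
        n = self.data.shape[1]
        for onset, _ in self.events:
            if not 0 <= onset < n:
                raise ValueError(f"event onset {onset} outside recording")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, label: str) -> int:
        return self.channel_labels.index(label)

    def copy_with(self, data: np.ndarray) -> "ContinuousRecording":
        return replace(self, data=data)


@dataclass
class EpochSet:
    """Epoched EEG: trials x channels x samples on a millisecond axis.

    ``rejected`` marks trials excluded from analysis; ``rejection_reasons``
    records why (empty string for retained trials). ``reference`` records
    the referencing state of the data.
    """

    data: np.ndarray
    time_ms: np.ndarray
    channel_labels: list[str]
    sample_rate: float
    conditions: list[TrialCondition]
    rejected: np.ndarray
    rejection_reasons: list[str] = field(default_factory=list)
    reference: str = "none"
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.rejected = np.asarray(self.rejected, dtype=bool)
        n_trials, n_ch, n_samp = self.data.shape
        if np.any(np.diff(self.time_ms) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if len(self.time_ms) != n_samp:
            raise ValueError("time axis length mismatch")
        if len(self.channel_labels) != n_ch:
            raise ValueError("channel label count mismatch")
        if len(self.conditions) != n_trials or len(self.rejected) != n_trials:
            raise ValueError("per-trial metadata length mismatch")
        if not self.rejection_reasons:
            self.rejection_reasons = [""] * n_trials

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def time_mask(self, window_ms: tuple[float, float]) -> np.ndarray:
        """Boolean sample mask for a half-open [t0, t1) window in ms."""
        t0, t1 = window_ms
        return (self.time_ms >= t0) & (self.time_ms < t1)

    def channel_indices(self, labels) -> np.ndarray:
        missing = [l for l in labels if l not in self.channel_labels]
        if missing:
            raise KeyError(f"channels not in montage: {missing}")
        return np.array([self.channel_labels.index(l) for l in labels])

    def copy_with(self, data: np.ndarray, **kw) -> "EpochSet":
        return replace(self, data=data, **kw)
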