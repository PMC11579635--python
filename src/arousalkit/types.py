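"""Shared domain types for the arousal-dynamics pipeline.

All time is expressed in seconds from recording start; epochs are
half-open intervals ``[k*epoch_s, (k+1)*epoch_s)`` with 0-based indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "ArousalSeries",
    "EpochGrid",
    "VocalEvent",
    "DayRecording",
    "StillFaceRecord",
]


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the asymmetric mean-reversion process.

    ``beta_pos`` applies when the state is above ``mu`` (down-regulation),
    ``beta_neg`` when it is below (up-regulation). ``sigma`` is the noise
    scale per epoch step (one standard-normal draw per epoch).
    """

    beta_pos: float
    beta_neg: float
    mu: float = 0.0
    sigma: float = 1.0
    epoch_s: float = 60.0

    def __post_init__(self) -> None:
        vals = (self.beta_pos, self.beta_neg, self.mu, self.sigma, self.epoch_s)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("ModelParams fields must be finite")
        if not (0.0 <= self.beta_pos <= 1.0 and 0.0 <= self.beta_neg <= 1.0):
            raise ValueError("beta_pos and beta_neg must lie in [0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be positive")


@dataclass
class ArousalSeries:
    """Uniformly sampled composite arousal with a validity mask."""

    participant_id: str
    t0_s: float
    dt_s: float
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if self.values.shape != self.valid.shape or self.values.ndim != 1:
            raise ValueError("values and valid must be 1-D arrays of equal length")
        if not np.all(np.isfinite(self.values[self.valid])):
            raise ValueError("values must be finite wherever valid")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + self.dt_s * np.arange(self.values.size)

    def copy(self) -> "ArousalSeries":
        return replace(self, values=self.values.copy(), valid=self.valid.copy())


@dataclass
class EpochGrid:
    """Arousal down-sampled to one value per epoch of duration ``epoch_s``."""

    epoch_s: float
    values: np.ndarray
    valid: np.ndarray
    coverage: np.ndarray
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.coverage = np.asarray(self.coverage, dtype=float)
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be positive")
        if np.any((self.coverage < 0) | (self.coverage > 1)):
            raise ValueError("coverage must lie in [0, 1]")

    def __len__(self) -> int:
        return self.values.size


#: morphological categories collapsed to speech-like vocalizations
SPEECH_LIKE_TYPES = (
    "quasi-resonant vowel",
    "fully resonant vowel",
    "marginal syllable",
    "canonical syllable",
)
#: categories excluded from analysis due to rarity
EXCLUDED_TYPES = ("laugh", "squeal", "growl")


@dataclass(frozen=True)
class VocalEvent:
    """One timed vocalization (infant or adult) with coding."""

    participant_id: str
    time_s: float
    speaker: str  # "infant" | "adult"
    morph_type: str
    affect: Optional[int] = None  # 1 (fussy) .. 5 (happy), infant only
    intensity: Optional[int] = None  # 1 (mild) .. 5 (intense), infant only
    vclass: Optional[str] = None  # "cry" | "speech_like" | "excluded"

    def __post_init__(self) -> None:
        if self.speaker not in ("infant", "adult"):
            raise ValueError(f"unknown speaker {self.speaker!r}")
        if self.speaker == "infant":
            for name in ("affect", "intensity"):
                v = getattr(self, name)
                if v is not None and v not in (1, 2, 3, 4, 5):
                    raise ValueError(f"{name} must be an integer in 1..5, got {v}")


@dataclass
class DayRecording:
    """All channels of one simulated day-long home recording."""

    arousal: ArousalSeries
    beat_times_s: np.ndarray
    rr_ms: np.ndarray
    movement_times_s: np.ndarray
    movement: np.ndarray
    home_mask: np.ndarray
    awake_mask: np.ndarray
    infant_events: list
    adult_events: list
    audio_sample_windows: list  # list of (start_s, end_s)
    ground_truth: dict = field(default_factory=dict)


STILLFACE_PHASES = ("play1", "still", "play2")


@dataclass
class StillFaceRecord:
    """Still-face session coded in ordered 5-s bins."""

    participant_id: str
    phase: np.ndarray  # str per bin, protocol order play1 -> still -> play2
    behavior_count: np.ndarray  # non-negative ints
    affect: np.ndarray  # ints 1..5
    bin_s: float = 5.0

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=object)
        self.behavior_count = np.asarray(self.behavior_count, dtype=int)
        self.affect = np.asarray(self.affect, dtype=int)
        n = self.phase.size
        if not (self.behavior_count.size == n == self.affect.size):
            raise ValueError("phase, behavior_count and affect must align")
        if np.any(self.behavior_count < 0):
            raise ValueError("behavior_count must be non-negative")
        if np.any((self.affect < 1) | (self.affect > 5)):
            raise ValueError("affect must be in 1..5")
        order = [p for p, _ in _group_runs(self.phase)]
        if order != [p for p in STILLFACE_PHASES if p in set(order)]:
            raise ValueError("phases must follow protocol order play1, still, play2")

    def __len__(self) -> int:
        return self.phase.size


def _group_runs(labels: Sequence) -> list:
    """Collapse a label sequence into (label, run_length) pairs."""
    out = []
    for lab in labels:
        if out and out[-1][0] == lab:
            out[-1][1] += 1
        else:
            out.append([lab, 1])
    return [(a, b) for a, b in out]
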