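"""Shared data containers for the conversation-analysis pipeline.

The pipeline's stages exchange a small set of typed objects:

* :class:`FrameTrack` — per-frame volume / pitch / voiced time series for one
  conversation (the privacy-preserving representation: no waveform content).
* :class:`DiarizedSegment` — a contiguous time interval labelled with one of
  the four volume regimes (clothing noise, participant, other speaker,
  silence).
* :class:`ConversationFeatures` — one row of conversation-level predictors.
* :class:`ConversationRecord` — everything known about one conversation.
* :class:`MixedModelFit` — the fitted two-level random-intercept model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Role labels in descending order of typical frame volume.  The loudest
#: regime is the phone rubbing against clothing, then the participant (the
#: person carrying the phone), then other speakers further from the
#: microphone, then silence.
ROLE_ORDER = ("clothing_noise", "participant", "other", "silence")

#: Roles that count as voiced speech for feature extraction.
SPEECH_ROLES = ("participant", "other")

#: Volume floor (dB) used for digitally silent frames so every frame has a
#: finite volume.
SILENCE_FLOOR_DB = -100.0


class ConfigurationError(ValueError):
    """A configuration field is invalid; the message names the field."""


class DataError(ValueError):
    """Input data violate a stage's preconditions."""


@dataclass
class FrameTrack:
    """Per-frame acoustic summary of one conversation.

    ``pitch_hz`` is NaN wherever no pitch is defined (unvoiced or aperiodic
    frames); ``periodicity`` (optional) is the normalized autocorrelation
    peak used as voicing evidence.
    """

    conversation_id: str
    frame_hop_s: float
    t_s: np.ndarray
    volume_db: np.ndarray
    pitch_hz: np.ndarray
    voiced: np.ndarray
    periodicity: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.volume_db = np.asarray(self.volume_db, dtype=float)
        self.pitch_hz = np.asarray(self.pitch_hz, dtype=float)
        self.voiced = np.asarray(self.voiced, dtype=bool)
        n = len(self.t_s)
        if not (len(self.volume_db) == len(self.pitch_hz) == len(self.voiced) == n):
            raise DataError("FrameTrack arrays must have equal length")
        if n == 0:
            raise DataError("FrameTrack must contain at least one frame")
        if not np.all(np.isfinite(self.volume_db)):
            raise DataError("volume_db must be finite for every frame")
        if n > 1 and not np.all(np.diff(self.t_s) > 0):
            raise DataError("t_s must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.t_s)

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0] + self.frame_hop_s)


@dataclass(frozen=True)
class DiarizedSegment:
    """A maximal run of frames sharing one role."""

    start_s: float
    end_s: float
    role: str

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise DataError(
                f"segment end ({self.end_s}) must exceed start ({self.start_s})"
            )
        if self.role not in ROLE_ORDER:
            raise DataError(f"unknown role {self.role!r}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def validate_segments(segments: list[DiarizedSegment], *, tol: float = 1e-9) -> None:
    """Check contiguity, ordering and maximal-run structure of a segment list."""
    if not segments:
        raise DataError("segment list is empty")
    for a, b in zip(segments, segments[1:]):
        if abs(b.start_s - a.end_s) > tol:
            raise DataError(f"segments not contiguous at t={a.end_s}")
        if b.role == a.role:
            raise DataError(f"adjacent segments share role {a.role!r} at t={a.end_s}")


@dataclass
class ConversationFeatures:
    """The conversation-level predictors used by the enjoyment model.

    ``pitch_mean_hz`` / ``pitch_sd_hz`` are NaN when no participant frame
    carries a pitch estimate (absent, never silently zero).
    """

    conversation_id: str
    length_min: float
    pct_speaking: float
    turn_count: int
    turn_rate_per_min: float
    vol_mean_db: float
    vol_sd_db: float
    pitch_mean_hz: float
    pitch_sd_hz: float

    def as_dict(self) -> dict:
        return {
            "conversation_id": self.conversation_id,
            "length_min": self.length_min,
            "pct_speaking": self.pct_speaking,
            "turn_count": self.turn_count,
            "turn_rate_per_min": self.turn_rate_per_min,
            "vol_mean_db": self.vol_mean_db,
            "vol_sd_db": self.vol_sd_db,
            "pitch_mean_hz": self.pitch_mean_hz,
            "pitch_sd_hz": self.pitch_sd_hz,
        }


@dataclass
class ConversationRecord:
    conversation_id: str
    participant_id: str
    segments: list[DiarizedSegment] = field(default_factory=list)
    features: Optional[ConversationFeatures] = None
    rating: Optional[float] = None
    tie_type: Optional[str] = None
    qc_flags: list[str] = field(default_factory=list)

    @property
    def qc_pass(self) -> bool:
        return not self.qc_flags


@dataclass
class FixedEffect:
    name: str
    beta: float
    se: float
    t: float
    df: float
    p: float


@dataclass
class MixedModelFit:
    """Two-level random-intercept linear model fit.

    Conversations are level 1, persons level 2; fixed effects are reported
    on the z-scored predictor scale.
    """

    fixed_effects: dict[str, FixedEffect]
    intercept: FixedEffect
    random_intercept_var: float
    residual_var: float
    n_obs: int
    n_groups: int
    converged: bool
    method: str = "reml"
    singular: bool = False

    def as_dict(self) -> dict:
        return {
            "fixed_effects": {
                k: vars(v) for k, v in self.fixed_effects.items()
            },
            "intercept": vars(self.intercept),
            "random_intercept_var": self.random_intercept_var,
            "residual_var": self.residual_var,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "converged": self.converged,
            "method": self.method,
            "singular": self.singular,
        }
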