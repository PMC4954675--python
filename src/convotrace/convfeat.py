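"""Conversation-level feature extraction.

From the diarized, smoothed, trailing-silence-trimmed segments (plus the
frame track for acoustics) this module computes the predictors of the
enjoyment model:

* conversation length (minutes; internal silence counts, trailing does not),
* percentage of time the participant spoke (of conversation length),
* turn-taking rate (maximal voiced runs — participant or other — per
  minute; a participant turn, a partner turn and another participant turn
  count as 3 turns),
* mean and SD of the participant's frame volume (dB) and pitch (Hz).

Acoustic statistics pool frames inside participant-role segments
(frame-weighted by default; segment-mean weighting available), using only
frames that carry a pitch estimate for the pitch statistics.  Clothing-noise
frames never contribute: the role itself excludes them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    ConversationFeatures,
    DataError,
    DiarizedSegment,
    FrameTrack,
    SPEECH_ROLES,
)

__all__ = [
    "FeatureConfig",
    "conversation_length",
    "pct_speaking",
    "turn_rate",
    "participant_acoustics",
    "extract_features",
    "features_frame",
]


@dataclass(frozen=True)
class FeatureConfig:
    sd_ddof: int = 1  # sample SD by default
    pooling: str = "frame"  # "frame" or "segment" weighting


def conversation_length(segments: list[DiarizedSegment]) -> float:
    """Span of the (trimmed) conversation in minutes."""
    if not segments:
        raise DataError("empty segment list")
    return (segments[-1].end_s - segments[0].start_s) / 60.0


def pct_speaking(segments: list[DiarizedSegment]) -> float:
    """Participant speaking time as a percentage of conversation length."""
    length_s = conversation_length(segments) * 60.0
    if length_s <= 0:
        raise DataError("zero-length conversation")
    spoke = sum(s.duration_s for s in segments if s.role == "participant")
    return 100.0 * spoke / length_s


def turn_rate(segments: list[DiarizedSegment]) -> tuple[int, float]:
    """(turn count, turns per minute): voiced segments of either speaker."""
    if not segments:
        raise DataError("empty segment list")
    count = sum(1 for s in segments if s.role in SPEECH_ROLES)
    return count, count / conversation_length(segments)


def _sd(x: np.ndarray, ddof: int) -> float:
    if len(x) <= ddof:
        return float("nan")
    return float(np.std(x, ddof=ddof))


def participant_acoustics(track: FrameTrack,
                          segments: list[DiarizedSegment],
                          config: FeatureConfig = FeatureConfig(),
                          ) -> tuple[float, float, float, float]:
    """(vol_mean, vol_sd, pitch_mean, pitch_sd) over participant frames.

    Returns NaN statistics (absent, never zero) when no frame falls inside
    a participant segment, and NaN pitch statistics when no such frame
    carries a pitch estimate.
    """
    in_part = np.zeros(track.n_frames, dtype=bool)
    for s in segments:
        if s.role == "participant":
            in_part |= (track.t_s >= s.start_s - 1e-9) & \
                       (track.t_s < s.end_s - 1e-9)
    if not in_part.any():
        return (float("nan"),) * 4

    if config.pooling == "segment":
        vms, vss, pms, pss = [], [], [], []
        for s in segments:
            if s.role != "participant":
                continue
            m = (track.t_s >= s.start_s - 1e-9) & (track.t_s < s.end_s - 1e-9)
            if not m.any():
                continue
            vms.append(float(np.mean(track.volume_db[m])))
            pv = track.pitch_hz[m]
            pv = pv[~np.isnan(pv)]
            if len(pv):
                pms.append(float(np.mean(pv)))
        vol = np.array(vms)
        pit = np.array(pms)
    else:
        vol = track.volume_db[in_part]
        pit = track.pitch_hz[in_part]
        pit = pit[~np.isnan(pit)]

    vol_mean = float(np.mean(vol))
    vol_sd = _sd(vol, config.sd_ddof)
    if len(pit) == 0:
        return vol_mean, vol_sd, float("nan"), float("nan")
    return vol_mean, vol_sd, float(np.mean(pit)), _sd(pit, config.sd_ddof)


def extract_features(track: FrameTrack,
                     segments: list[DiarizedSegment],
                     config: FeatureConfig = FeatureConfig(),
                     ) -> ConversationFeatures:
    """All conversation-level features for one diarized conversation."""
    length = conversation_length(segments)
    pct = pct_speaking(segments)
    count, rate = turn_rate(segments)
    vm, vs, pm, ps = participant_acoustics(track, segments, config)
    return ConversationFeatures(
        conversation_id=track.conversation_id,
        length_min=length, pct_speaking=pct,
        turn_count=count, turn_rate_per_min=rate,
        vol_mean_db=vm, vol_sd_db=vs,
        pitch_mean_hz=pm, pitch_sd_hz=ps,
    )


def features_frame(features: list[ConversationFeatures]) -> pd.DataFrame:
    """Stack per-conversation features into the features.csv layout."""
    return pd.DataFrame([f.as_dict() for f in features])
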