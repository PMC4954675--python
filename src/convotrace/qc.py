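"""Quality control: conversation exclusion rules and the participant filter.

Five conversation-level rules guard against corrupted files and failed
diarization, evaluated simultaneously against thresholds computed on the
full pre-exclusion batch (single pass, no iterative re-trimming):

* ``negative_speaking_time`` — computed speaking time below zero.  Our own
  pipeline cannot produce this (it signalled file corruption upstream in
  the original study); the rule guards imported external feature tables.
* ``no_nonparticipant_time`` — the participant was speaking the entire
  time (speaking percentage >= 100), i.e. diarization found no partner.
* ``turn_rate_gt_3sd`` — turn-taking rate more than 3 SDs above the batch
  mean.
* ``volume_gt_3sd`` — average participant volume more than 3 SDs above the
  batch mean.
* ``pitch_gt_255`` — average participant pitch above 255 Hz, the top of
  the typical adult range.

Participants with fewer than three retained conversations are then dropped,
since a two-level model needs a practical minimum of three observations per
person.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import DataError

__all__ = ["QCConfig", "QCReport", "apply_exclusion_rules",
           "participant_filter", "run_qc"]

RULES = ("negative_speaking_time", "no_nonparticipant_time",
         "turn_rate_gt_3sd", "volume_gt_3sd", "pitch_gt_255")

_REQUIRED = ("conversation_id", "pct_speaking", "turn_rate_per_min",
             "vol_mean_db", "pitch_mean_hz")


@dataclass(frozen=True)
class QCConfig:
    pitch_max_hz: float = 255.0
    sd_mult: float = 3.0
    min_conversations: int = 3


@dataclass
class QCReport:
    """Auditable record of what was excluded and why."""

    flags: pd.DataFrame  # one boolean column per rule, indexed like input
    rule_counts: dict = field(default_factory=dict)
    n_input: int = 0
    n_excluded: int = 0
    thresholds_used: dict = field(default_factory=dict)
    participants_dropped: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "rule_counts": self.rule_counts,
            "n_input": self.n_input,
            "n_excluded": self.n_excluded,
            "thresholds_used": self.thresholds_used,
            "participants_dropped": self.participants_dropped,
        }


def apply_exclusion_rules(features: pd.DataFrame,
                          config: QCConfig = QCConfig(),
                          frozen_thresholds: dict | None = None,
                          ) -> tuple[pd.DataFrame, QCReport]:
    """Flag and drop conversations violating any of the five rules.

    Batch-relative thresholds (the 3 SD rules) come from the full
    pre-exclusion table; passing ``frozen_thresholds`` (a previous report's
    ``thresholds_used``) re-applies historical cutoffs instead, which makes
    the operation idempotent on its own output.
    """
    if features.empty:
        raise DataError("features table is empty")
    missing = [c for c in _REQUIRED if c not in features.columns]
    if missing:
        raise DataError(f"features table lacks columns: {missing}")

    if frozen_thresholds is None:
        turn = features["turn_rate_per_min"].to_numpy(dtype=float)
        vol = features["vol_mean_db"].to_numpy(dtype=float)
        thresholds = {
            "turn_rate_max": float(np.nanmean(turn)
                                   + config.sd_mult * np.nanstd(turn, ddof=1)),
            "volume_max": float(np.nanmean(vol)
                                + config.sd_mult * np.nanstd(vol, ddof=1)),
            "pitch_max_hz": config.pitch_max_hz,
        }
    else:
        thresholds = dict(frozen_thresholds)

    pct = features["pct_speaking"].to_numpy(dtype=float)
    flags = pd.DataFrame({
        "negative_speaking_time": pct < 0,
        "no_nonparticipant_time": pct >= 100.0,
        "turn_rate_gt_3sd": features["turn_rate_per_min"].to_numpy(dtype=float)
        > thresholds["turn_rate_max"],
        "volume_gt_3sd": features["vol_mean_db"].to_numpy(dtype=float)
        > thresholds["volume_max"],
        "pitch_gt_255": features["pitch_mean_hz"].to_numpy(dtype=float)
        > thresholds["pitch_max_hz"],
    }, index=features.index)

    excluded = flags.any(axis=1)
    report = QCReport(
        flags=flags,
        rule_counts={r: int(flags[r].sum()) for r in RULES},
        n_input=len(features),
        n_excluded=int(excluded.sum()),
        thresholds_used=thresholds,
    )
    return features.loc[~excluded].copy(), report


def participant_filter(features: pd.DataFrame,
                       min_conversations: int = 3,
                       participant_col: str = "participant_id",
                       ) -> tuple[pd.DataFrame, list]:
    """Drop participants with fewer than ``min_conversations`` retained
    conversations (boundary inclusive: exactly the minimum is kept)."""
    if participant_col not in features.columns:
        raise DataError(f"features table lacks column {participant_col!r}")
    counts = features[participant_col].value_counts()
    dropped = [{"participant_id": str(p), "n_conversations": int(c),
                "reason": f"fewer than {min_conversations} conversations"}
               for p, c in counts.items() if c < min_conversations]
    keep = counts[counts >= min_conversations].index
    return features[features[participant_col].isin(keep)].copy(), dropped


def run_qc(features: pd.DataFrame,
           config: QCConfig = QCConfig(),
           ) -> tuple[pd.DataFrame, QCReport]:
    """Conversation rules, then the participant minimum-count filter."""
    retained, report = apply_exclusion_rules(features, config)
    retained, dropped = participant_filter(retained,
                                           config.min_conversations)
    report.participants_dropped = dropped
    return retained, report
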