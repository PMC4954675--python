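"""Synthetic conversation generator.

The study data this pipeline targets — frame-level volume/pitch traces of
everyday conversations recorded by a phone app, plus post-conversation
enjoyment ratings — were never deposited (by design: only privacy-preserving
features ever left the phone).  This module generates datasets with the same
statistical structure, so every downstream stage (voicing, diarization,
feature extraction, QC, mixed-model inference) is testable end to end:

* two-speaker alternating turn structure with optional silence gaps and a
  fixed trailing-silence block the app used to detect conversation end;
* four frame-volume regimes, loudest to quietest: phone-against-clothing
  noise, the participant (closest to the microphone), other speakers, and
  silence;
* participant fundamental frequency (F0) with person-level means in the
  adult range (92-253 Hz);
* enjoyment ratings from a two-level (conversation-within-person) linear
  model with a standardized speaking-percentage effect of -0.19 and scale
  descriptives mean 4.31, SD 1.25 on a 1-7 item.

Everything is deterministic given ``GeneratorConfig.seed``.  A ground-truth
table stores the true segments, true features and true coefficients so that
recovery can be measured exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import (
    ConfigurationError,
    DataError,
    DiarizedSegment,
    FrameTrack,
    ROLE_ORDER,
    SPEECH_ROLES,
)

__all__ = [
    "DistributionSpec",
    "ParticipantProfile",
    "GeneratorConfig",
    "GenerationError",
    "sample_participant_profile",
    "sample_turn_sequence",
    "render_frame_track",
    "render_waveform",
    "sample_rating",
    "generate_dataset",
    "SyntheticDataset",
    "PREDICTORS",
]

#: The five conversation-level predictors of the enjoyment model, in the
#: order they are reported.
PREDICTORS = ("length_min", "pct_speaking", "turn_rate_per_min",
              "vol_sd_db", "pitch_sd_hz")


class GenerationError(RuntimeError):
    """The requested conversation structure is infeasible."""


# ---------------------------------------------------------------------------
# distribution helper
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistributionSpec:
    """Truncated-lognormal spec parameterized by natural-scale mean and SD.

    Sampling draws from the lognormal matching (mean, sd) and clips to
    [min, max]; degenerate sd = 0 yields a point mass at the mean.
    """

    mean: float
    sd: float
    min: float = 0.0
    max: float = math.inf

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        if self.sd <= 0:
            out = np.full(np.prod(size) if size else 1, float(self.mean))
        else:
            sigma2 = math.log1p((self.sd / self.mean) ** 2)
            mu = math.log(self.mean) - sigma2 / 2.0
            out = rng.lognormal(mu, math.sqrt(sigma2), size=size)
            out = np.atleast_1d(out)
        out = np.clip(out, self.min, self.max)
        if size is None:
            return float(out[0])
        return out


# ---------------------------------------------------------------------------
# configuration and participant profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParticipantProfile:
    """Person-level generative parameters for one participant."""

    participant_id: str
    role_volume_db: dict  # role -> mean frame volume (dB)
    volume_jitter_db: float  # within-role frame SD (dB)
    f0_mean_hz: float
    f0_sd_hz: float
    random_intercept: float  # person deviation on the rating scale
    age: float
    gender: str
    big5: dict  # trait -> score (1-5)

    def __post_init__(self) -> None:
        vols = [self.role_volume_db[r] for r in ROLE_ORDER]
        if not all(a > b for a, b in zip(vols, vols[1:])):
            raise ConfigurationError(
                "role_volume_db must be strictly decreasing over "
                "clothing_noise > participant > other > silence; got "
                f"{self.role_volume_db}"
            )


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic-data generator (defaults = study scale).

    Defaults reproduce the scale of the original sample: 36 participants
    with 3-58 conversations each (mean 13, SD 12), conversation lengths
    0.5-128 min (mean 8.6), speaking fractions averaging 40% (SD 22%),
    turn rates averaging about 7/min, and ratings calibrated to mean 4.31 /
    SD 1.25 on the 1-7 scale with a -0.19 standardized speaking-percentage
    effect.
    """

    n_participants: int = 36
    conversations_per_participant: DistributionSpec = DistributionSpec(13.0, 12.0, 3, 58)
    conversation_length_min: DistributionSpec = DistributionSpec(8.6, 15.5, 0.5, 128.0)
    turn_duration_s: DistributionSpec = DistributionSpec(7.0, 5.0, 1.5, 90.0)
    # participant speaking fraction of (pre-trailing) conversation length
    speaking_fraction_mean: float = 0.40
    speaking_fraction_sd: float = 0.22
    speaking_fraction_bounds: tuple = (0.01, 0.95)
    # internal silence gaps between turns
    silence_gap_prob: float = 0.2
    silence_gap_s: DistributionSpec = DistributionSpec(3.0, 2.0, 1.5, 15.0)
    trailing_silence_s: float = 60.0
    # four volume regimes (dB) and frame jitter
    role_volume_db: dict = field(default_factory=lambda: {
        "clothing_noise": 70.0, "participant": 57.0,
        "other": 45.0, "silence": 20.0})
    role_volume_person_sd: float = 2.0  # person-level wobble on speech means
    volume_jitter_db: float = 2.0
    vol_mean_sd_corr: float = 0.0  # conv-level corr(vol_mean, vol_sd) knob
    clothing_burst_rate: float = 0.01  # fraction of frames hit by bursts
    clothing_burst_s: tuple = (0.1, 0.5)
    # participant F0 (person means gendered; adult range enforced)
    f0_range_hz: tuple = (92.0, 253.0)
    f0_mean_by_gender: dict = field(default_factory=lambda: {
        "female": (207.0, 22.0), "male": (131.0, 18.0)})
    p_female: float = 21.0 / 36.0
    f0_sd_hz: DistributionSpec = DistributionSpec(39.0, 15.0, 5.0, 80.0)
    #: frame-to-frame AR(1) coefficient of the participant F0 contour:
    #: pitch drifts smoothly on a prosodic (~1.6 s) timescale rather than
    #: jumping independently every 16 ms frame
    f0_ar1_phi: float = 0.99
    # demographics / traits (no true effect on ratings by default)
    age_mean: float = 20.6
    age_sd: float = 4.92
    # rating model
    fixed_effects: dict = field(default_factory=lambda: {
        "pct_speaking": -0.19, "length_min": 0.0, "turn_rate_per_min": 0.0,
        "vol_sd_db": 0.0, "pitch_sd_hz": 0.0})
    rating_mean: float = 4.31
    rating_sd: float = 1.25
    random_intercept_sd: float = 0.70
    discretize_ratings: bool = True
    # frame grid and audio
    frame_hop_s: float = 0.016
    sample_rate: int = 16000
    full_scale_db: float = 73.0  # dB value mapped to 0 dBFS RMS
    tie_type_probs: dict = field(default_factory=lambda: {
        "strong": 210 / 473, "weak": 197 / 473, "other": 66 / 473})
    seed: int = 0

    # -- derived ----------------------------------------------------------
    @property
    def residual_sd(self) -> float:
        """Level-1 residual SD implied by the target rating SD.

        The total rating variance is decomposed as random-intercept
        variance + fixed-effect variance (z-scored predictors, so each
        beta contributes beta²) + residual variance, plus ~1/12 rounding
        variance when ratings are discretized to integers.
        """
        beta_var = sum(b * b for b in self.fixed_effects.values())
        round_var = 1.0 / 12.0 if self.discretize_ratings else 0.0
        resid_var = (self.rating_sd ** 2 - self.random_intercept_sd ** 2
                     - beta_var - round_var)
        if resid_var <= 0:
            raise ConfigurationError(
                "rating_sd too small for the configured random_intercept_sd "
                "and fixed_effects (implied residual variance <= 0)")
        return math.sqrt(resid_var)

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if self.conversations_per_participant.min < 1:
            raise ConfigurationError(
                "conversations_per_participant: floor must be >= 1")
        if self.turn_duration_s.min <= 0:
            raise ConfigurationError("turn_duration_s: floor must be > 0")
        lo, hi = self.speaking_fraction_bounds
        if not (0 < lo < hi < 1):
            raise ConfigurationError(
                "speaking_fraction_bounds must satisfy 0 < lo < hi < 1")
        if not (1 <= self.rating_mean <= 7):
            raise ConfigurationError("rating_mean must lie in [1, 7]")
        if self.rating_sd <= 0:
            raise ConfigurationError("rating_sd must be > 0")
        # latent ratings should fall predominantly inside the 1-7 scale
        from scipy.stats import norm
        p_out = (norm.cdf(0.5, self.rating_mean, self.rating_sd)
                 + norm.sf(7.5, self.rating_mean, self.rating_sd))
        if p_out > 0.10:
            raise ConfigurationError(
                "rating_mean/rating_sd place more than 10% of latent mass "
                "outside the 1-7 scale")
        f0lo, f0hi = self.f0_range_hz
        if not (50 < f0lo < f0hi < 500):
            raise ConfigurationError("f0_range_hz must be inside (50, 500)")
        self.residual_sd  # raises if the variance budget is infeasible
        vols = [self.role_volume_db[r] for r in ROLE_ORDER]
        if not all(a > b for a, b in zip(vols, vols[1:])):
            raise ConfigurationError(
                "role_volume_db must be strictly decreasing in role order")
        if self.trailing_silence_s < 0:
            raise ConfigurationError("trailing_silence_s must be >= 0")


# ---------------------------------------------------------------------------
# participant sampling
# ---------------------------------------------------------------------------

def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float) -> float:
    """Draw one normal variate, redrawing (then clipping) into [lo, hi]."""
    if sd <= 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(64):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(x, lo, hi))


def sample_participant_profile(config: GeneratorConfig,
                               rng: np.random.Generator,
                               participant_id: str = "p000",
                               ) -> ParticipantProfile:
    """Draw one participant's person-level generative parameters."""
    config.validate()
    gender = "female" if rng.random() < config.p_female else "male"
    f0_mu, f0_s = config.f0_mean_by_gender[gender]
    f0lo, f0hi = config.f0_range_hz
    f0_mean = _truncnorm(rng, f0_mu, f0_s, f0lo, f0hi)
    f0_sd = config.f0_sd_hz.sample(rng)

    base = config.role_volume_db
    wob = config.role_volume_person_sd
    # person-level wobble on the speech regimes, bounded so the four role
    # means stay strictly ordered with >= 3 dB margins
    part = _truncnorm(rng, base["participant"], wob,
                      base["other"] + 4.0, base["clothing_noise"] - 4.0)
    other = _truncnorm(rng, base["other"], wob,
                       base["silence"] + 4.0, part - 4.0)
    role_volume = {"clothing_noise": base["clothing_noise"],
                   "participant": part, "other": other,
                   "silence": base["silence"]}

    big5 = {t: _truncnorm(rng, 3.5, 0.7, 1.0, 5.0)
            for t in ("openness", "conscientiousness", "extraversion",
                      "agreeableness", "neuroticism")}
    return ParticipantProfile(
        participant_id=participant_id,
        role_volume_db=role_volume,
        volume_jitter_db=config.volume_jitter_db,
        f0_mean_hz=f0_mean,
        f0_sd_hz=f0_sd,
        random_intercept=rng.normal(0.0, config.random_intercept_sd),
        age=_truncnorm(rng, config.age_mean, config.age_sd, 17.0, 65.0),
        gender=gender,
        big5=big5,
    )


# ---------------------------------------------------------------------------
# turn-structure sampling
# ---------------------------------------------------------------------------

def _scaled_durations(spec: DistributionSpec, total: float, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    """n positive durations ~ spec rescaled to sum exactly `total`,
    each >= spec.min (reducing n if the floor cannot be honored)."""
    floor = spec.min
    while n >= 1:
        if n * floor > total + 1e-9:
            n -= 1
            continue
        d = spec.sample(rng, size=n)
        d = d * (total / d.sum())
        if d.min() >= floor - 1e-9 or n == 1:
            return np.maximum(d, min(floor, total))
        n -= 1
    raise GenerationError(
        f"cannot tile {total:.2f}s with turns of floor {floor}s")


def sample_turn_sequence(profile: ParticipantProfile,
                         config: GeneratorConfig,
                         rng: np.random.Generator,
                         ) -> list[DiarizedSegment]:
    """Sample the ground-truth segment structure of one conversation.

    Participant and partner turns alternate (a semi-Markov structure with
    truncated-lognormal durations), with optional internal silence gaps; a
    trailing silence block of ``config.trailing_silence_s`` is appended, as
    the recording app required to detect the end of a conversation.  The
    realized participant speaking fraction (of the pre-trailing length)
    equals the sampled target exactly, because turn durations are rescaled
    after drawing.
    """
    length_s = config.conversation_length_min.sample(rng) * 60.0
    floor = config.turn_duration_s.min
    mean_turn = config.turn_duration_s.mean

    # feasible speaking fractions given the turn-duration floor: both the
    # participant and the partner need at least one floor-length turn
    lo = max(config.speaking_fraction_bounds[0], floor / length_s)
    hi = min(config.speaking_fraction_bounds[1], 1.0 - floor / length_s)
    if lo > hi:
        raise GenerationError(
            f"no feasible speaking fraction for a {length_s:.0f}s "
            f"conversation with turn-duration floor {floor}s")
    target = float(np.clip(rng.normal(config.speaking_fraction_mean,
                                      config.speaking_fraction_sd), lo, hi))

    # internal silence budget, capped so partner time stays feasible
    n_turns_est = max(1, round(length_s / mean_turn))
    n_gaps = rng.binomial(max(0, n_turns_est - 1), config.silence_gap_prob)
    gaps = list(config.silence_gap_s.sample(rng, size=n_gaps)) if n_gaps else []
    max_sil = max(0.0, 0.5 * (1.0 - target) * length_s - floor)
    while gaps and sum(gaps) > max_sil:
        gaps.pop()
    sil_total = sum(gaps)

    p_total = target * length_s
    o_total = length_s - sil_total - p_total
    if o_total < floor:
        # all non-participant time becomes partner speech
        gaps, sil_total = [], 0.0
        o_total = length_s - p_total
        if o_total < floor:
            raise GenerationError(
                f"no room for a partner turn (fraction {target:.3f})")

    n_p = max(1, round(p_total / mean_turn))
    n_o = int(np.clip(max(1, round(o_total / mean_turn)), n_p - 1, n_p + 1))
    p_durs = _scaled_durations(config.turn_duration_s, p_total, n_p, rng)
    o_durs = _scaled_durations(config.turn_duration_s, o_total, n_o, rng)
    n_p, n_o = len(p_durs), len(o_durs)
    # alternation needs |n_p - n_o| <= 1; re-tile the smaller list if the
    # floor-reduction loop broke that
    if abs(n_p - n_o) > 1:
        if n_p > n_o:
            p_durs = _scaled_durations(config.turn_duration_s, p_total,
                                       n_o + 1, rng)
            n_p = len(p_durs)
        else:
            o_durs = _scaled_durations(config.turn_duration_s, o_total,
                                       n_p + 1, rng)
            n_o = len(o_durs)

    if n_p > n_o:
        order = ["participant", "other"] * n_o + ["participant"]
    elif n_o > n_p:
        order = ["other", "participant"] * n_p + ["other"]
    else:
        first = "participant" if rng.random() < 0.5 else "other"
        second = "other" if first == "participant" else "participant"
        order = [first, second] * n_p

    it_p, it_o = iter(p_durs), iter(o_durs)
    turns = [(role, next(it_p) if role == "participant" else next(it_o))
             for role in order]

    # distribute silence gaps over distinct internal boundaries
    n_bounds = len(turns) - 1
    gaps = gaps[:n_bounds]
    gap_at = {}
    if gaps and n_bounds > 0:
        where = rng.choice(n_bounds, size=len(gaps), replace=False)
        gap_at = {int(w): g for w, g in zip(where, gaps)}

    segments: list[DiarizedSegment] = []
    t = 0.0
    for i, (role, dur) in enumerate(turns):
        segments.append(DiarizedSegment(t, t + dur, role))
        t += dur
        if i in gap_at:
            segments.append(DiarizedSegment(t, t + gap_at[i], "silence"))
            t += gap_at[i]
    if config.trailing_silence_s > 0:
        segments.append(DiarizedSegment(t, t + config.trailing_silence_s,
                                        "silence"))
    return segments


def true_features_from_segments(segments: list[DiarizedSegment],
                                trailing_silence_s: float) -> dict:
    """Exact structural features implied by a ground-truth segment list
    (pre-trailing length, speaking %, turn count/rate)."""
    if trailing_silence_s > 0:
        body = segments[:-1]
    else:
        body = segments
    length_s = body[-1].end_s - body[0].start_s
    p_time = sum(s.duration_s for s in body if s.role == "participant")
    turn_count = sum(1 for s in body if s.role in SPEECH_ROLES)
    length_min = length_s / 60.0
    return {
        "length_min": length_min,
        "pct_speaking": 100.0 * p_time / length_s,
        "turn_count": turn_count,
        "turn_rate_per_min": turn_count / length_min,
    }


# ---------------------------------------------------------------------------
# frame-track and waveform rendering
# ---------------------------------------------------------------------------

def _frame_roles(segments: list[DiarizedSegment],
                 t: np.ndarray) -> np.ndarray:
    ends = np.array([s.end_s for s in segments])
    idx = np.minimum(np.searchsorted(ends, t, side="right"),
                     len(segments) - 1)
    roles = np.array([s.role for s in segments], dtype=object)
    return roles[idx]


def _inject_bursts(roles: np.ndarray, config: GeneratorConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Overwrite random short runs of frames with clothing-noise bursts."""
    if config.clothing_burst_rate <= 0:
        return roles
    roles = roles.copy()
    n = len(roles)
    hop = config.frame_hop_s
    target_frames = config.clothing_burst_rate * n
    lo, hi = config.clothing_burst_s
    covered = 0
    while covered < target_frames:
        w = max(1, int(round(rng.uniform(lo, hi) / hop)))
        start = rng.integers(0, max(1, n - w))
        roles[start:start + w] = "clothing_noise"
        covered += w
    return roles


def render_frame_track(truth: list[DiarizedSegment],
                       profile: ParticipantProfile,
                       config: GeneratorConfig,
                       rng: np.random.Generator,
                       conversation_id: str = "c0000",
                       ) -> tuple[FrameTrack, np.ndarray]:
    """Render per-frame volume/pitch/voiced from a ground-truth segment list.

    Returns ``(track, frame_roles)`` where ``frame_roles`` is the effective
    per-frame role after clothing-noise bursts were injected — the label
    array diarization is scored against.
    """
    if not truth:
        raise DataError("empty ground-truth segment list")
    total = truth[-1].end_s
    hop = config.frame_hop_s
    t = np.arange(0.0, total - hop / 2, hop)
    roles = _frame_roles(truth, t)
    roles = _inject_bursts(roles, config, rng)

    vol = np.empty(len(t))
    for role in ROLE_ORDER:
        m = roles == role
        if m.any():
            vol[m] = profile.role_volume_db[role]
    if profile.volume_jitter_db > 0:
        vol = vol + rng.normal(0.0, profile.volume_jitter_db, size=len(t))

    pitch = np.full(len(t), np.nan)
    is_part = roles == "participant"
    if is_part.any():
        f0lo, f0hi = config.f0_range_hz
        k = int(is_part.sum())
        # smooth AR(1) pitch contour with stationary SD = profile.f0_sd_hz
        phi = float(np.clip(config.f0_ar1_phi, 0.0, 0.9999))
        w = rng.standard_normal(k) * math.sqrt(1.0 - phi * phi)
        w[0] = rng.standard_normal()  # stationary start, full variance
        from scipy.signal import lfilter
        dev = lfilter([1.0], [1.0, -phi], w)
        draws = profile.f0_mean_hz + profile.f0_sd_hz * dev
        pitch[is_part] = np.clip(draws, f0lo, f0hi)
    voiced = np.isin(roles, SPEECH_ROLES)
    track = FrameTrack(conversation_id=conversation_id, frame_hop_s=hop,
                       t_s=t, volume_db=vol, pitch_hz=pitch, voiced=voiced)
    return track, roles


def _db_to_rms(db: np.ndarray, full_scale_db: float) -> np.ndarray:
    return 10.0 ** ((np.asarray(db, dtype=float) - full_scale_db) / 20.0)


def render_waveform(truth: list[DiarizedSegment],
                    profile: ParticipantProfile,
                    config: GeneratorConfig,
                    rng: np.random.Generator,
                    track: Optional[FrameTrack] = None,
                    partner_f0_hz: Optional[float] = None,
                    ) -> tuple[np.ndarray, int]:
    """Render a mono waveform realizing a ground-truth segment list.

    Participant frames become a harmonic tone at the frame F0; partner
    frames a harmonic tone at a distinct F0; silence is near-zero noise.
    Per-frame RMS follows the frame track's volume (dB mapped to dBFS via
    ``config.full_scale_db``), so the waveform path and the direct
    frame-track path agree frame by frame.  When ``track`` is None a fresh
    frame track is rendered internally (burst placement then differs from
    any separately rendered track).

    Returns ``(samples, sample_rate)`` with float samples in [-1, 1].
    """
    sr = config.sample_rate
    if sr < 8000:
        raise ConfigurationError("sample_rate must be >= 8000 Hz")
    if track is None:
        track, _ = render_frame_track(truth, profile, config, rng)
    if partner_f0_hz is None:
        f0lo, f0hi = config.f0_range_hz
        partner_f0_hz = float(rng.uniform(f0lo, f0hi))

    hop = track.frame_hop_s
    spf = int(round(hop * sr))  # samples per frame hop
    n_frames = track.n_frames
    n_samples = spf * n_frames
    roles = _frame_roles(truth, track.t_s)

    target_rms = _db_to_rms(track.volume_db, config.full_scale_db)
    # frame-wise F0: participant frames use the track pitch; everything
    # rendered as tone uses continuous phase accumulation
    f0 = np.where(np.isnan(track.pitch_hz), partner_f0_hz, track.pitch_hz)
    f0_samples = np.repeat(f0, spf)
    phase = 2.0 * math.pi * np.cumsum(f0_samples) / sr
    harm_amp = np.array([1.0, 0.5, 0.25])
    tone = sum(a * np.sin((h + 1) * phase) for h, a in enumerate(harm_amp))
    tone_rms = math.sqrt(0.5 * float(np.sum(harm_amp ** 2)))
    tone /= tone_rms  # unit-RMS harmonic complex

    noise = rng.standard_normal(n_samples)  # unit-RMS (approx.) noise

    is_tone = np.isin(roles, SPEECH_ROLES)
    gain = np.repeat(target_rms, spf)
    use_tone = np.repeat(is_tone, spf)
    samples = gain * np.where(use_tone, tone, noise)
    return np.clip(samples, -1.0, 1.0), sr


# ---------------------------------------------------------------------------
# rating model
# ---------------------------------------------------------------------------

def sample_rating(z_features: dict,
                  profile: ParticipantProfile,
                  config: GeneratorConfig,
                  rng: np.random.Generator,
                  ) -> float:
    """Sample one enjoyment rating from the two-level linear model.

    ``z_features`` maps predictor name to its z-score (standardized over
    the dataset the conversation belongs to).  The latent response is

        mean + person_intercept + sum_k beta_k * z_k + Normal(0, sigma_resid)

    and is rounded to the nearest integer and clipped to [1, 7] when
    ``config.discretize_ratings`` is set.  Discretization attenuates
    recovered fixed effects slightly; the residual SD is calibrated so the
    observed rating SD still matches ``config.rating_sd``.
    """
    latent = config.rating_mean + profile.random_intercept
    for name, beta in config.fixed_effects.items():
        if beta != 0.0 and name not in z_features:
            raise DataError(f"missing z-scored predictor {name!r}")
        latent += beta * z_features.get(name, 0.0)
    latent += rng.normal(0.0, config.residual_sd)
    if config.discretize_ratings:
        return float(np.clip(round(latent), 1, 7))
    return float(latent)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Everything one generator run produces."""

    config: GeneratorConfig
    participants: pd.DataFrame
    conversations: pd.DataFrame  # id, participant, rating, tie_type
    truth: pd.DataFrame          # true conversation-level features
    profiles: dict               # participant_id -> ParticipantProfile
    segments: dict               # conversation_id -> list[DiarizedSegment]
    tracks: dict                 # conversation_id -> FrameTrack (optional)
    frame_roles: dict            # conversation_id -> per-frame role labels


def _sample_conv_acoustics(profile: ParticipantProfile,
                           config: GeneratorConfig,
                           rng: np.random.Generator) -> dict:
    """Conversation-level acoustic summary features (true values).

    vol_mean and vol_sd receive correlated conversation-level wobble so the
    mean/variability collinearity seen in real speech data can be emulated
    via ``config.vol_mean_sd_corr``.
    """
    rho = float(np.clip(config.vol_mean_sd_corr, -0.999, 0.999))
    e1 = rng.standard_normal()
    vol_mean = profile.role_volume_db["participant"] + 2.0 * e1
    # correlate vol_sd with the *total* vol_mean deviation (person-level
    # wobble + conversation-level wobble), so the knob sets the realized
    # column correlation, not just the conversation-level share
    scale = math.sqrt(config.role_volume_person_sd ** 2 + 4.0)
    dev = (vol_mean - config.role_volume_db["participant"]) / scale
    e2 = rho * dev + math.sqrt(1.0 - rho * rho) * rng.standard_normal()
    vol_sd = max(0.3, profile.volume_jitter_db + 0.6 * e2)
    pitch_mean = float(np.clip(profile.f0_mean_hz + rng.normal(0.0, 5.0),
                               *config.f0_range_hz))
    pitch_sd = max(1.0, profile.f0_sd_hz * rng.normal(1.0, 0.15))
    return {"vol_mean_db": vol_mean, "vol_sd_db": vol_sd,
            "pitch_mean_hz": pitch_mean, "pitch_sd_hz": pitch_sd}


def generate_dataset(config: GeneratorConfig,
                     render_frames: bool = False,
                     ) -> SyntheticDataset:
    """Generate one full synthetic dataset, reproducibly.

    Ratings require z-scored predictors, so generation is two-pass: first
    all conversation structures and true features, then dataset-level
    z-scoring, then ratings.  Frame tracks are rendered only on request
    (``render_frames=True``) because they dominate run time; structural and
    rating analyses need only the truth table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    participants = []
    profiles: dict[str, ParticipantProfile] = {}
    seg_map: dict[str, list[DiarizedSegment]] = {}
    roles_map: dict[str, np.ndarray] = {}
    tracks: dict[str, FrameTrack] = {}
    rows = []

    n_conv = np.maximum(
        np.round(config.conversations_per_participant.sample(
            rng, size=config.n_participants)).astype(int),
        int(config.conversations_per_participant.min))

    cid = 0
    tie_names = list(config.tie_type_probs)
    tie_p = np.array([config.tie_type_probs[k] for k in tie_names])
    tie_p = tie_p / tie_p.sum()
    for i in range(config.n_participants):
        pid = f"p{i:03d}"
        prof = sample_participant_profile(config, rng, participant_id=pid)
        profiles[pid] = prof
        participants.append({
            "participant_id": pid, "age": prof.age, "gender": prof.gender,
            **{f"big5_{k}": v for k, v in prof.big5.items()},
        })
        for _ in range(int(n_conv[i])):
            conv_id = f"c{cid:04d}"
            cid += 1
            segs = sample_turn_sequence(prof, config, rng)
            seg_map[conv_id] = segs
            feats = true_features_from_segments(
                segs, config.trailing_silence_s)
            feats.update(_sample_conv_acoustics(prof, config, rng))
            feats["conversation_id"] = conv_id
            feats["participant_id"] = pid
            feats["tie_type"] = tie_names[rng.choice(len(tie_names), p=tie_p)]
            rows.append(feats)
            if render_frames:
                track, froles = render_frame_track(
                    segs, prof, config, rng, conversation_id=conv_id)
                tracks[conv_id] = track
                roles_map[conv_id] = froles

    truth = pd.DataFrame(rows)
    # dataset-level z-scores of the five predictors drive the rating model
    z = {}
    for name in PREDICTORS:
        col = truth[name].to_numpy(dtype=float)
        sd = col.std(ddof=1)
        z[name] = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)
    ratings = []
    for j, row in truth.iterrows():
        zf = {name: z[name][j] for name in PREDICTORS}
        ratings.append(sample_rating(zf, profiles[row["participant_id"]],
                                     config, rng))
    truth["rating"] = ratings

    conversations = truth[["conversation_id", "participant_id",
                           "rating", "tie_type"]].copy()
    return SyntheticDataset(
        config=config,
        participants=pd.DataFrame(participants),
        conversations=conversations,
        truth=truth,
        profiles=profiles,
        segments=seg_map,
        tracks=tracks,
        frame_roles=roles_map,
    )


def with_overrides(config: GeneratorConfig, **kw) -> GeneratorConfig:
    """Convenience: a copy of `config` with fields replaced."""
    return replace(config, **kw)
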