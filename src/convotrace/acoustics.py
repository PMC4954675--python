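"""Waveform → frame-level volume / pitch / voicing.

This is the privacy-preserving front end: from a mono WAV it keeps only a
per-frame RMS level (dBFS), an autocorrelation F0 estimate, and a voiced
flag — nothing from which speech content could be reconstructed.  It is a
simplified, documented stand-in for the validated on-phone feature
extractor used in mobile-sensing studies of this kind; that extractor's
exact voicing detector is not public, so ours is an approximation, not a
reconstruction.

Volume is reported in dBFS (decibels relative to digital full scale).
Absolute dB values printed for phone-microphone studies are uncalibrated
SPL-like numbers and are not directly comparable; an optional ``db_offset``
shifts our scale when matching an externally referenced track.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datatypes import ConfigurationError, DataError, FrameTrack, SILENCE_FLOOR_DB

__all__ = [
    "AcousticsConfig",
    "compute_volume_track",
    "estimate_pitch",
    "detect_voiced",
    "track_from_waveform",
    "read_wav",
    "write_wav",
]


@dataclass(frozen=True)
class AcousticsConfig:
    """Framing and thresholds for feature extraction.

    Defaults: 32 ms frames with 16 ms hop (>= 2 periods of a 92 Hz F0 fit
    in one frame), F0 search 65-300 Hz, voicing requires frame energy above
    -45 dBFS and a normalized autocorrelation peak above 0.5.
    """

    frame_s: float = 0.032
    hop_s: float = 0.016
    f0_min_hz: float = 65.0
    f0_max_hz: float = 300.0
    energy_threshold_db: float = -45.0
    periodicity_threshold: float = 0.5
    db_offset: float = 0.0


def _frame_starts(n_samples: int, sr: int, frame_s: float,
                  hop_s: float) -> np.ndarray:
    flen = int(round(frame_s * sr))
    hop = int(round(hop_s * sr))
    if flen <= 0 or hop <= 0 or flen < hop:
        raise ConfigurationError("need frame_s >= hop_s > 0")
    if n_samples < flen:
        raise DataError("audio shorter than one frame")
    return np.arange(0, n_samples - flen + 1, hop)


def _framed(samples: np.ndarray, starts: np.ndarray, flen: int) -> np.ndarray:
    idx = starts[:, None] + np.arange(flen)[None, :]
    return samples[idx]


def compute_volume_track(samples: np.ndarray, sample_rate: int,
                         frame_s: float = 0.032, hop_s: float = 0.016,
                         db_offset: float = 0.0) -> np.ndarray:
    """Per-frame RMS level in dBFS: 20*log10(RMS), 0 dB = full-scale RMS.

    Digitally silent frames are clamped to the documented floor
    (:data:`~convotrace.datatypes.SILENCE_FLOOR_DB`).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise DataError("empty audio")
    if not np.all(np.isfinite(samples)):
        raise DataError("audio contains non-finite samples")
    flen = int(round(frame_s * sample_rate))
    starts = _frame_starts(samples.size, sample_rate, frame_s, hop_s)
    frames = _framed(samples, starts, flen)
    rms = np.sqrt(np.mean(frames ** 2, axis=1))
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(rms)
    return np.maximum(db, SILENCE_FLOOR_DB) + db_offset


def estimate_pitch(samples: np.ndarray, sample_rate: int,
                   frame_s: float = 0.032, hop_s: float = 0.016,
                   f0_min_hz: float = 65.0, f0_max_hz: float = 300.0,
                   periodicity_threshold: float = 0.5,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame F0 by normalized autocorrelation with parabolic refinement.

    Returns ``(pitch_hz, periodicity)``; ``pitch_hz`` is NaN on frames whose
    autocorrelation peak falls below ``periodicity_threshold`` (aperiodic
    frames), ``periodicity`` is the peak height in [-1, 1].
    """
    samples = np.asarray(samples, dtype=float)
    if not (50.0 < f0_min_hz < f0_max_hz < 500.0):
        raise ConfigurationError("f0 range must lie inside (50, 500) Hz")
    flen = int(round(frame_s * sample_rate))
    lag_min = int(math.floor(sample_rate / f0_max_hz))
    lag_max = int(math.ceil(sample_rate / f0_min_hz))
    if lag_max >= flen:
        raise ConfigurationError(
            f"frame of {frame_s*1e3:.0f} ms too short for f0_min "
            f"{f0_min_hz} Hz (needs >= {lag_max+1} samples, has {flen})")
    starts = _frame_starts(samples.size, sample_rate, frame_s, hop_s)
    frames = _framed(samples, starts, flen)
    frames = frames - frames.mean(axis=1, keepdims=True)

    # full autocorrelation per frame via FFT; unbiased normalization
    # (divide lag tau by (N - tau)/N) so a pure tone peaks at ~1 and the
    # linear taper cannot tilt the parabolic interpolation
    nfft = 1 << int(np.ceil(np.log2(2 * flen)))
    spec = np.fft.rfft(frames, nfft, axis=1)
    ac = np.fft.irfft(spec * np.conj(spec), nfft, axis=1)[:, :flen]
    ac0 = ac[:, 0].copy()
    ac0[ac0 <= 0] = np.inf  # silent frame -> periodicity 0
    taper = (flen - np.arange(flen)) / flen
    nac = ac / ac0[:, None] / taper[None, :]

    window = nac[:, lag_min:lag_max + 1]
    peak = np.max(window, axis=1)
    # a periodic frame correlates equally at every multiple of its period;
    # take the smallest *local maximum* within tolerance of the global one
    # to avoid subharmonic (octave-down) errors
    interior = np.zeros_like(window, dtype=bool)
    interior[:, 1:-1] = ((window[:, 1:-1] >= window[:, :-2])
                         & (window[:, 1:-1] >= window[:, 2:]))
    cand = interior & (window >= peak[:, None] - 0.05)
    has_cand = cand.any(axis=1)
    best = np.where(has_cand, np.argmax(cand, axis=1),
                    np.argmax(window, axis=1))
    lag = (lag_min + best).astype(float)

    # parabolic interpolation around the peak lag
    li = lag_min + best
    can = (li > lag_min) & (li < lag_max)
    if can.any():
        i = np.where(can)[0]
        y0 = nac[i, li[i] - 1]
        y1 = nac[i, li[i]]
        y2 = nac[i, li[i] + 1]
        denom = y0 - 2 * y1 + y2
        ok = np.abs(denom) > 1e-12
        shift = np.zeros_like(y1)
        shift[ok] = 0.5 * (y0[ok] - y2[ok]) / denom[ok]
        lag[i] = li[i] + np.clip(shift, -1, 1)

    pitch = sample_rate / lag
    periodicity = np.clip(peak, -1.0, 1.0)
    pitch[periodicity < periodicity_threshold] = np.nan
    pitch[(pitch < f0_min_hz) | (pitch > f0_max_hz)] = np.nan
    return pitch, periodicity


def detect_voiced(track: FrameTrack,
                  energy_threshold_db: float = -45.0,
                  periodicity_threshold: float = 0.5,
                  ) -> np.ndarray:
    """Voicing flags: energy above threshold AND (periodic OR rescued).

    A frame failing the periodicity test is rescued when both its
    neighbors pass it (majority smoothing over a 3-frame window), which
    fills single-frame dropouts inside voiced runs.  The rule is
    idempotent: rescued frames do not enable further rescues.
    """
    if not np.isfinite(energy_threshold_db):
        raise ConfigurationError("energy_threshold_db must be finite")
    loud = track.volume_db > energy_threshold_db
    if track.periodicity is not None:
        periodic = np.asarray(track.periodicity) >= periodicity_threshold
    else:
        periodic = ~np.isnan(track.pitch_hz)
    rescued = np.zeros_like(periodic)
    if len(periodic) > 2:
        rescued[1:-1] = periodic[:-2] & periodic[2:]
    return loud & (periodic | rescued)


def track_from_waveform(samples: np.ndarray, sample_rate: int,
                        conversation_id: str = "c0000",
                        config: AcousticsConfig = AcousticsConfig(),
                        ) -> FrameTrack:
    """Full front end: volume + pitch + voicing from a mono waveform."""
    vol = compute_volume_track(samples, sample_rate, config.frame_s,
                               config.hop_s, db_offset=config.db_offset)
    pitch, periodicity = estimate_pitch(
        samples, sample_rate, config.frame_s, config.hop_s,
        config.f0_min_hz, config.f0_max_hz, config.periodicity_threshold)
    t = np.arange(len(vol)) * config.hop_s
    track = FrameTrack(conversation_id=conversation_id,
                       frame_hop_s=config.hop_s, t_s=t, volume_db=vol,
                       pitch_hz=pitch, voiced=np.zeros(len(vol), bool),
                       periodicity=periodicity)
    track.voiced = detect_voiced(track, config.energy_threshold_db,
                                 config.periodicity_threshold)
    track.pitch_hz = np.where(track.voiced, track.pitch_hz, np.nan)
    return track


# -- WAV I/O (PCM16 mono) ---------------------------------------------------

def write_wav(path, samples: np.ndarray, sample_rate: int) -> None:
    """Write float samples in [-1, 1] as RIFF PCM 16-bit mono."""
    from scipy.io import wavfile
    pcm = np.clip(np.asarray(samples, dtype=float), -1.0, 1.0)
    wavfile.write(path, sample_rate, np.round(pcm * 32767.0).astype(np.int16))


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a mono WAV into float samples in [-1, 1]."""
    from scipy.io import wavfile
    sr, data = wavfile.read(path)
    if data.ndim != 1:
        raise DataError(f"{path}: expected mono audio")
    if data.dtype == np.int16:
        samples = data.astype(float) / 32767.0
    elif data.dtype == np.int32:
        samples = data.astype(float) / 2147483647.0
    elif data.dtype == np.uint8:
        samples = (data.astype(float) - 128.0) / 127.0
    else:
        samples = data.astype(float)
    return samples, int(sr)
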