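"""Generator contracts: profile invariants, turn structure, rendering,
rating model, dataset determinism and calibration."""

import dataclasses

import numpy as np
import pytest

from convotrace import synthgen
from convotrace.datatypes import ConfigurationError, ROLE_ORDER, SPEECH_ROLES
from convotrace.synthgen import (
    DistributionSpec,
    GeneratorConfig,
    generate_dataset,
    render_frame_track,
    render_waveform,
    sample_participant_profile,
    sample_rating,
    sample_turn_sequence,
    true_features_from_segments,
    with_overrides,
)


# ---------------------------------------------------------------------------
# participant profiles
# ---------------------------------------------------------------------------

def test_profile_role_volumes_ordered_and_f0_in_adult_range(default_config):
    rng = np.random.default_rng(0)
    for _ in range(50):
        p = sample_participant_profile(default_config, rng)
        vols = [p.role_volume_db[r] for r in ROLE_ORDER]
        assert all(a > b for a, b in zip(vols, vols[1:]))
        assert 92.0 <= p.f0_mean_hz <= 253.0


def test_profile_degenerate_f0_distribution_is_point_mass(default_config):
    cfg = with_overrides(default_config,
                         f0_mean_by_gender={"female": (182.0, 0.0),
                                            "male": (182.0, 0.0)})
    rng = np.random.default_rng(1)
    assert all(sample_participant_profile(cfg, rng).f0_mean_hz == 182.0
               for _ in range(10))


def test_profile_f0_mean_matches_configured_mixture(default_config):
    """Monte-Carlo: empirical mean F0 within 3 SE of the configured
    gender-mixture mean."""
    cfg = default_config
    rng = np.random.default_rng(2)
    f0 = np.array([sample_participant_profile(cfg, rng).f0_mean_hz
                   for _ in range(1000)])
    pf = cfg.p_female
    expected = (pf * cfg.f0_mean_by_gender["female"][0]
                + (1 - pf) * cfg.f0_mean_by_gender["male"][0])
    se = f0.std(ddof=1) / np.sqrt(len(f0))
    assert abs(f0.mean() - expected) < 3 * se


def test_invalid_config_names_offending_field():
    with pytest.raises(ConfigurationError, match="rating_sd"):
        GeneratorConfig(rating_sd=-1.0).validate()
    with pytest.raises(ConfigurationError, match="n_participants"):
        GeneratorConfig(n_participants=0).validate()
    with pytest.raises(ConfigurationError, match="f0_range_hz"):
        GeneratorConfig(f0_range_hz=(10.0, 900.0)).validate()


# ---------------------------------------------------------------------------
# turn sequences
# ---------------------------------------------------------------------------

def test_turn_sequence_tiles_time_and_alternates(default_config, profile):
    rng = np.random.default_rng(3)
    for _ in range(20):
        segs = sample_turn_sequence(profile, default_config, rng)
        assert segs[0].start_s == 0.0
        for a, b in zip(segs, segs[1:]):
            assert b.start_s == pytest.approx(a.end_s)
            assert a.role != b.role
        # speech roles strictly alternate (silence gaps aside)
        speech = [s.role for s in segs if s.role in SPEECH_ROLES]
        assert all(x != y for x, y in zip(speech, speech[1:]))


def test_turn_sequence_ends_with_trailing_silence(default_config, profile):
    rng = np.random.default_rng(4)
    segs = sample_turn_sequence(profile, default_config, rng)
    assert segs[-1].role == "silence"
    assert segs[-1].duration_s == pytest.approx(60.0)


def test_turn_sequence_realizes_target_fraction(default_config, profile):
    """Realized speaking fraction tracks the sampled target; with duration
    rescaling the deviation is bookkeeping-level (< 0.02 mean absolute)."""
    rng = np.random.default_rng(5)
    devs = []
    for _ in range(200):
        segs = sample_turn_sequence(profile, default_config, rng)
        f = true_features_from_segments(
            segs, default_config.trailing_silence_s)
        devs.append(f["pct_speaking"] / 100.0)
    devs = np.asarray(devs)
    # fractions stay inside the configured bounds and average near the
    # configured mean (clamping at short lengths shifts it slightly)
    assert devs.min() >= default_config.speaking_fraction_bounds[0] - 1e-9
    assert devs.max() <= default_config.speaking_fraction_bounds[1] + 1e-9
    assert abs(devs.mean() - default_config.speaking_fraction_mean) < 0.05


def test_turn_sequence_infeasible_fraction_raises(default_config, profile):
    cfg = with_overrides(default_config,
                         conversation_length_min=DistributionSpec(
                             0.04, 0.0, 0.04, 0.04),
                         turn_duration_s=DistributionSpec(1.5, 0.0, 1.5, 1.5))
    with pytest.raises(synthgen.GenerationError):
        sample_turn_sequence(profile, cfg, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# frame-track rendering
# ---------------------------------------------------------------------------

def test_frame_track_zero_jitter_hits_role_means(default_config, profile):
    cfg = with_overrides(default_config, clothing_burst_rate=0.0)
    prof = dataclasses.replace(profile, volume_jitter_db=0.0)
    rng = np.random.default_rng(6)
    segs = sample_turn_sequence(prof, cfg, rng)
    track, roles = render_frame_track(segs, prof, cfg, rng)
    for role in ROLE_ORDER:
        m = roles == role
        if m.any():
            assert np.allclose(track.volume_db[m],
                               prof.role_volume_db[role])


def test_frame_track_pitch_only_on_participant_frames(default_config,
                                                      profile):
    rng = np.random.default_rng(7)
    segs = sample_turn_sequence(profile, default_config, rng)
    track, roles = render_frame_track(segs, profile, default_config, rng)
    assert np.all(np.isnan(track.pitch_hz[roles != "participant"]))
    assert not np.any(np.isnan(track.pitch_hz[roles == "participant"]))
    assert np.array_equal(track.voiced, np.isin(roles, SPEECH_ROLES))


def test_frame_track_role_volume_regimes_are_separable(default_config):
    """Adjacent role means sit > 4 frame-SDs apart under default spacing,
    so the volume histograms barely overlap."""
    cfg = default_config
    vols = [cfg.role_volume_db[r] for r in ROLE_ORDER]
    min_gap = min(a - b for a, b in zip(vols, vols[1:]))
    assert min_gap > 4 * cfg.volume_jitter_db
    rng = np.random.default_rng(8)
    prof = sample_participant_profile(cfg, rng)
    segs = sample_turn_sequence(prof, cfg, rng)
    track, roles = render_frame_track(segs, prof, cfg, rng)
    mu_p = track.volume_db[roles == "participant"].mean()
    mu_o = track.volume_db[roles == "other"].mean()
    sd = cfg.volume_jitter_db
    assert (mu_p - mu_o) > 4 * sd


def test_frame_track_empty_truth_raises(default_config, profile):
    with pytest.raises(Exception):
        render_frame_track([], profile, default_config,
                           np.random.default_rng(0))


# ---------------------------------------------------------------------------
# waveform rendering
# ---------------------------------------------------------------------------

def test_waveform_pitch_recoverable_from_tone(default_config):
    from convotrace import acoustics
    cfg = with_overrides(default_config, clothing_burst_rate=0.0,
                         volume_jitter_db=0.0)
    rng = np.random.default_rng(9)
    prof = sample_participant_profile(cfg, rng)
    prof = dataclasses.replace(prof, f0_mean_hz=200.0, f0_sd_hz=0.0,
                               volume_jitter_db=0.0)
    from convotrace.datatypes import DiarizedSegment
    segs = [DiarizedSegment(0.0, 10.0, "participant"),
            DiarizedSegment(10.0, 70.0, "silence")]
    track, roles = render_frame_track(segs, prof, cfg, rng)
    samples, sr = render_waveform(segs, prof, cfg, rng, track=track)
    pitch, _ = acoustics.estimate_pitch(samples[: 10 * sr], sr)
    est = pitch[~np.isnan(pitch)]
    assert len(est) > 0.9 * len(pitch)
    assert np.max(np.abs(est - 200.0)) < 1.0


def test_waveform_all_silence_stays_below_floor(default_config, profile):
    from convotrace.datatypes import DiarizedSegment
    cfg = with_overrides(default_config, clothing_burst_rate=0.0)
    segs = [DiarizedSegment(0.0, 5.0, "silence")]
    rng = np.random.default_rng(10)
    samples, sr = render_waveform(segs, profile, cfg, rng)
    # silence regime sits 53 dB below full scale; allow noise crest factor
    floor_amp = 10 ** ((cfg.role_volume_db["silence"] + 6
                        - cfg.full_scale_db) / 20)
    assert np.max(np.abs(samples)) < 5 * floor_amp


def test_waveform_halving_amplitude_drops_6dB(default_config, profile):
    from convotrace import acoustics
    from convotrace.datatypes import DiarizedSegment
    cfg = with_overrides(default_config, clothing_burst_rate=0.0)
    segs = [DiarizedSegment(0.0, 3.0, "participant"),
            DiarizedSegment(3.0, 63.0, "silence")]
    rng = np.random.default_rng(11)
    samples, sr = render_waveform(segs, profile, cfg, rng)
    v1 = acoustics.compute_volume_track(samples[: 2 * sr], sr)
    v2 = acoustics.compute_volume_track(0.5 * samples[: 2 * sr], sr)
    assert np.allclose(v1 - v2, 20 * np.log10(2.0), atol=1e-9)


def test_waveform_roundtrips_through_wav(tmp_path, default_config, profile):
    from convotrace import acoustics
    from convotrace.datatypes import DiarizedSegment
    segs = [DiarizedSegment(0.0, 2.0, "participant"),
            DiarizedSegment(2.0, 62.0, "silence")]
    rng = np.random.default_rng(12)
    samples, sr = render_waveform(segs, profile, default_config, rng)
    acoustics.write_wav(tmp_path / "c.wav", samples, sr)
    back, sr2 = acoustics.read_wav(tmp_path / "c.wav")
    assert sr2 == sr
    assert np.max(np.abs(back - samples)) < 1.5 / 32767


# ---------------------------------------------------------------------------
# rating model
# ---------------------------------------------------------------------------

def test_rating_noise_free_limit_rounds_the_mean(default_config, profile):
    cfg = with_overrides(default_config, random_intercept_sd=0.0,
                         fixed_effects={k: 0.0 for k in
                                        default_config.fixed_effects})
    prof = dataclasses.replace(profile, random_intercept=0.0)
    # force zero residual by shrinking rating_sd to the rounding floor
    cfg = with_overrides(cfg, rating_sd=np.sqrt(1 / 12) + 1e-9)
    r = sample_rating({}, prof, cfg, np.random.default_rng(0))
    assert r == 4.0  # round(4.31)


def test_rating_speaking_effect_has_negative_sign(default_config, profile):
    cfg = with_overrides(default_config,
                         fixed_effects={"pct_speaking": -0.19})
    rng = np.random.default_rng(13)
    z = np.linspace(-2.5, 2.5, 4000)
    ratings = np.array([sample_rating({"pct_speaking": zi}, profile, cfg,
                                      rng) for zi in z])
    top = ratings[z > np.quantile(z, 0.9)].mean()
    bottom = ratings[z < np.quantile(z, 0.1)].mean()
    assert top < bottom


def test_rating_calibration_mean_and_sd(default_config):
    """Pooled over datasets, 10,000 default-config ratings match the
    configured scale descriptives (mean 4.31, SD 1.25) within 3 SE."""
    ratings = []
    s = 0
    while len(ratings) < 10000:
        ds = generate_dataset(with_overrides(default_config, seed=500 + s))
        ratings.extend(ds.truth["rating"])
        s += 1
    r = np.asarray(ratings[:10000])
    se_mean = default_config.rating_sd / np.sqrt(len(r))
    se_sd = default_config.rating_sd / np.sqrt(2 * len(r))
    assert abs(r.mean() - default_config.rating_mean) < 3 * se_mean
    assert abs(r.std(ddof=1) - default_config.rating_sd) < 3 * se_sd


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def test_dataset_default_has_36_participants(default_config):
    ds = generate_dataset(default_config)
    assert ds.participants.shape[0] == 36
    assert set(ds.conversations["participant_id"]) <= set(
        ds.participants["participant_id"])


def test_dataset_reproducible_given_seed(small_config):
    a = generate_dataset(small_config, render_frames=True)
    b = generate_dataset(small_config, render_frames=True)
    assert a.truth.to_csv(index=False) == b.truth.to_csv(index=False)
    assert a.participants.to_csv(index=False) == \
        b.participants.to_csv(index=False)
    cid = a.conversations["conversation_id"].iloc[0]
    assert np.array_equal(a.tracks[cid].volume_db, b.tracks[cid].volume_db)


def test_dataset_minimum_viable_single_participant(default_config):
    cfg = with_overrides(default_config, n_participants=1,
                         conversations_per_participant=DistributionSpec(
                             3, 0, 3, 3))
    ds = generate_dataset(cfg)
    assert len(ds.conversations) == 3
    assert ds.participants.shape[0] == 1


def test_dataset_truth_features_consistent_with_segments(small_config):
    """True % speaking stored in the truth table equals an exact recount
    from the stored ground-truth segments."""
    ds = generate_dataset(small_config)
    for _, row in ds.truth.head(20).iterrows():
        f = true_features_from_segments(
            ds.segments[row["conversation_id"]],
            small_config.trailing_silence_s)
        assert row["pct_speaking"] == pytest.approx(f["pct_speaking"])
        assert row["turn_count"] == f["turn_count"]
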