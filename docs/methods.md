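# Methods

This note documents the models, parameters, and numerical choices behind
`convotrace`, and what the synthetic-data generator does and does not
emulate.

## The analysis model

Conversations (level 1) are nested in persons (level 2). The outcome is a
post-conversation enjoyment rating on a 1–7 scale; the predictors are five
conversation-level quantities, z-scored over all retained conversations
(grand-mean standardization) and entered simultaneously:

    rating_ij = γ0 + u_j + Σ_k β_k z_kij + ε_ij
    u_j  ~ N(0, τ²)      person-level random intercept
    ε_ij ~ N(0, σ²)      conversation-level residual

with k ∈ {conversation length (min), % speaking time, turn rate (/min),
volume SD (dB), pitch SD (Hz)}. Estimation is REML through statsmodels
`MixedLM` (ML available via `reml=False`; the test suite cross-checks ML
fixed effects against an independent maximization of the profiled marginal
likelihood). Random slopes are not modeled: the design has modest
observations per person and the scientific claim concerns average
within-person effects.

**Degrees of freedom.** Fixed-effect t-tests use between-within
(containment-style) df: level-1 effects are tested on
`n_obs − n_groups − p₁` df and level-2 (person-constant) effects on
`n_groups − p₂ − 1` df. Small-sample df conventions for mixed models are
not unique (Satterthwaite and Kenward–Roger exist and can differ); the
convention used is reported in every fit so p-values are interpretable.

**Why variability, not average, volume/pitch.** Average and SD of an
acoustic family are strongly collinear in conversation data; including
both invites multicollinearity. The model therefore uses the SD member of
each family. `collinearity_guard` computes and logs the observed mean/SD
correlation per family so the choice is auditable; a non-faithful mode
drops the mean member only when |r| exceeds a threshold (default 0.8).

**Standardization choice.** Grand-mean z-scoring is the default; a
within-person option exists (`zscore_predictors(..., within=...)`) but
changes the estimand (purely within-person contrasts) and is not used by
the default pipeline.

**Group comparisons.** Tie-type contrasts (strong vs weak ties) compare
conversation-level rows; between-person contrasts (e.g. gender differences
in pitch) first aggregate to participant means, then apply an
equal-variance two-sample t-test.

## The acoustic front end

- Frames of 32 ms with a 16 ms hop; at least two periods of the lowest
  F0 searched (65 Hz by default, covering the observed adult range of
  92–253 Hz) fit in one frame.
- Volume = 20·log10(frame RMS) in dBFS (0 dB = full-scale RMS). Digitally
  silent frames are clamped to −100 dB. Phone-study dB values are
  uncalibrated SPL-like numbers; only relative structure is comparable,
  and an optional `db_offset` aligns scales when needed.
- Pitch: normalized autocorrelation per frame (FFT-based), with an
  unbiased lag normalization (dividing lag τ by (N−τ)/N) so a pure tone
  peaks at ~1 and the taper cannot tilt the peak; parabolic interpolation
  refines the peak lag. Because a periodic signal correlates equally at
  every multiple of its period, the smallest local maximum within 0.05 of
  the global one is taken (subharmonic/octave protection). Frames whose
  peak falls below 0.5 yield "no pitch".
- Voicing: a frame is voiced iff its volume exceeds −45 dBFS *and* it is
  periodic (peak ≥ 0.5) or rescued by both neighbors being periodic
  (single-frame dropout repair). The rule is idempotent.

This front end is a deliberately simple, documented stand-in for the
validated privacy-sensitive feature extractors used on-device in
mobile-sensing studies; it never computes a representation from which
speech content could be reconstructed (no spectra, no formants, no MFCCs).

## Diarization

1-D k-means (k = 4) on the frame volumes, best of `n_restarts` (default
10) by WCSS, seeded and deterministic. For tracks of ≤ 4096 frames an
exact dynamic program over interval partitions (1-D k-means optima are
interval partitions) is run as an additional candidate, so oracle-scale
solutions are provably optimal. Clusters map to roles by descending
centroid volume: clothing noise ≻ participant ≻ other ≻ silence.

**Validity of the role mapping.** Two checks guard the mapping:

- exact centroid ties (< 1e−6 dB apart) are ambiguous and raise an error;
- adjacent centroids must be separated by ≥ 4 pooled within-cluster SDs.

The second check matters because the 4-regime interpretation can fail
*while k-means succeeds on its own objective*: when one regime holds more
than roughly ⅔ of the frames, splitting it in two reduces WCSS more than
keeping the rare clothing-noise cluster (≈1% of frames) separate, and the
global optimum genuinely abandons a regime. The two halves of a split
near-normal cluster sit ~2.7 within-SDs apart, while genuinely distinct
regimes sit ≳5.5 apart under the default spacing, so a threshold of 4
separates the cases cleanly. Under the generator's default conditions this
flags roughly half of conversations — consistent with the fact that
energy-only k = 4 diarization needs downstream exclusion rules at all —
and time-weighted role accuracy on the conversations that pass is ≥ 0.99.
Flagged conversations surface in the diarization report and QC as
failures; they are never silently relabeled.

**Smoothing.** The shortest run below the minimum speaking time (1.5 s)
is absorbed into its longer neighbor (ties and boundaries resolve to the
earlier neighbor), repeating until all runs are compliant or one run
remains; adjacent same-role runs merge. The fast implementation (linked
list + lazy heap) is oracle-tested against a quadratic re-implementation
of the same rule. Smoothing preserves total duration and applies to all
roles uniformly.

**Trailing silence.** The maximal non-speech suffix (silence, possibly
interrupted by clothing-noise bursts) is removed when it spans the
end-detection window (60 s), with 0.5 s slack for frame quantization.
Interior silences are untouched; the operation is idempotent.

## The synthetic-data generator

Defaults reproduce the scale and descriptive statistics of the kind of
EMA study the pipeline targets:

| quantity | default | note |
|---|---|---|
| participants | 36 | 58% female |
| conversations/person | lognormal, mean 13, SD 12, clipped 3–58 | |
| conversation length | lognormal, mean 8.6 min, SD 15.5, clipped 0.5–128 | |
| speaking fraction | normal(0.40, 0.22) clipped to feasibility | exact by construction |
| turn durations | lognormal mean 7 s, floor 1.5 s | → ~7 turns/min |
| role volumes | 70 / 57 / 45 / 20 dB, 2 dB frame jitter | person wobble 2 dB |
| clothing bursts | 1% of frames, 0.1–0.5 s | |
| F0 person means | ♀ N(207, 22), ♂ N(131, 18), clipped 92–253 Hz | |
| F0 contour | AR(1), φ = 0.99 per 16 ms frame | ~1.6 s timescale |
| rating scale | mean 4.31, SD 1.25, 1–7 integers | |
| speaking-% effect | β = −0.19 (standardized); other βs 0 | |
| random intercept SD | 0.70 (ICC ≈ 0.31) | |
| trailing silence | 60 s | |

Turn structure is an alternating semi-Markov process: participant and
partner turns alternate, with optional ≥1.5 s silence gaps at internal
boundaries; turn durations are drawn then rescaled so the realized
speaking fraction equals the sampled target exactly. The trailing
one-minute silence block is always appended.

Ratings come from the two-level model above using dataset-level z-scores
of the *true* features, then are rounded to the nearest integer and
clipped to [1, 7]. Discretization adds ≈1/12 rounding variance and
slightly attenuates recoverable effects, so the residual SD is derived as

    σ² = rating_sd² − τ² − Σ β_k² − 1/12·[discretize]

which makes the *observed* rating SD match the configured 1.25. Clipping
at the scale ends biases the mean by only ≈ −0.004. Individual differences
(Big Five, age, gender) are generated with zero true effect on ratings.

Waveform rendering (for exercising the WAV front end) realizes speech as
harmonic tone complexes (3 harmonics) at the frame F0 — the participant's
contour for participant turns, a distinct per-conversation F0 for the
partner — with per-frame RMS following the frame track's volume, mapped to
dBFS by `full_scale_db` (73 dB ↦ 0 dBFS, leaving crest-factor headroom).
Silence is near-zero noise. When the frame track is passed in, the
waveform path and the direct path agree frame-by-frame (≤1 dB volume,
≤2 Hz pitch away from segment boundaries in the noise-free limit).

**What the generator does *not* emulate** — and hence what passing tests
do not show about real data: phonetically realistic speech (formants,
consonants, amplitude modulation within syllables), overlapping speech,
within-regime volume dynamics beyond white jitter, room acoustics and
device variation, missing ratings, and any systematic relation between
acoustics and enjoyment beyond the configured linear effects. Parameter
recovery results demonstrate correctness of the estimation machinery under
the generating model, not robustness to real-world misspecification.

## QC

The five exclusion rules are evaluated simultaneously against thresholds
computed once from the full pre-exclusion batch (single pass, no
iterative re-trimming; re-running with frozen thresholds excludes nothing
new). `negative_speaking_time` cannot be produced by this pipeline — it
guarded file corruption in the kind of study this reproduces — but is
retained to validate imported external feature tables. The participant
filter keeps persons with ≥ 3 retained conversations (boundary
inclusive), the practical minimum for a random-intercept fit.

## Problem sizes used by the test suite and acceptance script

Simulation-based checks use: 200 datasets of 36 participants for
recovery of the speaking-percentage effect (continuous latent ratings,
Monte-Carlo tolerance ±0.02); 10,000 pooled ratings for calibration;
100 conversations for the smoothing contract; 200 random label sequences
and 20 random 60-frame tracks for the oracle equivalences; 8–16
default-scale conversations for diarization/feature recovery. These sizes
give Monte-Carlo error comfortably inside each tolerance while keeping a
full run near a minute.

## Known limitations

- The cluster-separation threshold (4 within-SDs) is calibrated to the
  default volume geometry; very different regime spacings may need a
  different ratio.
- Between-within df are a convention; small-sample p-values differ under
  Satterthwaite/Kenward–Roger.
- The pitch estimator assumes quasi-stationary F0 within a 32 ms frame;
  it is not a production pitch tracker.
- 1-D k-means diarization has no concept of overlapping speech and no
  speaker model: it identifies *volume regimes*, which coincide with
  speakers only under the near-phone/far-phone geometry assumed here.
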