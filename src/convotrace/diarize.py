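"""Volume-based speaker diarization.

Each conversation's frame-level volume series is clustered with k-means
(k = 4 in faithful mode) into the four volume regimes, the clusters are
mapped to roles by descending centroid volume (clothing noise > participant
> other speakers > silence), the frame labels are smoothed so that no
segment is shorter than a minimum speaking time (1.5 s by default), and the
trailing silence block the recording app needed to detect conversation end
is removed.

Because the data are one-dimensional, the globally optimal k-means solution
is an interval partition of the sorted volumes.  For small tracks we
therefore add an exact dynamic-programming candidate alongside the random
Lloyd restarts and keep whichever has the lower within-cluster sum of
squares (WCSS); on large tracks the regimes are well separated and Lloyd's
algorithm with k-means++ restarts is reliable and fast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datatypes import (
    ConfigurationError,
    DataError,
    DiarizedSegment,
    FrameTrack,
    ROLE_ORDER,
    validate_segments,
)

__all__ = [
    "DiarizationConfig",
    "AmbiguousRolesError",
    "cluster_frames",
    "assign_roles",
    "smooth_segments",
    "trim_trailing_silence",
    "diarize_track",
]

#: Track size up to which the exact 1-D dynamic program is run in addition
#: to Lloyd restarts (O(k n^2) cost).
_EXACT_DP_MAX_N = 4096


class AmbiguousRolesError(ValueError):
    """Two centroids coincide, so the volume ordering cannot assign roles."""


@dataclass(frozen=True)
class DiarizationConfig:
    """Clustering and smoothing parameters (paper-faithful defaults)."""

    k: int = 4
    n_restarts: int = 10
    seed: int = 0
    min_segment_s: float = 1.5
    trailing_silence_window_s: float = 60.0
    #: slack on the trailing window so frame quantization (a trailing
    #: block never aligns exactly with the frame grid) cannot keep an
    #: end-of-conversation silence from being recognized
    trailing_tolerance_s: float = 0.5

    def validate(self) -> None:
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")
        if self.n_restarts < 1:
            raise ConfigurationError("n_restarts must be >= 1")
        if self.min_segment_s <= 0:
            raise ConfigurationError("min_segment_s must be > 0")


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _wcss(x: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    return float(np.sum((x - centroids[labels]) ** 2))


def _exact_1d_kmeans(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Globally optimal 1-D k-means via DP over interval partitions.

    Returns (labels, centroids) on the original ordering of ``x``.
    """
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = len(xs)
    c1 = np.concatenate(([0.0], np.cumsum(xs)))
    c2 = np.concatenate(([0.0], np.cumsum(xs ** 2)))

    def seg_cost(i: int, j: np.ndarray) -> np.ndarray:
        # SSE of xs[i:j] around its mean, vectorized over j (j > i)
        m = j - i
        s = c1[j] - c1[i]
        return (c2[j] - c2[i]) - s * s / m

    INF = np.inf
    # cost[c][j] = optimal SSE of xs[:j] with c clusters
    cost = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    js = np.arange(1, n + 1)
    cost[1][1:] = seg_cost(0, js)
    for c in range(2, k + 1):
        for j in range(c, n + 1):
            i = np.arange(c - 1, j)
            cand = cost[c - 1][i] + seg_cost_vec(c1, c2, i, j)
            b = int(np.argmin(cand))
            cost[c][j] = cand[b]
            back[c][j] = i[b]
    labels_sorted = np.empty(n, dtype=int)
    j = n
    for c in range(k, 0, -1):
        i = back[c][j] if c > 1 else 0
        labels_sorted[i:j] = c - 1
        j = i
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    centroids = np.array([x[labels == c].mean() for c in range(k)])
    return labels, centroids


def seg_cost_vec(c1: np.ndarray, c2: np.ndarray, i: np.ndarray,
                 j: int) -> np.ndarray:
    """SSE of sorted prefix slices xs[i:j] around their means, i vectorized."""
    m = j - i
    s = c1[j] - c1[i]
    return (c2[j] - c2[i]) - s * s / m


def cluster_frames(track: FrameTrack,
                   config: DiarizationConfig = DiarizationConfig(),
                   ) -> tuple[np.ndarray, np.ndarray]:
    """K-means on the 1-D volume series; best of ``n_restarts`` by WCSS.

    Returns ``(labels, centroids)`` with centroids indexed by cluster id.
    Deterministic given ``config.seed``.  Raises :class:`DataError` when
    the track has fewer than k distinct volume values.
    """
    config.validate()
    x = track.volume_db.astype(float)
    if len(np.unique(x)) < config.k:
        raise DataError(
            f"conversation {track.conversation_id}: fewer than "
            f"{config.k} distinct volume values; cannot cluster")

    from sklearn.cluster import KMeans
    km = KMeans(n_clusters=config.k, n_init=config.n_restarts,
                random_state=config.seed % (2 ** 31))
    labels = km.fit_predict(x[:, None])
    centroids = km.cluster_centers_.ravel()
    best = _wcss(x, labels, centroids)

    if len(x) <= _EXACT_DP_MAX_N:
        dp_labels, dp_centroids = _exact_1d_kmeans(x, config.k)
        if _wcss(x, dp_labels, dp_centroids) < best - 1e-12:
            labels, centroids = dp_labels, dp_centroids
    return labels, centroids


def assign_roles(centroids: np.ndarray,
                 tie_tol_db: float = 1e-6,
                 within_sd_db: float | None = None,
                 separation_min_ratio: float = 4.0) -> dict[int, str]:
    """Map cluster ids to roles by descending centroid volume.

    Loudest cluster = clothing noise, then participant, other, silence.
    Centroids closer than ``tie_tol_db`` make the ordering ambiguous and
    raise :class:`AmbiguousRolesError`; callers surface this through QC
    rather than guessing.

    When ``within_sd_db`` (pooled within-cluster SD) is supplied, a
    sensitivity criterion is applied as well: adjacent centroids must be
    separated by at least ``separation_min_ratio`` within-cluster SDs.
    A conversation that genuinely lacks one volume regime makes k = 4
    k-means split some other regime in two instead, and the two halves of
    a split (roughly normal) cluster end up only ~2.7 within-SDs apart,
    while genuinely distinct regimes sit far wider; such solutions carry
    no valid role ordering and are flagged, not silently fixed.
    """
    centroids = np.asarray(centroids, dtype=float)
    if len(centroids) != len(ROLE_ORDER):
        raise ConfigurationError(
            f"expected {len(ROLE_ORDER)} centroids, got {len(centroids)}")
    if not np.all(np.isfinite(centroids)):
        raise DataError("non-finite centroid")
    order = np.argsort(-centroids, kind="stable")
    ranked = centroids[order]
    gaps = -np.diff(ranked)
    if np.any(gaps <= tie_tol_db):
        raise AmbiguousRolesError(
            f"tied centroids (within {tie_tol_db} dB): {sorted(centroids)}")
    if within_sd_db is not None and within_sd_db > 0:
        if gaps.min() < separation_min_ratio * within_sd_db:
            raise AmbiguousRolesError(
                f"cluster separation too small for role assignment: min "
                f"adjacent centroid gap {gaps.min():.2f} dB < "
                f"{separation_min_ratio} x within-cluster SD "
                f"{within_sd_db:.2f} dB (likely a split/collapsed regime)")
    return {int(order[r]): ROLE_ORDER[r] for r in range(len(order))}


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def _runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of equal labels as (start_index, length) pairs."""
    n = len(labels)
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [n])))
    return list(zip(starts.tolist(), lengths.tolist()))


def smooth_segments(frame_labels, frame_hop_s: float,
                    config: DiarizationConfig = DiarizationConfig(),
                    t0: float = 0.0) -> list[DiarizedSegment]:
    """Absorb sub-minimum runs until every segment lasts >= min_segment_s.

    Iteratively the shortest run below the minimum duration is merged into
    whichever neighbor run is longer (ties and boundaries resolved toward
    the earlier neighbor); absorbed frames inherit the neighbor's role and
    adjacent same-role runs merge.  The loop ends when all runs meet the
    minimum or a single run remains.  Total duration is preserved.

    ``frame_labels`` may be any per-frame label sequence (role strings or
    cluster ids mapped through roles beforehand).  Returns maximal-run
    :class:`DiarizedSegment` objects starting at ``t0``.
    """
    labels = np.asarray(frame_labels, dtype=object)
    if labels.size == 0:
        raise DataError("empty frame-label sequence")
    if frame_hop_s <= 0:
        raise ConfigurationError("frame_hop_s must be > 0")
    min_frames = config.min_segment_s / frame_hop_s

    import heapq

    runs = _runs(labels)  # list of (start, length)
    role = [labels[s] for s, _ in runs]
    length = [ln for _, ln in runs]
    alive = [True] * len(runs)
    prev = list(range(-1, len(runs) - 1))
    nxt = list(range(1, len(runs) + 1))
    nxt[-1] = -1
    n_alive = len(runs)

    def unlink(i: int) -> None:
        nonlocal n_alive
        alive[i] = False
        n_alive -= 1
        if prev[i] != -1:
            nxt[prev[i]] = nxt[i]
        if nxt[i] != -1:
            prev[nxt[i]] = prev[i]

    heap = [(ln, i) for i, ln in enumerate(length) if ln < min_frames]
    heapq.heapify(heap)

    while heap and n_alive > 1:
        ln, i = heapq.heappop(heap)
        if not alive[i] or length[i] != ln:
            continue  # stale heap entry
        p, q = prev[i], nxt[i]
        if p == -1 and q == -1:
            break
        # absorb into the longer neighbor; ties and boundaries -> earlier
        if q == -1 or (p != -1 and length[p] >= length[q]):
            target = p
        else:
            target = q
        unlink(i)
        length[target] += length[i]
        # absorbing may have made target adjacent to a same-role run
        while (prev[target] != -1
               and role[prev[target]] == role[target]):
            p2 = prev[target]
            length[p2] += length[target]
            unlink(target)
            target = p2
        while (nxt[target] != -1
               and role[nxt[target]] == role[target]):
            q2 = nxt[target]
            length[target] += length[q2]
            unlink(q2)
        if length[target] < min_frames:
            heapq.heappush(heap, (length[target], target))

    head = next(i for i in range(len(runs)) if alive[i])
    segments: list[DiarizedSegment] = []
    t = t0
    i = head
    while i != -1:
        dur = length[i] * frame_hop_s
        if segments and segments[-1].role == role[i]:
            segments[-1] = DiarizedSegment(segments[-1].start_s, t + dur,
                                           role[i])
        else:
            segments.append(DiarizedSegment(t, t + dur, role[i]))
        t += dur
        i = nxt[i]
    validate_segments(segments)
    return segments


def smooth_segments_bruteforce(frame_labels, frame_hop_s: float,
                               config: DiarizationConfig = DiarizationConfig(),
                               ) -> list[DiarizedSegment]:
    """Reference implementation of the same absorb-until-fixpoint rule.

    Quadratic list-based rewrite used as the oracle in tests; kept in the
    package so external users can cross-check the fast path.
    """
    labels = list(frame_labels)
    if not labels:
        raise DataError("empty frame-label sequence")
    min_frames = config.min_segment_s / frame_hop_s

    def to_runs(lab):
        runs = []
        for x in lab:
            if runs and runs[-1][0] == x:
                runs[-1][1] += 1
            else:
                runs.append([x, 1])
        return runs

    runs = to_runs(labels)
    while len(runs) > 1:
        short = [(ln, i) for i, (_, ln) in enumerate(runs) if ln < min_frames]
        if not short:
            break
        _, i = min(short)
        left_len = runs[i - 1][1] if i > 0 else -1
        right_len = runs[i + 1][1] if i + 1 < len(runs) else -1
        target = i - 1 if left_len >= right_len else i + 1
        runs[target][1] += runs[i][1]
        del runs[i]
        # merge adjacent same-role runs
        j = 1
        while j < len(runs):
            if runs[j][0] == runs[j - 1][0]:
                runs[j - 1][1] += runs[j][1]
                del runs[j]
            else:
                j += 1
    out = []
    t = 0.0
    for lab, ln in runs:
        dur = ln * frame_hop_s
        out.append(DiarizedSegment(t, t + dur, lab))
        t += dur
    return out


# ---------------------------------------------------------------------------
# trailing-silence removal
# ---------------------------------------------------------------------------

def trim_trailing_silence(segments: list[DiarizedSegment],
                          config: DiarizationConfig = DiarizationConfig(),
                          ) -> list[DiarizedSegment]:
    """Drop the end-of-conversation silence block when it spans the app's
    end-detection window (default 60 s).  Idempotent; earlier silence is
    untouched.

    The trailing block is the maximal suffix of non-speech segments
    (silence, possibly interrupted by clothing-noise bursts — the phone
    keeps rubbing while nobody talks); it is removed as a whole when its
    total duration reaches the window, since no part of it belongs to the
    conversation.
    """
    if not segments:
        raise DataError("empty segment list")
    from .datatypes import SPEECH_ROLES
    i = len(segments)
    while i > 0 and segments[i - 1].role not in SPEECH_ROLES:
        i -= 1
    if i == 0:
        raise DataError("conversation is entirely silence/noise")
    tail = segments[i:]
    window = config.trailing_silence_window_s - config.trailing_tolerance_s
    if tail and sum(s.duration_s for s in tail) >= window:
        return segments[:i]
    return segments


# ---------------------------------------------------------------------------
# end-to-end per-conversation driver
# ---------------------------------------------------------------------------

def diarize_track(track: FrameTrack,
                  config: DiarizationConfig = DiarizationConfig(),
                  ) -> tuple[list[DiarizedSegment], dict]:
    """Cluster → assign roles → smooth → trim for one conversation.

    Returns the trimmed segments and a report dict (centroids, WCSS, role
    map) suitable for JSON serialization.
    """
    labels, centroids = cluster_frames(track, config)
    wcss = _wcss(track.volume_db.astype(float), labels, centroids)
    within_sd = math.sqrt(wcss / track.n_frames)
    role_map = assign_roles(centroids, within_sd_db=within_sd)
    frame_roles = np.array([role_map[int(c)] for c in labels], dtype=object)
    segments = smooth_segments(frame_roles, track.frame_hop_s, config,
                               t0=float(track.t_s[0]))
    segments = trim_trailing_silence(segments, config)
    report = {
        "conversation_id": track.conversation_id,
        "centroids_db": sorted(float(c) for c in centroids),
        "wcss": _wcss(track.volume_db.astype(float), labels, centroids),
        "role_map": {str(k): v for k, v in role_map.items()},
        "n_segments": len(segments),
    }
    return segments, report
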