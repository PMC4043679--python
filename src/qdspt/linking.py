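"""Trajectory linking, blink-tolerant re-linking, and duplicate removal.

Three stages, matching the experimental post-processing pipeline:

1. :func:`link_detections` — greedy frame-to-frame nearest-neighbour
   linking of raw detections, bridging up to ``link_range`` missing frames
   (this stage exists to exercise synthetic data end-to-end; experimental
   data arrives already linked by the detection software).
2. :func:`relink_trajectories` — coincidence search in time and space that
   re-joins trajectory fragments created by fluorophore blinking: an
   earlier-ending fragment A is merged with a later-starting fragment B if
   the dark gap is shorter than ``max_gap`` frames and the squared
   end-to-start distance is below ``gap_scale × gap`` px².  Only
   trajectories longer than ``min_len`` displacements survive the final cut.
3. :func:`remove_cross_channel_duplicates` — deletes trajectories that
   appear in more than one spectral detection channel (spectral bleed), by
   coincidence of positions on shared frames.

All three stages only regroup localizations; no coordinate or frame value
is ever altered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import Trajectory, TrackSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LinkParams:
    """Frame-to-frame linking parameters (conservative defaults: link range
    4–5 frames, two pixels maximum displacement per frame)."""

    link_range: int = 5       # frames a track may bridge
    max_disp: float = 2.0     # pixels per frame

    def __post_init__(self) -> None:
        if self.link_range < 1:
            raise ValueError("link_range must be >= 1")
        if self.max_disp <= 0:
            raise ValueError("max_disp must be > 0")


@dataclass(frozen=True)
class RelinkParams:
    """Coincidence-search re-linking parameters.

    Defaults: keep tracks with more than 50 displacements, close dark gaps
    shorter than 100 frames when the squared end-to-start separation is
    below 0.1×gap px².
    """

    min_len: int = 50         # displacements; strictly-greater filter
    max_gap: int = 100        # frames; strictly-less criterion
    gap_scale: float = 0.1    # px² per gap frame

    def __post_init__(self) -> None:
        if self.min_len < 1 or self.max_gap < 1 or self.gap_scale <= 0:
            raise ValueError("all relink parameters must be positive")


def link_detections(detections, params: LinkParams = LinkParams(),
                    channel: str = "") -> list[Trajectory]:
    """Greedy nearest-neighbour linking of per-frame detections.

    ``detections`` is a list of :class:`~qdspt.core.Localization` sorted by
    frame (a single channel).  Open tracks accept the nearest detection in
    the next frames; a candidate at a gap of g missing frames must lie
    within ``max_disp × (g + 1)`` pixels of the track end, and a track is
    closed once ``link_range`` frames pass without an assignment.
    Unassigned detections seed new tracks.  Returns the linked trajectories
    (pixels); degenerate input yields an empty list.
    """
    by_frame: dict[int, list] = {}
    for det in detections:
        by_frame.setdefault(det.frame, []).append(det)
    if not by_frame:
        return []

    open_tracks: list[dict] = []   # each: frames, xy, last taken frame
    closed: list[dict] = []
    for frame in sorted(by_frame):
        dets = by_frame[frame]
        still_open = []
        for tr in open_tracks:
            if frame - tr["frames"][-1] > params.link_range:
                closed.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open

        # candidate (distance, track, detection) pairs within the gate
        pairs = []
        for ti, tr in enumerate(open_tracks):
            gap = frame - tr["frames"][-1]       # >= 1
            gate = params.max_disp * gap
            tx, ty = tr["xy"][-1]
            for di, det in enumerate(dets):
                dist = np.hypot(det.x - tx, det.y - ty)
                if dist <= gate:
                    pairs.append((dist, ti, di))
        pairs.sort(key=lambda p: (p[0], p[1], p[2]))
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for dist, ti, di in pairs:
            if ti in used_tracks or di in used_dets:
                continue
            used_tracks.add(ti)
            used_dets.add(di)
            det = dets[di]
            open_tracks[ti]["frames"].append(det.frame)
            open_tracks[ti]["xy"].append((det.x, det.y))
        for di, det in enumerate(dets):
            if di not in used_dets:
                open_tracks.append(
                    {"frames": [det.frame], "xy": [(det.x, det.y)]})
    closed.extend(open_tracks)
    closed.sort(key=lambda tr: (tr["frames"][0], tr["xy"][0]))
    return [
        Trajectory(id=f"track{i:05d}", frames=tr["frames"],
                   xy=np.array(tr["xy"]), channel=channel)
        for i, tr in enumerate(closed)
    ]


def _eligible(a: Trajectory, b: Trajectory, params: RelinkParams):
    """Merge score for fragment pair (a ends before b starts), or None."""
    gap = b.start_frame - a.end_frame
    if gap <= 0 or gap >= params.max_gap:
        return None
    dx = b.xy[0] - a.xy[-1]
    sq = float(dx[0] ** 2 + dx[1] ** 2)
    if sq >= params.gap_scale * gap:
        return None
    return sq / gap


def relink_trajectories(
    tracks: TrackSet, params: RelinkParams = RelinkParams()
) -> TrackSet:
    """Re-join blink-fragmented trajectories by time/space coincidence.

    Fragments are processed by ascending end frame; each is merged with the
    *earliest-starting* eligible partner, ties broken by the smaller
    (squared distance / gap) score.  Preferring the earliest continuation
    keeps a blinking particle's fragment chain intact: a pure best-score
    rule would bridge the longest eligible gap (the score falls with gap
    for a near-immobile particle) and strand the fragments in between.
    Merging repeats until no eligible pair remains; no positions are
    interpolated across the dark gaps, so merged tracks simply have missing
    frames.  Finally only trajectories with more than ``min_len``
    displacements are retained.

    Coordinates are expected in pixels (the spatial criterion is in px²).
    """
    pool = list(tracks.trajectories)
    changed = True
    while changed:
        changed = False
        pool.sort(key=lambda t: t.end_frame)
        merged_pool: list[Trajectory] = []
        consumed: set[int] = set()
        for i, a in enumerate(pool):
            if i in consumed:
                continue
            best = None
            for j in range(len(pool)):
                if j == i or j in consumed:
                    continue
                b = pool[j]
                score = _eligible(a, b, params)
                if score is None:
                    continue
                key = (b.start_frame, score)
                if best is None or key < best[0]:
                    best = (key, j)
            if best is None:
                merged_pool.append(a)
                continue
            j = best[1]
            b = pool[j]
            consumed.add(j)
            merged = Trajectory(
                id=a.id,
                frames=np.concatenate([a.frames, b.frames]),
                xy=np.vstack([a.xy, b.xy]),
                channel=a.channel,
                unit=a.unit,
                merged_from=(a.merged_from or [a.id]) + (b.merged_from
                                                         or [b.id]),
            )
            merged_pool.append(merged)
            changed = True
        pool = merged_pool
    kept = [t for t in pool if t.n_displacements > params.min_len]
    logger.info("relink: %d fragments -> %d merged tracks, %d pass the "
                "min-length cut", len(tracks), len(pool), len(kept))
    return TrackSet(kept, tracks.meta, tracks.condition)


def remove_cross_channel_duplicates(
    per_channel: list[TrackSet],
    radius: float = 1.0,
    min_overlap_fraction: float = 0.8,
) -> list[TrackSet]:
    """Delete trajectories detected in more than one spectral channel.

    For every cross-channel trajectory pair sharing at least one frame, if
    at least ``min_overlap_fraction`` of the shared-frame position pairs lie
    within ``radius`` (same unit as the coordinates), the copy in the
    lower-priority channel (later in the input list) is removed.  Removals
    are logged.
    """
    if len(per_channel) < 2:
        return list(per_channel)
    removed: dict[int, set[str]] = {i: set() for i in range(len(per_channel))}
    for i in range(len(per_channel)):
        for j in range(i + 1, len(per_channel)):
            for ta in per_channel[i]:
                if ta.id in removed[i]:
                    continue
                for tb in per_channel[j]:
                    if tb.id in removed[j]:
                        continue
                    shared, ia, ib = np.intersect1d(
                        ta.frames, tb.frames, return_indices=True)
                    if shared.size == 0:
                        continue
                    d = np.linalg.norm(ta.xy[ia] - tb.xy[ib], axis=1)
                    frac = float(np.mean(d <= radius))
                    if frac >= min_overlap_fraction:
                        removed[j].add(tb.id)
                        logger.info(
                            "dedupe: removed %r from channel %d "
                            "(duplicate of %r, overlap %.2f)",
                            tb.id, j, ta.id, frac)
    return [
        TrackSet([t for t in ts if t.id not in removed[i]], ts.meta,
                 ts.condition)
        for i, ts in enumerate(per_channel)
    ]
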