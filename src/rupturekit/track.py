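"""Frame-to-frame linking of nucleus detections into tracks.

Detections are connected through time by nearest-neighbor assignment bounded
by a maximum displacement; a track whose nucleus goes undetected for a frame
(focus loss, transient segmentation failure) probes up to ``max_gap``
subsequent frames with a displacement budget that grows linearly with the
gap length. Contention between tracks for the same detection is resolved
greedily by ascending centroid distance (on these sparse scenes this is the
Hungarian optimum), with ties broken by the lower track id. Short tracks
(< 60 min by default) are removed before any kinetic analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Track",
    "TrackSet",
    "link_tracks",
    "filter_tracks",
    "interpolate_gaps",
    "tracks_to_dataframe",
]

TRACE_COLUMNS = [
    "y", "x", "area", "perimeter", "circularity", "mean_ref", "mean_rep",
]


@dataclass
class Track:
    """Time-ordered detections of one nucleus."""

    track_id: int
    frames: list[int] = field(default_factory=list)
    rows: list[int] = field(default_factory=list)  # indices into detections

    @property
    def first_frame(self) -> int:
        return self.frames[0]

    @property
    def last_frame(self) -> int:
        return self.frames[-1]

    @property
    def gap_frames(self) -> list[int]:
        present = set(self.frames)
        return [
            f for f in range(self.first_frame, self.last_frame + 1)
            if f not in present
        ]

    def duration(self, frame_interval: float) -> float:
        """Track duration in minutes."""
        return (self.last_frame - self.first_frame) * frame_interval


@dataclass
class TrackSet:
    tracks: list[Track]
    detections: pd.DataFrame
    frame_interval: float
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.tracks)


def link_tracks(
    detections: pd.DataFrame,
    frame_interval: float,
    max_displacement: float = 40.0,
    max_gap: int = 5,
) -> TrackSet:
    """Link a detection table (columns frame, y, x, ...) into tracks.

    A track end at frame ``f0`` may claim a detection at frame ``f0+g+1``
    (``g <= max_gap`` missed frames) if the centroid moved less than
    ``max_displacement * (g + 1)``. Unclaimed detections seed new tracks.
    The outcome is invariant to the ordering of detections within a frame.
    """
    if max_displacement <= 0:
        raise ValueError("max_displacement must be positive")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    det = detections.reset_index(drop=True)
    tracks: list[Track] = []
    open_tracks: list[Track] = []
    last_pos: dict[int, np.ndarray] = {}  # track_id -> last centroid
    if len(det):
        frames = range(int(det["frame"].min()), int(det["frame"].max()) + 1)
        all_coords = det[["y", "x"]].to_numpy(float)
        frame_col = det["frame"].to_numpy()
    else:
        frames = range(0)
    for f in frames:
        open_tracks = [t for t in open_tracks if f - t.last_frame <= max_gap + 1]
        rows = np.flatnonzero(frame_col == f)
        if not rows.size:
            continue
        coords = all_coords[rows]
        # deterministic candidate ordering regardless of input order
        order = np.lexsort((coords[:, 1], coords[:, 0]))
        coords, row_ids = coords[order], rows[order]
        claimed = np.zeros(len(row_ids), dtype=bool)
        candidates = []
        for t in open_tracks:
            gap = f - t.last_frame - 1
            budget = max_displacement * (gap + 1)
            dist = np.hypot(*(coords - last_pos[t.track_id]).T)
            for j in np.flatnonzero(dist <= budget):
                candidates.append((float(dist[j]), t.track_id, int(j), t))
        used_tracks: set[int] = set()
        for dist, tid, j, t in sorted(candidates, key=lambda c: (c[0], c[1], c[2])):
            if claimed[j] or tid in used_tracks:
                continue
            claimed[j] = True
            used_tracks.add(tid)
            t.frames.append(f)
            t.rows.append(int(row_ids[j]))
            last_pos[tid] = coords[j]
        for j in np.flatnonzero(~claimed):
            t = Track(track_id=len(tracks), frames=[f], rows=[int(row_ids[j])])
            tracks.append(t)
            open_tracks.append(t)
            last_pos[t.track_id] = coords[j]
    return TrackSet(
        tracks=tracks,
        detections=det,
        frame_interval=frame_interval,
        params={"max_displacement": max_displacement, "max_gap": max_gap},
    )


def filter_tracks(trackset: TrackSet, min_duration: float = 60.0) -> TrackSet:
    """Remove short tracks (duration strictly below ``min_duration`` minutes)."""
    if min_duration < 0:
        raise ValueError("min_duration must be >= 0")
    kept = [
        t for t in trackset.tracks
        if t.duration(trackset.frame_interval) >= min_duration
    ]
    return TrackSet(
        tracks=kept,
        detections=trackset.detections,
        frame_interval=trackset.frame_interval,
        params={**trackset.params, "min_duration": min_duration},
    )


def interpolate_gaps(track: Track, trackset: TrackSet) -> pd.DataFrame:
    """Per-frame trace of one track with gap frames linearly interpolated.

    Returns a table with one row per frame from the track's first to last
    detection: frame, time_min, the measurement columns, and ``is_gap``
    flagging interpolated rows (rupture calls are never anchored on these).
    Values are never extrapolated beyond the track's endpoints.
    """
    det = trackset.detections
    frames = np.arange(track.first_frame, track.last_frame + 1)
    have = np.asarray(track.frames)
    out = pd.DataFrame({"frame": frames})
    out["time_min"] = frames * trackset.frame_interval
    cols = [c for c in TRACE_COLUMNS if c in det.columns]
    src = det.loc[track.rows]
    for c in cols:
        out[c] = np.interp(frames, have, src[c].to_numpy(float))
    out["is_gap"] = ~np.isin(frames, have)
    out["track_id"] = track.track_id
    return out


def tracks_to_dataframe(trackset: TrackSet) -> pd.DataFrame:
    """Tidy long table of all tracks (gap frames included and flagged)."""
    if not trackset.tracks:
        cols = ["track_id", "frame", "time_min"] + TRACE_COLUMNS + ["is_gap"]
        return pd.DataFrame(columns=cols)
    parts = [interpolate_gaps(t, trackset) for t in trackset.tracks]
    df = pd.concat(parts, ignore_index=True)
    lead = ["track_id", "frame", "time_min"]
    rest = [c for c in df.columns if c not in lead]
    return df[lead + rest]
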