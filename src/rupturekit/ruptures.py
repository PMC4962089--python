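"""Rupture detection, in-silico synchronization and recovery kinetics.

A nuclear-envelope rupture empties part of the nuclear NLS reporter into the
cytoplasm while the chromatin-bound reference (H2B) signal is untouched, so
the per-nucleus H2B/NLS mean-intensity ratio jumps up at rupture onset. The
detection statistic dH/N is the *multiplicative* frame-to-frame fold change
of that ratio, ratio(t)/ratio(t-1): a unit-free quantity that is exactly
invariant to any global per-frame scaling of both channels (focus dips,
illumination drift) and for which the canonical operating point is a fixed
threshold of 1.2, i.e. a 20% step increase of the ratio.

Detected events are then characterized on the unsmoothed reporter trace
(pre-rupture baseline, post-rupture minimum, fractional extent, recovery
halftime T_r) and can be synchronized to a common onset to form ensemble
recovery curves, exactly as stochastic, asynchronous events must be pooled
to study their kinetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

__all__ = [
    "IntensityTrace",
    "RuptureEvent",
    "SynchronizedEnsemble",
    "compute_ratio_derivative",
    "detect_rupture_events",
    "characterize_event",
    "extract_events",
    "synchronize_events",
    "rupture_frequency",
    "circularity_cov",
    "initial_recovery_slope",
    "events_to_dataframe",
]

DEFAULT_THRESHOLD = 1.2  # dH/N cutoff: 20% ratio increase
DEFAULT_BASELINE_WINDOW = 5  # frames
DEFAULT_COMPLETENESS = 0.95  # "restored completely" = back to >=95% of baseline
FAST_SLOW_BOUNDARY_MIN = 30.0  # fast (T_r <= 30 min) vs slow populations
DEFAULT_MAX_AREA_JUMP = 0.35  # fractional area change that flags a merge artifact
# a dH/N crossing of 1.2 implies a genuine reporter drop of ~17% when the
# reference is stable; calls whose measured amplitude drop stays far below
# that are internally inconsistent (segmentation artifacts) and are vetoed
DEFAULT_MIN_EXTENT = 0.1


@dataclass
class IntensityTrace:
    """Two-channel intensity trace of one tracked nucleus.

    ``ref`` and ``rep`` are the per-frame mean H2B and NLS intensities on a
    uniform time grid (minutes); ``is_gap`` flags frames whose values were
    interpolated across a tracking gap. ``detection_sigma_t`` optionally
    applies a Gaussian temporal smoothing (minutes) to the reporter series
    used for the dH/N statistic only; kinetic quantities (baseline, minimum,
    halftime) are always measured on the raw series.
    """

    track_id: int
    time_min: np.ndarray
    ref: np.ndarray
    rep: np.ndarray
    is_gap: np.ndarray | None = None
    circularity: np.ndarray | None = None
    area: np.ndarray | None = None
    detection_sigma_t: float = 0.0

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.ref = np.asarray(self.ref, dtype=float)
        self.rep = np.asarray(self.rep, dtype=float)
        n = len(self.time_min)
        if len(self.ref) != n or len(self.rep) != n:
            raise ValueError("time, ref and rep series must have equal length")
        if self.is_gap is None:
            self.is_gap = np.zeros(n, dtype=bool)
        else:
            self.is_gap = np.asarray(self.is_gap, dtype=bool)
        bad = np.flatnonzero(self.rep <= 0)
        if bad.size:
            raise ValueError(
                f"track {self.track_id}: non-positive reporter intensity at "
                f"frame index {int(bad[0])}"
            )

    @property
    def n_frames(self) -> int:
        return len(self.time_min)

    @property
    def frame_interval(self) -> float:
        if self.n_frames < 2:
            return float("nan")
        return float(self.time_min[1] - self.time_min[0])

    @property
    def ratio(self) -> np.ndarray:
        """H2B/NLS ratio on the series used for event detection."""
        return self.ref / self._rep_detect()

    def _rep_detect(self) -> np.ndarray:
        if self.detection_sigma_t > 0:
            return ndi.gaussian_filter1d(
                self.rep, self.detection_sigma_t / self.frame_interval,
                mode="nearest",
            )
        return self.rep

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "IntensityTrace":
        """Build from one track's tidy trace table (see ``track`` module)."""
        tid = int(df["track_id"].iloc[0]) if "track_id" in df else -1
        return cls(
            track_id=tid,
            time_min=df["time_min"].to_numpy(),
            ref=df["mean_ref"].to_numpy(),
            rep=df["mean_rep"].to_numpy(),
            is_gap=df["is_gap"].to_numpy() if "is_gap" in df else None,
            circularity=(
                df["circularity"].to_numpy() if "circularity" in df else None
            ),
            area=df["area"].to_numpy() if "area" in df else None,
            **kwargs,
        )


@dataclass
class RuptureEvent:
    """One detected rupture with its recovery characterization.

    ``extent`` is the fractional NLS drop from the pre-rupture baseline to
    the post-rupture minimum; ``t_r`` the recovery halftime in minutes
    (time from onset until the reporter crosses halfway back from the
    minimum toward the baseline), present only for complete recoveries.
    """

    track_id: int
    onset_frame: int
    onset_time: float
    extent: float | None = None
    t_r: float | None = None
    complete: bool = False
    baseline: float | None = None
    minimum: float | None = None
    recovery_frame: int | None = None  # first frame back at completeness level
    minimum_frame: int | None = None


@dataclass
class SynchronizedEnsemble:
    """Onset-aligned, baseline-normalized reporter traces of many events."""

    rel_time_min: np.ndarray
    matrix: np.ndarray  # events x time, NaN-padded
    events: list[RuptureEvent] = field(default_factory=list)
    group_labels: list[str] | None = None

    @property
    def mean(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.matrix, axis=0)

    @property
    def sem(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            n = np.sum(np.isfinite(self.matrix), axis=0)
            sd = np.nanstd(self.matrix, axis=0, ddof=1)
        return np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)

    def subset(self, keep: np.ndarray) -> "SynchronizedEnsemble":
        keep = np.asarray(keep)
        return SynchronizedEnsemble(
            rel_time_min=self.rel_time_min,
            matrix=self.matrix[keep],
            events=[e for e, k in zip(self.events, keep) if k],
            group_labels=(
                [g for g, k in zip(self.group_labels, keep) if k]
                if self.group_labels is not None
                else None
            ),
        )


# ---------------------------------------------------------------------------
# detection


def compute_ratio_derivative(trace: IntensityTrace) -> np.ndarray:
    """Per-frame fold change of the H2B/NLS ratio (dH/N).

    ``dhn[t] = ratio(t) / ratio(t-1)`` for ``t >= 1``; undefined (NaN) at
    the first frame. Exactly 1 wherever both channels scale identically.
    """
    ratio = trace.ratio
    dhn = np.full(trace.n_frames, np.nan)
    dhn[1:] = ratio[1:] / ratio[:-1]
    return dhn


def detect_rupture_events(
    trace: IntensityTrace,
    threshold: float = DEFAULT_THRESHOLD,
    max_area_jump: float | None = DEFAULT_MAX_AREA_JUMP,
) -> list[RuptureEvent]:
    """Call rupture onsets where dH/N exceeds ``threshold``.

    Maximal runs of consecutive supra-threshold frames are merged into one
    event whose onset is the first frame of the run (a second event needs at
    least one sub-threshold frame in between). Onsets landing on
    gap-interpolated frames are rejected, as are onsets coinciding with an
    abrupt segmented-area change beyond ``max_area_jump`` (fractional): a
    rupture moves intensity, not area, so a concurrent area jump marks a
    segmentation artifact such as two touching nuclei merging or splitting
    (``None`` disables the gate).
    """
    if threshold <= 1:
        raise ValueError("threshold must exceed 1 (a fold change)")
    dhn = compute_ratio_derivative(trace)
    above = np.zeros(trace.n_frames, dtype=bool)
    above[1:] = dhn[1:] > threshold
    starts = np.flatnonzero(above & ~np.roll(above, 1))
    events = []
    for s in starts:
        if trace.is_gap[s]:
            continue
        if (
            max_area_jump is not None
            and trace.area is not None
            and s >= 1
            and abs(trace.area[s] / trace.area[s - 1] - 1.0) > max_area_jump
        ):
            continue
        events.append(
            RuptureEvent(
                track_id=trace.track_id,
                onset_frame=int(s),
                onset_time=float(trace.time_min[s]),
            )
        )
    return events


# ---------------------------------------------------------------------------
# characterization


def characterize_event(
    trace: IntensityTrace,
    onset: int,
    baseline_window: int = DEFAULT_BASELINE_WINDOW,
    completeness_level: float = DEFAULT_COMPLETENESS,
    segment_end: int | None = None,
    excluded: np.ndarray | None = None,
) -> RuptureEvent:
    """Measure baseline, extent, completeness and halftime of one event.

    All amplitudes are read from the raw (unsmoothed) reporter series.
    ``segment_end`` bounds the event's territory (the next event's onset or
    the track end); ``excluded`` marks frames inside earlier events that must
    not contribute to the baseline. With fewer than 2 usable baseline frames
    the event is kept but extent/halftime are left unavailable.
    """
    rep = trace.rep
    n = trace.n_frames
    end = n if segment_end is None else int(segment_end)
    if not 0 <= onset < end <= n:
        raise ValueError("onset/segment_end outside the trace")
    if excluded is None:
        excluded = np.zeros(n, dtype=bool)

    event = RuptureEvent(
        track_id=trace.track_id,
        onset_frame=int(onset),
        onset_time=float(trace.time_min[onset]),
    )

    usable = [
        j for j in range(onset - 1, -1, -1) if not excluded[j]
    ][:baseline_window]
    if len(usable) < 2:
        return event
    baseline = float(np.mean(rep[usable]))
    # single-frame spikes (e.g. a transiently merged segmentation mask) must
    # not fake a recovery crossing: search crossings on a width-3 running
    # median, which is the identity on monotone stretches
    rep_r = ndi.median_filter(rep, size=3, mode="nearest")
    rep_r[onset] = rep[onset]  # the abrupt drop at onset is genuine
    seg = rep_r[onset:end]
    min_idx = int(np.argmin(seg)) + onset
    minimum = float(rep_r[min_idx])
    event.baseline = baseline
    event.minimum = minimum
    event.minimum_frame = min_idx
    event.extent = max(0.0, (baseline - minimum) / baseline)

    level = completeness_level * baseline
    after_min = np.arange(min_idx, end)
    back = after_min[rep_r[after_min] >= level]
    if back.size:
        event.complete = True
        event.recovery_frame = int(back[0])
        half = baseline - (baseline - minimum) / 2.0
        for j in range(onset + 1, end):
            if rep_r[j] >= half and rep_r[j - 1] < half:
                t_prev, t_j = trace.time_min[j - 1], trace.time_min[j]
                frac = (half - rep_r[j - 1]) / (rep_r[j] - rep_r[j - 1])
                event.t_r = float(
                    t_prev + frac * (t_j - t_prev) - trace.time_min[onset]
                )
                break
    return event


def extract_events(
    trace: IntensityTrace,
    threshold: float = DEFAULT_THRESHOLD,
    baseline_window: int = DEFAULT_BASELINE_WINDOW,
    completeness_level: float = DEFAULT_COMPLETENESS,
    max_area_jump: float | None = DEFAULT_MAX_AREA_JUMP,
    min_extent: float | None = DEFAULT_MIN_EXTENT,
) -> list[RuptureEvent]:
    """Detect and characterize all rupture events of one trace, in order.

    Frames between an earlier event's onset and its return to the
    completeness level are excluded from later baselines. Characterized
    events whose extent falls below ``min_extent`` are vetoed as
    inconsistent with a genuine supra-threshold ratio step (``None`` keeps
    them).
    """
    events = detect_rupture_events(trace, threshold, max_area_jump)
    excluded = np.zeros(trace.n_frames, dtype=bool)
    out = []
    for k, ev in enumerate(events):
        end = (
            events[k + 1].onset_frame if k + 1 < len(events) else trace.n_frames
        )
        ev = characterize_event(
            trace,
            ev.onset_frame,
            baseline_window=baseline_window,
            completeness_level=completeness_level,
            segment_end=end,
            excluded=excluded,
        )
        stop = ev.recovery_frame if ev.recovery_frame is not None else end
        excluded[ev.onset_frame : stop] = True
        out.append(ev)
    if min_extent is not None:
        out = [
            e for e in out if e.extent is None or e.extent >= min_extent
        ]
    return out


# ---------------------------------------------------------------------------
# synchronization and population summaries


def synchronize_events(
    events: list[RuptureEvent],
    traces: dict[int, IntensityTrace],
    pre_frames: int = 5,
    post_frames: int = 60,
    fast_slow_boundary: float | None = FAST_SLOW_BOUNDARY_MIN,
) -> SynchronizedEnsemble:
    """Align events to their onset and normalize each to its baseline.

    Each event's reporter trace is cropped to
    ``[onset - pre_frames, onset + post_frames]`` and divided by its
    pre-rupture baseline; tails outside the track are NaN-padded. Events
    without a measurable baseline are skipped. Group labels "fast"/"slow"
    are assigned by comparing T_r to ``fast_slow_boundary`` (minutes).
    """
    usable = [e for e in events if e.baseline]
    if not usable:
        return SynchronizedEnsemble(
            rel_time_min=np.empty(0), matrix=np.empty((0, 0)), events=[]
        )
    interval = next(iter(traces.values())).frame_interval
    width = pre_frames + post_frames + 1
    rel_time = (np.arange(width) - pre_frames) * interval
    matrix = np.full((len(usable), width), np.nan)
    labels: list[str] = []
    for i, ev in enumerate(usable):
        trace = traces[ev.track_id]
        lo = ev.onset_frame - pre_frames
        hi = ev.onset_frame + post_frames + 1
        src_lo, src_hi = max(lo, 0), min(hi, trace.n_frames)
        matrix[i, src_lo - lo : src_hi - lo] = (
            trace.rep[src_lo:src_hi] / ev.baseline
        )
        if fast_slow_boundary is not None and ev.t_r is not None:
            labels.append("fast" if ev.t_r <= fast_slow_boundary else "slow")
        else:
            labels.append("unclassified")
    return SynchronizedEnsemble(
        rel_time_min=rel_time,
        matrix=matrix,
        events=usable,
        group_labels=labels,
    )


def rupture_frequency(
    track_ids: list[int],
    events: list[RuptureEvent],
    track_start_times: dict[int, float] | None = None,
    horizon: float | None = None,
) -> dict:
    """Per-track rupture counts and population frequency.

    ``horizon`` (minutes) restricts counting to events within that time of
    each track's start. Returns per-track counts, the fraction of tracks
    with at least one event, and the mean number of events per tracked
    nucleus.
    """
    counts = {tid: 0 for tid in track_ids}
    for ev in events:
        if ev.track_id not in counts:
            continue
        if horizon is not None:
            start = (track_start_times or {}).get(ev.track_id, 0.0)
            if ev.onset_time - start > horizon:
                continue
        counts[ev.track_id] += 1
    values = np.array(list(counts.values()), dtype=float)
    n = len(values)
    return {
        "per_track": counts,
        "fraction_with_event": float((values > 0).mean()) if n else 0.0,
        "mean_events_per_track": float(values.mean()) if n else 0.0,
        "max_events_per_track": int(values.max()) if n else 0,
        "n_tracks": n,
    }


def circularity_cov(circularity: np.ndarray) -> float:
    """Coefficient of variation (sample SD / mean) of circularity over time.

    A plasticity metric: rigid nuclei keep a constant outline (CoV ~ 0),
    dysmorphic deforming nuclei fluctuate.
    """
    c = np.asarray(circularity, dtype=float)
    c = c[np.isfinite(c)]
    if c.size < 2:
        raise ValueError("need at least 2 frames of circularity")
    mean = float(c.mean())
    if mean <= 0:
        raise ValueError("circularity mean must be positive")
    return float(c.std(ddof=1) / mean)


def initial_recovery_slope(
    trace: IntensityTrace,
    event: RuptureEvent,
    window: float = 20.0,
) -> float | None:
    """Least-squares slope of the normalized reporter right after the minimum.

    Fit over ``[t_min, t_min + window]`` minutes on the baseline-normalized
    series; ``None`` when fewer than 2 frames fall in the window or the
    event lacks a characterized minimum.
    """
    if event.minimum_frame is None or not event.baseline:
        return None
    t = trace.time_min
    t0 = t[event.minimum_frame]
    sel = (t >= t0) & (t <= t0 + window)
    if sel.sum() < 2:
        return None
    y = trace.rep[sel] / event.baseline
    slope = np.polyfit(t[sel], y, 1)[0]
    return float(slope)


def events_to_dataframe(events: list[RuptureEvent]) -> pd.DataFrame:
    """Tidy event table (one row per rupture)."""
    return pd.DataFrame(
        [
            {
                "track_id": e.track_id,
                "onset_frame": e.onset_frame,
                "onset_time_min": e.onset_time,
                "extent": e.extent if e.extent is not None else math.nan,
                "complete": e.complete,
                "T_r_min": e.t_r if e.t_r is not None else math.nan,
                "baseline": e.baseline if e.baseline is not None else math.nan,
                "minimum": e.minimum if e.minimum is not None else math.nan,
            }
            for e in events
        ],
        columns=[
            "track_id", "onset_frame", "onset_time_min", "extent",
            "complete", "T_r_min", "baseline", "minimum",
        ],
    ).astype({"complete": bool})
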