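"""Ground-truth benchmarks of the full detection/tracking/kinetics chain.

Each benchmark renders synthetic recordings under fixed, documented study
conditions, runs the real pipeline on them and scores the result against
the generator's exact ground truth:

* ``detector_benchmark`` — event recall/precision on movies with scripted
  ruptures (drop >= 0.25, SNR 10) plus false-call control movies that
  contain only global both-channel dimming, and frame-to-frame tracking
  identity agreement on the same movies.
* ``kinetics_sweep`` — halftime and extent accuracy on noiseless
  exponential recoveries over a wide range of time constants.
* ``gap_closure_check`` — single-frame detection dropouts must never split
  a track.
* ``population_benchmark`` — end-to-end cohorts with bimodal scripted
  halftimes; scores two-component mixture recovery and dip-test rejection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pipeline import build_traces
from .ruptures import RuptureEvent, extract_events
from .segment import SegmentationParams, detect_nuclei, normalize_intensity
from .stats import dip_test, fit_two_component_mixture
from .synthgen import (
    GroundTruth,
    RuptureScriptEntry,
    SceneSpec,
    render_timelapse,
    simulate_trace,
)
from .track import TrackSet, filter_tracks, link_tracks, tracks_to_dataframe

__all__ = [
    "detector_benchmark",
    "kinetics_sweep",
    "gap_closure_check",
    "population_benchmark",
    "analyze_movie",
    "match_events",
]

ONSET_TOLERANCE_FRAMES = 2


# ---------------------------------------------------------------------------
# shared plumbing


def analyze_movie(
    spec: SceneSpec,
    seg_params: SegmentationParams | None = None,
    min_duration: float = 60.0,
    threshold: float = 1.2,
) -> tuple[list[RuptureEvent], pd.DataFrame, TrackSet, GroundTruth]:
    """Render one movie and run segment -> track -> events on it."""
    stack, truth = render_timelapse(spec)
    normalized = normalize_intensity(stack)
    _, detections = detect_nuclei(normalized, "reference", seg_params)
    trackset = filter_tracks(
        link_tracks(detections, stack.frame_interval), min_duration
    )
    tracks_df = tracks_to_dataframe(trackset)
    events: list[RuptureEvent] = []
    for trace in build_traces(tracks_df).values():
        events.extend(extract_events(trace, threshold=threshold))
    return events, tracks_df, trackset, truth


def _track_identities(
    tracks_df: pd.DataFrame, truth: GroundTruth
) -> pd.DataFrame:
    """Assign each (track, frame) row the nearest true nucleus id."""
    cent = truth.centroids.set_index(["frame"])
    rows = []
    for frame, g in tracks_df[~tracks_df["is_gap"]].groupby("frame"):
        tc = cent.loc[[frame]]
        ty = tc["y"].to_numpy()
        tx = tc["x"].to_numpy()
        ids = tc["nucleus_id"].to_numpy()
        gy = g["y"].to_numpy()
        gx = g["x"].to_numpy()
        d = np.hypot(ty[None, :] - gy[:, None], tx[None, :] - gx[:, None])
        j = np.argmin(d, axis=1)
        for tid, jj, dd in zip(g["track_id"].to_numpy(), j, d[np.arange(len(j)), j]):
            rows.append((int(tid), int(frame), int(ids[jj]), float(dd)))
    return pd.DataFrame(rows, columns=["track_id", "frame", "nucleus_id", "dist"])


def match_events(
    events: list[RuptureEvent],
    tracks_df: pd.DataFrame,
    truth: GroundTruth,
    onset_tolerance: int = ONSET_TOLERANCE_FRAMES,
) -> tuple[int, int, int]:
    """Greedy event-to-truth matching; returns (tp, fp, fn).

    A called event matches a scripted one when its track sits on that
    nucleus at the onset frame and the onsets agree within
    ``onset_tolerance`` frames; every scripted event can be matched once.
    """
    ident = _track_identities(tracks_df, truth)
    ident = ident.set_index(["track_id", "frame"])["nucleus_id"]
    truth_events = truth.events.copy()
    used = np.zeros(len(truth_events), dtype=bool)
    tp = fp = 0
    for ev in sorted(events, key=lambda e: e.onset_frame):
        nid = None
        for probe in (ev.onset_frame, ev.onset_frame - 1, ev.onset_frame + 1):
            key = (ev.track_id, probe)
            if key in ident.index:
                nid = int(ident.loc[key])
                break
        matched = False
        if nid is not None:
            cand = truth_events.index[
                (~used)
                & (truth_events["nucleus_id"] == nid)
                & (
                    (truth_events["onset_frame"] - ev.onset_frame).abs()
                    <= onset_tolerance
                )
            ]
            if len(cand):
                used[truth_events.index.get_loc(cand[0])] = True
                matched = True
        tp += matched
        fp += not matched
    fn = int((~used).sum())
    return tp, fp, fn


def link_agreement(tracks_df: pd.DataFrame, truth: GroundTruth) -> tuple[int, int]:
    """Count frame-to-frame links that connect the same true nucleus."""
    ident = _track_identities(tracks_df, truth)
    good = total = 0
    for _, g in ident.groupby("track_id"):
        g = g.sort_values("frame")
        ids = g["nucleus_id"].to_numpy()
        good += int((ids[1:] == ids[:-1]).sum())
        total += len(ids) - 1
    return good, total


# ---------------------------------------------------------------------------
# benchmarks


def _detector_spec(seed: int, rupture: bool) -> SceneSpec:
    """Study conditions of the detector benchmark: 10 nuclei, 150 frames,
    2-min interval, SNR 10; ruptures with drop >= 0.25 on ~55% of nuclei
    (the rest never rupture), or dimming-only controls with both channels
    scaled down by up to 50%."""
    rng = np.random.default_rng(seed)
    n_nuclei, frame_count = 10, 150
    script: list[RuptureScriptEntry] = []
    illumination = None
    if rupture:
        for i in range(n_nuclei):
            if rng.random() < 0.45:  # non-rupturing fraction
                continue
            n_events = 1 + (rng.random() < 0.3)
            onsets = np.sort(
                rng.choice(np.arange(10, frame_count - 15), n_events, replace=False)
            )
            prev_end = -100
            for onset in onsets:
                if onset - prev_end < 30:
                    continue
                script.append(
                    RuptureScriptEntry(
                        nucleus_id=i,
                        onset_frame=int(onset),
                        drop_fraction=float(rng.uniform(0.25, 0.6)),
                        recovery_tau=float(rng.uniform(10.0, 60.0)),
                    )
                )
                prev_end = onset
    else:
        # smooth global dips of both channels, down to 50% brightness
        t = np.arange(frame_count)
        illumination = np.ones(frame_count)
        for _ in range(3):
            center = rng.uniform(20, frame_count - 20)
            width = rng.uniform(3, 10)
            depth = rng.uniform(0.2, 0.5)
            illumination *= 1.0 - depth * np.exp(
                -((t - center) ** 2) / (2 * width**2)
            )
        illumination = np.clip(illumination, 0.5, None)
    return SceneSpec(
        n_nuclei=n_nuclei,
        frame_count=frame_count,
        rng_seed=seed,
        rupture_script=tuple(script),
        illumination_series=illumination,
    )


def detector_benchmark(
    n_movies: int = 20, n_controls: int = 5, seed: int = 0
) -> dict:
    """Recall/precision of rupture calls and tracking agreement vs truth."""
    root = np.random.SeedSequence(seed)
    movie_seeds = [int(s) for s in root.generate_state(n_movies + n_controls) % 2**31]
    tp = fp = fn = 0
    good_links = total_links = 0
    frac_no_event = []
    for s in movie_seeds[:n_movies]:
        events, tracks_df, trackset, truth = analyze_movie(_detector_spec(s, True))
        a, b, c = match_events(events, tracks_df, truth)
        tp, fp, fn = tp + a, fp + b, fn + c
        g, t = link_agreement(tracks_df, truth)
        good_links, total_links = good_links + g, total_links + t
        with_event = {e.track_id for e in events}
        frac_no_event.append(
            1.0 - len(with_event) / max(len(trackset), 1)
        )
    control_events = 0
    for s in movie_seeds[n_movies:]:
        events, *_ = analyze_movie(_detector_spec(s, False))
        control_events += len(events)
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "recall": tp / (tp + fn) if tp + fn else float("nan"),
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "control_false_events": control_events,
        "n_movies": n_movies,
        "n_controls": n_controls,
        "link_agreement": good_links / total_links if total_links else float("nan"),
        "n_links": total_links,
        "fraction_tracks_without_event": float(np.mean(frac_no_event)),
    }


def kinetics_sweep(
    taus_min: np.ndarray | None = None,
    drop_fraction: float = 0.5,
    frame_interval: float = 2.0,
    n_frames: int = 220,
) -> dict:
    """Halftime/extent accuracy on noiseless exponential recoveries.

    For each recovery time constant tau the closed-form truth is
    T_r = tau * ln 2 and extent = drop_fraction; the sweep reports the worst
    absolute errors across tau in [5, 120] min.
    """
    if taus_min is None:
        taus_min = np.linspace(5.0, 120.0, 47)
    t_errors, e_errors = [], []
    for tau in taus_min:
        entry = RuptureScriptEntry(
            nucleus_id=0, onset_frame=10, drop_fraction=drop_fraction,
            recovery_tau=float(tau),
        )
        trace_df, _ = simulate_trace(
            entry, n_frames=n_frames, frame_interval=frame_interval
        )
        traces = build_traces(
            trace_df.assign(track_id=0).rename(
                columns={"ref": "mean_ref", "rep": "mean_rep"}
            )
        )
        events = extract_events(traces[0])
        assert len(events) == 1, f"tau={tau}: expected 1 event, got {len(events)}"
        ev = events[0]
        assert ev.t_r is not None, f"tau={tau}: no halftime"
        t_errors.append(abs(ev.t_r - tau * math.log(2.0)))
        e_errors.append(abs(ev.extent - drop_fraction))
    return {
        "max_halftime_error_min": float(np.max(t_errors)),
        "max_extent_error": float(np.max(e_errors)),
        "frame_interval_min": frame_interval,
        "n_taus": len(taus_min),
    }


def gap_closure_check(
    n_nuclei: int = 10, n_frames: int = 60, seed: int = 0, max_gap: int = 5
) -> dict:
    """Delete one random detection frame per nucleus; tracks must not split.

    Runs on an ideal detection table built from ground-truth centroids, so
    the check isolates the linker's gap handling from segmentation noise.
    """
    spec = SceneSpec(
        n_nuclei=n_nuclei, frame_count=n_frames, rng_seed=seed,
        noise_gaussian_sd=0.0,
    )
    _, truth = render_timelapse(spec)
    det = truth.centroids.rename(columns={"nucleus_id": "label"}).copy()
    det["mean_ref"] = 1000.0
    det["mean_rep"] = 1000.0
    rng = np.random.default_rng(seed + 1)
    dropped = []
    for nid in range(n_nuclei):
        f = int(rng.integers(5, n_frames - 5))
        det = det[~((det["label"] == nid) & (det["frame"] == f))]
        dropped.append(f)
    ts = link_tracks(det, frame_interval=2.0, max_gap=max_gap)
    n_splits = len(ts.tracks) - n_nuclei
    gap_lengths = [len(t.gap_frames) for t in ts.tracks]
    return {
        "n_tracks": len(ts.tracks),
        "n_nuclei": n_nuclei,
        "n_splits": int(n_splits),
        "all_gaps_closed": all(g == 1 for g in gap_lengths),
    }


# ---------------------------------------------------------------------------
# population cohorts


@dataclass(frozen=True)
class CohortDesign:
    """Study conditions of one bimodal-recovery cohort.

    Thirty nuclei, one scripted rupture each with halftime drawn from a
    two-component normal mixture (fast 13 min, slow 67 min), truncated so
    every recovery can complete within the 160-frame (320-min) recording.
    """

    n_nuclei: int = 45
    frame_count: int = 160
    image_size: tuple[int, int] = (320, 320)
    means: tuple[float, float] = (13.0, 67.0)
    sds: tuple[float, float] = (3.0, 10.0)
    weights: tuple[float, float] = (0.5, 0.5)
    halftime_bounds: tuple[tuple[float, float], tuple[float, float]] = (
        (5.0, 22.0),
        (40.0, 85.0),
    )
    onset_frames: tuple[int, int] = (8, 14)
    drop_range: tuple[float, float] = (0.3, 0.5)


def _cohort_spec(design: CohortDesign, seed: int) -> tuple[SceneSpec, np.ndarray]:
    rng = np.random.default_rng(seed)
    script = []
    components = []
    for i in range(design.n_nuclei):
        comp = int(rng.random() < design.weights[1])
        lo, hi = design.halftime_bounds[comp]
        while True:
            halftime = rng.normal(design.means[comp], design.sds[comp])
            if lo <= halftime <= hi:
                break
        script.append(
            RuptureScriptEntry(
                nucleus_id=i,
                onset_frame=int(rng.integers(*design.onset_frames)),
                drop_fraction=float(rng.uniform(*design.drop_range)),
                recovery_tau=halftime / math.log(2.0),
            )
        )
        components.append(comp)
    # radius range shrunk so 30 nuclei fit a 256x256 field without touching
    spec = SceneSpec(
        n_nuclei=design.n_nuclei,
        frame_count=design.frame_count,
        image_size=design.image_size,
        nucleus_radius_range=(8.0, 12.0),
        rng_seed=seed,
        rupture_script=tuple(script),
    )
    return spec, np.asarray(components)


def population_benchmark(
    n_cohorts: int = 50,
    seed: int = 0,
    design: CohortDesign | None = None,
    n_boot: int = 300,
) -> dict:
    """End-to-end bimodality recovery over seeded cohorts.

    For each cohort the full chain (render -> segment -> track -> events ->
    halftimes) is followed by a two-component mixture fit and a dip test.
    A cohort succeeds when both fitted component means are within 20% of the
    cohort's realized scripted means and the dip test rejects unimodality at
    p < 0.05. EM log-likelihood monotonicity is verified on every fit.
    """
    design = design or CohortDesign()
    root = np.random.SeedSequence(seed)
    cohort_seeds = [int(s) for s in root.generate_state(n_cohorts) % 2**31]
    seg_params = SegmentationParams(log_sigma=6.0, min_area=70)
    successes = []
    mean_errors = []
    dip_rejections = []
    monotone = []
    n_halftimes = []
    for i, s in enumerate(cohort_seeds):
        spec, components = _cohort_spec(design, s)
        events, tracks_df, trackset, truth = analyze_movie(spec, seg_params)
        halftimes = np.array(
            [e.t_r for e in events if e.complete and e.t_r is not None]
        )
        n_halftimes.append(len(halftimes))
        scripted = truth.events["true_halftime_min"].to_numpy()
        true_means = (
            float(scripted[components == 0].mean()),
            float(scripted[components == 1].mean()),
        )
        if len(halftimes) < 10:
            successes.append(False)
            dip_rejections.append(False)
            monotone.append(True)
            continue
        fit = fit_two_component_mixture(halftimes, seed=s)
        monotone.append(bool(np.all(np.diff(fit.loglik_history) >= -1e-8)))
        rel_err = (
            abs(fit.means[0] - true_means[0]) / true_means[0],
            abs(fit.means[1] - true_means[1]) / true_means[1],
        )
        mean_errors.append(max(rel_err))
        dip = dip_test(halftimes, n_boot=n_boot, seed=s)
        dip_rejections.append(dip.pvalue < 0.05)
        successes.append(max(rel_err) <= 0.20 and dip.pvalue < 0.05)
    return {
        "n_cohorts": n_cohorts,
        "success_fraction": float(np.mean(successes)),
        "dip_rejection_fraction": float(np.mean(dip_rejections)),
        "median_worst_mean_error": (
            float(np.median(mean_errors)) if mean_errors else float("nan")
        ),
        "em_monotone_all": bool(all(monotone)),
        "mean_halftimes_per_cohort": float(np.mean(n_halftimes)),
    }
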