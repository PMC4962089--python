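"""End-to-end orchestration: simulate/load -> segment -> track -> analyze -> stats.

Each stage writes its output as a standalone CSV/JSON file so any stage can
be re-run or inspected in isolation; a manifest with the config hash, seeds
and per-stage row counts is written atomically at the end. Identical
config + seed reruns produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, dump_config
from .ruptures import (
    IntensityTrace,
    circularity_cov,
    events_to_dataframe,
    extract_events,
    rupture_frequency,
    synchronize_events,
)
from .segment import SegmentationParams, detect_nuclei, normalize_intensity
from .stack import read_stack, write_stack
from .synthgen import RuptureScriptEntry, SceneSpec, render_timelapse
from .stats import dip_test, fit_two_component_mixture, linear_fit_r2, tipping_point
from .track import filter_tracks, link_tracks, tracks_to_dataframe

__all__ = ["run_pipeline", "StageError"]

log = logging.getLogger("rupturekit")

# NLS-only recordings get mandatory temporal smoothing on the detection
# pathway, because the segmented channel itself dims at every rupture
SINGLE_MARKER_MIN_SIGMA_T = 4.0  # minutes


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs remain on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _scene_spec(config: PipelineConfig) -> SceneSpec:
    sim = config.simulate
    assert sim is not None
    return SceneSpec(
        n_nuclei=sim.n_nuclei,
        frame_count=sim.frame_count,
        frame_interval=sim.frame_interval,
        image_size=tuple(sim.image_size),
        nucleus_radius_range=tuple(sim.nucleus_radius_range),
        motion_step_sd=sim.motion_step_sd,
        deformation_amplitude=sim.deformation_amplitude,
        expression_cv=sim.expression_cv,
        signal_level=sim.signal_level,
        background_level=sim.background_level,
        noise_gaussian_sd=sim.noise_gaussian_sd,
        noise_poisson=sim.noise_poisson,
        rupture_script=tuple(
            RuptureScriptEntry(**entry.model_dump())
            for entry in sim.rupture_script
        ),
        rng_seed=config.seed,
    )


def build_traces(
    tracks_df: pd.DataFrame, detection_sigma_t: float = 0.0,
    single_marker: bool = False,
    area_bounds: tuple[float, float] | None = (0.6, 1.4),
) -> dict[int, IntensityTrace]:
    """Per-track intensity traces from the tidy track table.

    Frames whose segmented area falls outside ``area_bounds`` times the
    track's median area are invalid measurements (two touching nuclei
    merged into one mask, or a mask fragment) and are treated like tracking
    gaps: values interpolated, frame flagged, never an event anchor.

    In single-marker mode there is no reference channel; the reference
    series is set to 1, so dH/N degenerates to the normalized-NLS fold
    *drop* rep(t-1)/rep(t) — the fallback detection statistic, without
    focus-dip immunity.
    """
    traces = {}
    for tid, g in tracks_df.groupby("track_id"):
        g = g.sort_values("frame").reset_index(drop=True)
        if single_marker or "mean_ref" not in g:
            g = g.assign(mean_ref=1.0)
        if area_bounds is not None and "area" in g and "is_gap" in g:
            area = g["area"].to_numpy(float)
            med = float(np.median(area[~g["is_gap"].to_numpy()]))
            bad = (area < area_bounds[0] * med) | (area > area_bounds[1] * med)
            if bad.any() and not bad.all():
                good = np.flatnonzero(~bad)
                frames = g["frame"].to_numpy(float)
                numeric = [
                    c for c in g.columns
                    if c not in ("frame", "track_id", "is_gap")
                    and pd.api.types.is_numeric_dtype(g[c])
                ]
                for c in numeric:
                    vals = g[c].to_numpy(float)
                    g[c] = np.interp(frames, frames[good], vals[good])
                g.loc[bad, "is_gap"] = True
        traces[int(tid)] = IntensityTrace.from_dataframe(
            g, detection_sigma_t=detection_sigma_t
        )
    return traces


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all stages; returns a summary dict (also written as manifest)."""
    config.validate_ready()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    # ---- stage: input ----------------------------------------------------
    stage = "input"
    try:
        if config.simulate is not None:
            spec = _scene_spec(config)
            stack, truth = render_timelapse(spec)
            write_stack(out / "movie.tif", stack)
            truth.events.to_csv(out / "truth_events.csv", index=False)
            truth.centroids.to_csv(out / "truth_centroids.csv", index=False)
            log.info("simulated %d nuclei, %d frames", spec.n_nuclei, spec.frame_count)
        else:
            stack = read_stack(config.input_path)
        counts["frames"] = stack.n_frames
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc

    # ---- stage: segment --------------------------------------------------
    stage = "segment"
    try:
        seg = config.segmentation
        channel = "reporter" if config.single_marker else seg.channel
        sigma_t = seg.sigma_t_min
        if config.single_marker:
            sigma_t = max(sigma_t, SINGLE_MARKER_MIN_SIGMA_T)
        params = SegmentationParams(
            log_sigma=seg.log_sigma,
            min_area=seg.min_area,
            max_area=seg.max_area,
            sigma_xy=seg.sigma_xy,
            sigma_t_min=sigma_t,
            clahe_clip=seg.clahe_clip,
            peak_snr=seg.peak_snr,
            watershed_enabled=seg.watershed_enabled,
        )
        normalized = normalize_intensity(stack)
        labelmap, detections = detect_nuclei(normalized, channel, params)
        detections.to_csv(out / "detections.csv", index=False)
        counts["detections"] = len(detections)
        log.info(
            "segmented %d detections (%.1f per frame)",
            len(detections), len(detections) / stack.n_frames,
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- stage: track ----------------------------------------------------
    stage = "track"
    try:
        tr = config.tracking
        trackset = link_tracks(
            detections,
            frame_interval=stack.frame_interval,
            max_displacement=tr.max_displacement,
            max_gap=tr.max_gap,
        )
        trackset = filter_tracks(trackset, min_duration=tr.min_duration)
        tracks_df = tracks_to_dataframe(trackset)
        tracks_df.to_csv(out / "tracks.csv", index=False)
        counts["tracks"] = len(trackset)
        log.info("linked %d tracks (>= %g min)", len(trackset), tr.min_duration)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- stage: analyze --------------------------------------------------
    stage = "analyze"
    try:
        ana = config.analysis
        traces = build_traces(
            tracks_df,
            detection_sigma_t=ana.detection_sigma_t,
            single_marker=config.single_marker,
        )
        all_events = []
        for trace in traces.values():
            all_events.extend(
                extract_events(
                    trace,
                    threshold=ana.threshold,
                    baseline_window=ana.baseline_window,
                    completeness_level=ana.completeness_level,
                )
            )
        events_df = events_to_dataframe(all_events)
        events_df.to_csv(out / "events.csv", index=False)
        ensemble = synchronize_events(
            all_events, traces,
            pre_frames=ana.pre_frames, post_frames=ana.post_frames,
            fast_slow_boundary=ana.fast_slow_boundary_min,
        )
        if ensemble.matrix.size:
            wide = pd.DataFrame(
                ensemble.matrix,
                columns=[f"t{t:+.0f}" for t in ensemble.rel_time_min],
            )
            wide.insert(0, "group", ensemble.group_labels)
            wide.insert(0, "track_id", [e.track_id for e in ensemble.events])
            wide.to_csv(out / "ensemble.csv", index=False)
        freq = rupture_frequency(
            [t.track_id for t in trackset.tracks], all_events
        )
        covs = {}
        for tid, trace in traces.items():
            if trace.circularity is not None and len(trace.circularity) >= 2:
                covs[tid] = circularity_cov(trace.circularity)
        counts["events"] = len(all_events)
        log.info(
            "called %d events on %d tracks (fraction with event %.2f)",
            len(all_events), len(trackset), freq["fraction_with_event"],
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- stage: stats ----------------------------------------------------
    stage = "stats"
    try:
        halftimes = events_df.loc[
            events_df["complete"].astype(bool), "T_r_min"
        ].dropna()
        halftimes.to_csv(out / "halftimes.csv", index=False)
        st = config.stats
        fit_payload: dict = {
            "n_halftimes": int(len(halftimes)),
            "mean_halftime_min": (
                float(halftimes.mean()) if len(halftimes) else None
            ),
            "sd_halftime_min": (
                float(halftimes.std(ddof=1)) if len(halftimes) > 1 else None
            ),
            "rupture_frequency": {
                k: v for k, v in freq.items() if k != "per_track"
            },
            "circularity_cov_mean": (
                float(np.mean(list(covs.values()))) if covs else None
            ),
        }
        if len(halftimes) >= 4:
            dip = dip_test(halftimes, n_boot=st.n_boot, seed=config.seed)
            fit_payload["dip"] = {"statistic": dip.dip, "pvalue": dip.pvalue}
        if len(halftimes) >= st.min_halftimes:
            fit = fit_two_component_mixture(
                halftimes, n_starts=st.n_starts, seed=config.seed
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                tip = tipping_point(fit)
            fit_payload["mixture"] = {
                "means": fit.means.tolist(),
                "sds": fit.sds.tolist(),
                "weights": fit.weights.tolist(),
                "log_likelihood": fit.log_likelihood,
                "converged": fit.converged,
                "degenerate": fit.degenerate,
                "tipping_point_min": tip,
            }
        complete = events_df[events_df["complete"].astype(bool)].dropna(
            subset=["extent", "T_r_min"]
        )
        if len(complete) >= 3 and complete["extent"].nunique() > 1:
            reg = linear_fit_r2(complete["extent"], complete["T_r_min"])
            fit_payload["extent_vs_halftime"] = {
                "slope": reg.slope, "intercept": reg.intercept,
                "r2": reg.r2, "n": reg.n,
            }
        _atomic_write(out / "fit.json", json.dumps(fit_payload, indent=2))
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- manifest --------------------------------------------------------
    config_text = dump_config(config)
    manifest = {
        "package_version": __version__,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "seed": config.seed,
        "counts": counts,
    }
    _atomic_write(out / "manifest.json", json.dumps(manifest, indent=2))
    return {"counts": counts, "fit": fit_payload, "manifest": manifest}
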