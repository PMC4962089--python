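"""Synthetic two-channel time-lapse generator with exact ground truth.

Renders movies that emulate live-cell recordings of lamin-deficient cells
co-expressing a chromatin-bound reference marker (H2B) and an NLS shuttling
reporter: flat-ish, possibly dysmorphic nuclei wander and deform in 2D, each
cell has its own expression level, global illumination/focus fluctuations
scale both channels identically, and scripted nuclear-envelope ruptures make
the nuclear NLS signal drop abruptly and recover exponentially while the H2B
signal stays constant (optionally with a transient local contraction and a
focal H2B brightening at the rupture site).

Every movie comes with exact ground truth — per-frame label masks, centroids,
noise-free per-nucleus intensity traces and the scripted event table — so the
whole detection/tracking/kinetics chain can be benchmarked quantitatively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import polygon as draw_polygon

from .stack import FrameStack

__all__ = [
    "SceneSpec",
    "RuptureScriptEntry",
    "GroundTruth",
    "render_timelapse",
    "simulate_trace",
    "sample_halftimes",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class RuptureScriptEntry:
    """One scripted nuclear-envelope rupture.

    ``drop_fraction`` is the fraction of nuclear NLS signal lost at onset
    (0-1, exclusive); recovery is single-exponential with time constant
    ``recovery_tau`` minutes, so the true recovery halftime is
    ``recovery_tau * ln 2``. ``contraction_fraction`` is a transient
    fractional loss of nuclear area after the rupture; ``h2b_focal_gain``
    multiplies the H2B signal inside a focal spot at the rupture site
    (1 = no chromatin condensation visible).
    """

    nucleus_id: int
    onset_frame: int
    drop_fraction: float
    recovery_tau: float
    contraction_fraction: float = 0.0
    h2b_focal_gain: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.drop_fraction < 1.0:
            raise ValueError("drop_fraction must be in (0, 1)")
        if self.recovery_tau <= 0:
            raise ValueError("recovery_tau must be positive (minutes)")
        if not 0.0 <= self.contraction_fraction < 1.0:
            raise ValueError("contraction_fraction must be in [0, 1)")
        if self.h2b_focal_gain < 1.0:
            raise ValueError("h2b_focal_gain must be >= 1")

    @property
    def true_halftime(self) -> float:
        """Halftime of the exponential recovery, minutes."""
        return self.recovery_tau * LN2


@dataclass
class SceneSpec:
    """Parameters of one synthetic recording.

    Defaults mirror a desk-scale version of a spinning-disk live-cell
    acquisition: 2-min frame interval, ten nuclei of ~10-16 px radius in a
    256x256 field, camera read noise giving SNR ~ 10 above background.
    ``deformation_amplitude`` controls both static shape irregularity and
    per-frame boundary wobble; 0 renders rigid circular disks.
    """

    n_nuclei: int = 10
    frame_count: int = 150
    frame_interval: float = 2.0  # minutes; recordings made every 2-3 min
    image_size: tuple[int, int] = (256, 256)
    nucleus_radius_range: tuple[float, float] = (10.0, 16.0)
    motion_step_sd: float = 2.0  # px/frame, per axis
    deformation_amplitude: float = 0.0
    expression_cv: float = 0.2
    signal_level: float = 1000.0  # mean nuclear intensity above background
    background_level: float = 100.0
    noise_gaussian_sd: float = 100.0  # signal_level / 10 -> SNR 10
    noise_poisson: bool = False
    illumination_series: np.ndarray | None = None
    rupture_script: tuple[RuptureScriptEntry, ...] = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_count < 2:
            raise ValueError("frame_count must be >= 2")
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        lo, hi = self.nucleus_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("nucleus_radius_range must be 0 < lo <= hi")
        if self.illumination_series is not None:
            s = np.asarray(self.illumination_series, dtype=float)
            if s.shape != (self.frame_count,):
                raise ValueError(
                    "illumination_series must have one factor per frame"
                )
            if np.any(s <= 0):
                raise ValueError("illumination factors must be positive")
            object.__setattr__(self, "illumination_series", s)
        for entry in self.rupture_script:
            if not 0 <= entry.onset_frame < self.frame_count:
                raise ValueError(
                    f"onset_frame {entry.onset_frame} outside movie "
                    f"(frame_count={self.frame_count})"
                )
            if not 0 <= entry.nucleus_id < self.n_nuclei:
                raise ValueError(f"unknown nucleus_id {entry.nucleus_id}")

    @property
    def snr(self) -> float:
        """Nuclear signal above background over read-noise SD."""
        return self.signal_level / self.noise_gaussian_sd


@dataclass
class GroundTruth:
    """Exact per-movie truth tables.

    ``events``: one row per scripted rupture landing inside the movie
    (nucleus_id, onset_frame, onset_time_min, drop_fraction, recovery_tau,
    true_halftime_min, contraction_fraction, h2b_focal_gain).
    ``centroids``: per frame and nucleus true centroid (frame, nucleus_id,
    y, x).  ``traces``: noise-free per-nucleus mean intensities before
    illumination scaling (frame, nucleus_id, ref_true, rep_true).
    ``labels``: T x Y x X label masks, label = nucleus_id + 1.
    """

    events: pd.DataFrame
    centroids: pd.DataFrame
    traces: pd.DataFrame
    labels: np.ndarray | None = None


# ---------------------------------------------------------------------------
# geometry helpers

_N_VERTICES = 96
_HARMONICS = (2, 3, 4, 5)


def _radius_profile(
    base_radius: float,
    aspect: float,
    orientation: float,
    coeffs: np.ndarray,
    phases: np.ndarray,
    theta: np.ndarray,
) -> np.ndarray:
    """Radial outline r(theta): ellipse plus low-order Fourier perturbation."""
    # ellipse radius for semi-axes (a, b) = base*(1/sqrt(aspect), sqrt(aspect))
    a = base_radius / math.sqrt(aspect)
    b = base_radius * math.sqrt(aspect)
    t = theta - orientation
    r = a * b / np.sqrt((b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2)
    wobble = np.zeros_like(theta)
    for k, c, ph in zip(_HARMONICS, coeffs, phases):
        wobble += c * np.cos(k * theta + ph)
    return r * np.clip(1.0 + wobble, 0.25, 2.0)


def _nls_factor(entry: RuptureScriptEntry, t_min: float, onset_min: float) -> float:
    if t_min < onset_min:
        return 1.0
    return 1.0 - entry.drop_fraction * math.exp(
        -(t_min - onset_min) / entry.recovery_tau
    )


# ---------------------------------------------------------------------------
# rendering


def render_timelapse(spec: SceneSpec) -> tuple[FrameStack, GroundTruth]:
    """Render a two-channel movie plus exact ground truth.

    The same spec (including ``rng_seed``) always produces bit-identical
    output. Raises ``RuntimeError`` if non-overlapping initial positions
    cannot be found after a bounded number of retries.
    """
    rng = np.random.default_rng(spec.rng_seed)
    ny, nx = spec.image_size
    T = spec.frame_count
    lo, hi = spec.nucleus_radius_range

    radii = rng.uniform(lo, hi, size=spec.n_nuclei)
    # non-overlapping initialization (rejection sampling, bounded retries)
    margin = radii.max() + 3.0
    centers = np.empty((spec.n_nuclei, 2))
    for i in range(spec.n_nuclei):
        for attempt in range(5000):
            cand = rng.uniform(
                [margin, margin], [ny - margin, nx - margin], size=2
            )
            if i == 0:
                centers[i] = cand
                break
            sep = np.hypot(*(centers[:i] - cand).T)
            if np.all(sep > radii[:i] + radii[i] + 4.0):
                centers[i] = cand
                break
        else:
            raise RuntimeError(
                f"could not place nucleus {i} without overlap after 5000 tries; "
                "reduce n_nuclei or nucleus radii"
            )

    d = spec.deformation_amplitude
    aspects = rng.uniform(max(0.6, 1.0 - 2.0 * d), 1.0, size=spec.n_nuclei)
    if d == 0:
        aspects[:] = 1.0
    orientations = rng.uniform(0, 2 * math.pi, size=spec.n_nuclei)
    base_coeffs = rng.normal(0.0, d / 3.0, size=(spec.n_nuclei, len(_HARMONICS)))
    phases = rng.uniform(0, 2 * math.pi, size=(spec.n_nuclei, len(_HARMONICS)))

    # per-cell, per-channel expression (lognormal with requested CV)
    if spec.expression_cv > 0:
        sig = math.sqrt(math.log(1.0 + spec.expression_cv**2))
        expr = rng.lognormal(-0.5 * sig**2, sig, size=(spec.n_nuclei, 2))
    else:
        expr = np.ones((spec.n_nuclei, 2))
    ref_level = spec.signal_level * expr[:, 0]
    rep_level = spec.signal_level * expr[:, 1]

    # random-walk motion, reflected at the borders, with pairwise exclusion:
    # nuclei belong to different cells and cannot interpenetrate, so a step
    # that would bring two outlines into overlap is rejected for that frame
    if ny - 2 * margin <= 0 or nx - 2 * margin <= 0:
        raise RuntimeError("image too small for the requested nucleus radii")
    steps = rng.normal(0.0, spec.motion_step_sd, size=(T, spec.n_nuclei, 2))
    sep = radii[:, None] + radii[None, :] + 1.0
    pos = np.empty((T, spec.n_nuclei, 2))
    pos[0] = centers
    for t in range(1, T):
        pos[t] = pos[t - 1]
        for i in range(spec.n_nuclei):
            cand = pos[t - 1, i] + steps[t, i]
            for ax, size in ((0, ny), (1, nx)):
                low, high = margin, size - margin
                span = high - low
                p = math.fmod(cand[ax] - low, 2 * span)
                if p < 0:
                    p += 2 * span
                cand[ax] = low + (p if p <= span else 2 * span - p)
            gaps = np.hypot(*(pos[t] - cand).T)
            gaps[i] = np.inf
            if np.all(gaps > sep[i]):
                pos[t, i] = cand

    # per-frame boundary wobble (AR(1) around the base shape)
    wobble = np.zeros((T, spec.n_nuclei, len(_HARMONICS)))
    if d > 0:
        rho = 0.9
        innov = rng.normal(
            0.0, d / 4.0, size=(T, spec.n_nuclei, len(_HARMONICS))
        )
        for t in range(1, T):
            wobble[t] = rho * wobble[t - 1] + math.sqrt(1 - rho**2) * innov[t]

    script_by_nucleus: dict[int, list[RuptureScriptEntry]] = {}
    for entry in spec.rupture_script:
        script_by_nucleus.setdefault(entry.nucleus_id, []).append(entry)
    for entries in script_by_nucleus.values():
        entries.sort(key=lambda e: e.onset_frame)
    # focal-spot placement for chromatin condensation, fixed per event
    focal_offsets = {
        (e.nucleus_id, e.onset_frame): rng.uniform(-0.4, 0.4, size=2)
        for e in spec.rupture_script
    }

    illum = (
        np.ones(T)
        if spec.illumination_series is None
        else np.asarray(spec.illumination_series, dtype=float)
    )

    theta = np.linspace(0.0, 2 * math.pi, _N_VERTICES, endpoint=False)
    data = np.empty((T, 2, ny, nx), dtype=np.float64)
    labels = np.zeros((T, ny, nx), dtype=np.uint16)
    yy, xx = np.mgrid[0:ny, 0:nx]

    cent_rows: list[tuple] = []
    trace_rows: list[tuple] = []
    for t in range(T):
        t_min = t * spec.frame_interval
        ref_img = np.zeros((ny, nx))
        rep_img = np.zeros((ny, nx))
        for i in range(spec.n_nuclei):
            nls = 1.0
            shrink = 1.0
            focal: tuple[np.ndarray, float, float] | None = None
            for entry in script_by_nucleus.get(i, ()):
                onset_min = entry.onset_frame * spec.frame_interval
                nls *= _nls_factor(entry, t_min, onset_min)
                if t_min >= onset_min:
                    decay = math.exp(-(t_min - onset_min) / entry.recovery_tau)
                    shrink *= math.sqrt(
                        1.0 - entry.contraction_fraction * decay
                    )
                    if entry.h2b_focal_gain > 1.0:
                        gain_now = 1.0 + (entry.h2b_focal_gain - 1.0) * decay
                        focal = (
                            focal_offsets[(i, entry.onset_frame)],
                            gain_now,
                            radii[i] / 3.0,
                        )
            r_prof = _radius_profile(
                radii[i] * shrink,
                aspects[i],
                orientations[i],
                base_coeffs[i] + wobble[t, i],
                phases[i],
                theta,
            )
            cy, cx = pos[t, i]
            py = cy + r_prof * np.sin(theta)
            px = cx + r_prof * np.cos(theta)
            rr, cc = draw_polygon(py, px, shape=(ny, nx))
            labels[t, rr, cc] = i + 1
            ref_val = ref_level[i]
            rep_val = rep_level[i] * nls
            ref_img[rr, cc] = ref_val
            rep_img[rr, cc] = rep_val
            ref_mean = ref_val
            if focal is not None:
                off, gain_now, spot_r = focal
                sy, sx = cy + off[0] * radii[i], cx + off[1] * radii[i]
                spot = np.exp(
                    -((yy[rr, cc] - sy) ** 2 + (xx[rr, cc] - sx) ** 2)
                    / (2.0 * spot_r**2)
                )
                ref_img[rr, cc] *= 1.0 + (gain_now - 1.0) * spot
                if rr.size:
                    ref_mean = float(ref_img[rr, cc].mean())
            cent_rows.append((t, i, cy, cx))
            trace_rows.append((t, i, ref_mean, rep_val))
        # soften edges (optical blur), add background, illumination, noise
        for c, img in ((0, ref_img), (1, rep_img)):
            img = ndi.gaussian_filter(img, 1.0) + spec.background_level
            img *= illum[t]
            if spec.noise_poisson:
                img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
            if spec.noise_gaussian_sd > 0:
                img = img + rng.normal(0.0, spec.noise_gaussian_sd, img.shape)
            data[t, c] = np.clip(img, 0.0, None)

    events = pd.DataFrame(
        [
            {
                "nucleus_id": e.nucleus_id,
                "onset_frame": e.onset_frame,
                "onset_time_min": e.onset_frame * spec.frame_interval,
                "drop_fraction": e.drop_fraction,
                "recovery_tau": e.recovery_tau,
                "true_halftime_min": e.true_halftime,
                "contraction_fraction": e.contraction_fraction,
                "h2b_focal_gain": e.h2b_focal_gain,
            }
            for e in spec.rupture_script
        ],
        columns=[
            "nucleus_id",
            "onset_frame",
            "onset_time_min",
            "drop_fraction",
            "recovery_tau",
            "true_halftime_min",
            "contraction_fraction",
            "h2b_focal_gain",
        ],
    )
    truth = GroundTruth(
        events=events,
        centroids=pd.DataFrame(
            cent_rows, columns=["frame", "nucleus_id", "y", "x"]
        ),
        traces=pd.DataFrame(
            trace_rows, columns=["frame", "nucleus_id", "ref_true", "rep_true"]
        ),
        labels=labels,
    )
    stack = FrameStack(
        data=data,
        frame_interval=spec.frame_interval,
        channel_roles={"reference": 0, "reporter": 1},
    )
    return stack, truth


# ---------------------------------------------------------------------------
# trace-level shortcut


def simulate_trace(
    entry: RuptureScriptEntry,
    n_frames: int,
    frame_interval: float = 2.0,
    ref_baseline: float = 1000.0,
    rep_baseline: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one nucleus's intensity trace without rendering images.

    Reporter follows ``B * (1 - drop * exp(-(t - t_onset)/tau))`` from onset
    on; reference is constant. Gaussian noise of SD ``noise_sd`` is added to
    both channels. Returns ``(trace, truth_events)`` where ``trace`` has
    columns frame, time_min, ref, rep, is_gap and ``truth_events`` is a
    one-row event table matching :class:`GroundTruth`'s events schema.
    """
    if not 0 <= entry.onset_frame < n_frames:
        raise ValueError("onset_frame outside the frame grid")
    t = np.arange(n_frames) * frame_interval
    onset_min = entry.onset_frame * frame_interval
    rep = rep_baseline * np.array(
        [_nls_factor(entry, tm, onset_min) for tm in t]
    )
    ref = np.full(n_frames, float(ref_baseline))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ref = ref + rng.normal(0, noise_sd, n_frames)
        rep = rep + rng.normal(0, noise_sd, n_frames)
    trace = pd.DataFrame(
        {
            "frame": np.arange(n_frames),
            "time_min": t,
            "ref": ref,
            "rep": rep,
            "is_gap": False,
        }
    )
    truth = pd.DataFrame(
        [
            {
                "nucleus_id": entry.nucleus_id,
                "onset_frame": entry.onset_frame,
                "onset_time_min": onset_min,
                "drop_fraction": entry.drop_fraction,
                "recovery_tau": entry.recovery_tau,
                "true_halftime_min": entry.true_halftime,
                "contraction_fraction": entry.contraction_fraction,
                "h2b_focal_gain": entry.h2b_focal_gain,
            }
        ]
    )
    return trace, truth


def sample_halftimes(
    component_means: tuple[float, float] = (13.0, 67.0),
    component_sds: tuple[float, float] = (6.0, 43.0),
    weights: tuple[float, float] = (0.5, 0.5),
    n: int = 200,
    seed: int | None = None,
) -> np.ndarray:
    """Draw a positive halftime sample from a two-component normal mixture.

    Defaults emulate the fast/slow recovery populations seen in
    lamin-A/C-knockout fibroblasts (13 +/- 6 and 67 +/- 43 min); negative
    draws are rejected and resampled so all halftimes are > 0.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (2,) or np.any(w < 0) or not math.isclose(w.sum(), 1.0):
        raise ValueError("weights must be two non-negatives summing to 1")
    sds = np.asarray(component_sds, dtype=float)
    if np.any(sds <= 0):
        raise ValueError("component SDs must be positive")
    means = np.asarray(component_means, dtype=float)
    rng = np.random.default_rng(seed)
    if n == 0:
        return np.empty(0)
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = n - filled
        comp = rng.choice(2, size=m, p=w)
        draw = rng.normal(means[comp], sds[comp])
        ok = draw > 0
        k = int(ok.sum())
        out[filled : filled + k] = draw[ok]
        filled += k
    return out
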