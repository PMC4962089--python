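# rupturekit

Quantitative analysis of **spontaneous nuclear-envelope ruptures** in
live-cell fluorescence time-lapse recordings.

Nuclei of lamin-A/C-deficient cells (laminopathy models, many cancers)
transiently lose nucleo-cytoplasmic compartmentalization: a fluorescent
protein carrying a nuclear localization signal (NLS) abruptly leaks into the
cytoplasm and is slowly re-imported as the envelope reseals. Because these
events are stochastic and rare, studying their kinetics requires automated
detection across hundreds of tracked nuclei and *in silico* synchronization
of the events to a common onset. `rupturekit` implements that workflow for
two-channel recordings — a chromatin-bound **H2B** reference marker that
stays nuclear through ruptures, and the shuttling **NLS reporter**:

1. **segment** — per-frame intensity normalization, local contrast
   enhancement, spatiotemporal Gaussian smoothing, Laplacian-of-Gaussian
   blob detection with automatic (Otsu) thresholding, and a conditional
   watershed that separates touching nuclei on size and intensity criteria.
2. **track** — nearest-neighbor linking bounded by a maximum displacement,
   with temporal gap filling and removal of short (< 60 min) tracks.
3. **ruptures** — the core statistic ΔH/N, the per-frame fold change of the
   per-nucleus H2B/NLS mean-intensity ratio,

   ΔH/N(t) = [H(t)/N(t)] / [H(t−1)/N(t−1)],

   which spikes above the fixed threshold **1.2** (a 20% ratio step) at
   rupture onset and is *exactly* invariant to global illumination or focus
   fluctuations (both channels scale identically). Each event is
   characterized by its **extent** (fractional NLS drop from the pre-rupture
   baseline to the post-rupture minimum) and, for recoveries that return to
   ≥ 95% of baseline, the **recovery halftime T_r** (time from onset to the
   half-way crossing between minimum and baseline). Events are synchronized
   to onset for ensemble recovery curves, and nuclear plasticity is scored
   as the coefficient of variation of circularity (4πA/P²) over time.
4. **stats** — Hartigan's dip test for non-unimodality of the halftime
   sample (bootstrap p-value against the uniform null), a two-component
   normal mixture fitted by multi-start EM (fast vs slow recovery
   populations), the **tipping point** (halftime with equal posterior
   membership probability, the root of w₁φ₁(x) = w₂φ₂(x) between the
   component means), and the extent-vs-halftime OLS regression with R².
5. **synthgen** — a synthetic movie generator with exact ground truth
   (label masks, centroids, noise-free traces, scripted events) that
   emulates the acquisition: dysmorphic nuclei moving and deforming in 2D,
   per-cell expression variability, global illumination dips hitting both
   channels, and scripted ruptures with exponential recovery — used to
   validate every stage quantitatively.

## Worked example

```python
import rupturekit as rk

# a 10-nucleus, 150-frame (2 min/frame) recording with one scripted rupture
spec = rk.SceneSpec(
    n_nuclei=10, frame_count=150, rng_seed=42,
    rupture_script=(
        rk.RuptureScriptEntry(nucleus_id=3, onset_frame=30,
                              drop_fraction=0.5, recovery_tau=20.0),
    ),
)
stack, truth = rk.render_timelapse(spec)

normalized = rk.normalize_intensity(stack)
labels, detections = rk.detect_nuclei(normalized, "reference")
tracks = rk.filter_tracks(
    rk.link_tracks(detections, stack.frame_interval), min_duration=60
)

from rupturekit.pipeline import build_traces
from rupturekit.track import tracks_to_dataframe

events = []
for trace in build_traces(tracks_to_dataframe(tracks)).values():
    events.extend(rk.extract_events(trace, threshold=1.2))
for e in events:
    print(f"track {e.track_id}: onset {e.onset_time:.0f} min, "
          f"extent {e.extent:.2f}, T_r {e.t_r:.1f} min")
```

prints

```
track 3: onset 60 min, extent 0.46, T_r 14.0 min
```

one event on the scripted nucleus: onset at frame 30 (60 min), a 0.46
measured intensity drop (the scripted 0.5 nuclear drop, slightly diluted by
background at image level), and a halftime of 14.0 min against the
closed-form truth tau·ln 2 = 13.9 min.

The same pipeline runs from the shell:

```bash
rupturekit run --config scene.yaml --out results/ --seed 42
```

producing `detections.csv`, `tracks.csv`, `events.csv`, `ensemble.csv`,
`halftimes.csv`, `fit.json` (dip test, mixture components, tipping point,
extent-vs-halftime regression) and a reproducibility manifest.

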