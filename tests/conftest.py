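import numpy as np
import pytest

from rupturekit import (
    FrameStack,
    RuptureScriptEntry,
    SceneSpec,
    render_timelapse,
)


@pytest.fixture(scope="session")
def small_scene():
    """Five nuclei, 40 frames, one scripted rupture; shared across tests."""
    spec = SceneSpec(
        n_nuclei=5,
        frame_count=40,
        image_size=(192, 192),
        rng_seed=11,
        rupture_script=(
            RuptureScriptEntry(
                nucleus_id=2, onset_frame=15, drop_fraction=0.4,
                recovery_tau=14.43,
            ),
        ),
    )
    stack, truth = render_timelapse(spec)
    return spec, stack, truth


@pytest.fixture()
def disk_stack():
    """Two-frame stack with one bright disk, for measurement tests."""
    from skimage.draw import disk

    img = np.full((128, 128), 100.0)
    rr, cc = disk((64, 64), 30)
    img[rr, cc] = 1000.0
    data = np.stack([np.stack([img, img]), np.stack([img, img])], axis=1)
    return FrameStack(data, channel_roles={"reference": 0, "reporter": 1})


def make_trace_df(rep, ref=None, frame_interval=2.0, track_id=0, area=None):
    """Tidy one-track table from raw series, for event-analysis tests."""
    import pandas as pd

    rep = np.asarray(rep, dtype=float)
    n = len(rep)
    df = pd.DataFrame(
        {
            "track_id": track_id,
            "frame": np.arange(n),
            "time_min": np.arange(n) * frame_interval,
            "mean_ref": np.full(n, 1000.0) if ref is None else np.asarray(ref, float),
            "mean_rep": rep,
            "is_gap": False,
        }
    )
    if area is not None:
        df["area"] = np.asarray(area, dtype=float)
    return df
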