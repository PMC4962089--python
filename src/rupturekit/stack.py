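"""Multi-frame, multi-channel image container and TIFF round-trip.

The central raw-data object is a :class:`FrameStack`: a ``T x C x Y x X``
intensity volume with acquisition metadata (frame interval in minutes,
optional pixel size) and a mapping of channel *roles* — ``reference`` for the
chromatin-bound marker (H2B) that stays nuclear through envelope ruptures,
and ``reporter`` for the NLS-tagged shuttling marker that leaks out of the
nucleus when the envelope breaks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["FrameStack", "read_stack", "write_stack"]

_META_PREFIX = "rupturekit:"


@dataclass
class FrameStack:
    """T x C x Y x X fluorescence time-lapse with acquisition metadata.

    Parameters
    ----------
    data
        Intensity array, axis order ``(frame, channel, y, x)``; non-negative.
    frame_interval
        Time between consecutive frames, minutes.
    pixel_size
        Lateral pixel size in micrometres per pixel, or ``None`` if unknown.
    channel_roles
        Maps ``"reference"`` / ``"reporter"`` to channel indices. Single-marker
        recordings carry only ``"reporter"``.
    """

    data: np.ndarray
    frame_interval: float = 2.0
    pixel_size: float | None = None
    channel_roles: dict[str, int] = field(
        default_factory=lambda: {"reference": 0, "reporter": 1}
    )

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"expected TCYX data with 4 axes, got shape {self.data.shape}"
            )
        if self.n_frames < 2:
            raise ValueError("a time-lapse needs at least 2 frames")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive (minutes)")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")
        for role, idx in self.channel_roles.items():
            if not 0 <= idx < self.n_channels:
                raise ValueError(f"channel role {role!r} -> {idx} out of range")

    # -- shape shortcuts ---------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel(self, role_or_index: str | int) -> np.ndarray:
        """T x Y x X view of one channel, addressed by role name or index."""
        if isinstance(role_or_index, str):
            try:
                idx = self.channel_roles[role_or_index]
            except KeyError:
                raise KeyError(
                    f"no channel with role {role_or_index!r}; "
                    f"available roles: {sorted(self.channel_roles)}"
                ) from None
        else:
            idx = int(role_or_index)
        return self.data[:, idx]

    def times_min(self) -> np.ndarray:
        """Acquisition time of each frame in minutes (frame 0 at t=0)."""
        return np.arange(self.n_frames, dtype=float) * self.frame_interval

    def with_data(self, data: np.ndarray) -> "FrameStack":
        """Copy of this stack carrying new pixel data, same metadata."""
        return replace(self, data=data)


def write_stack(path: str | Path, stack: FrameStack) -> None:
    """Write a stack as multi-page TIFF (TCYX) with metadata in the description."""
    meta = {
        "frame_interval": stack.frame_interval,
        "pixel_size": stack.pixel_size,
        "channel_roles": stack.channel_roles,
        "axes": "TCYX",
    }
    tifffile.imwrite(
        str(path),
        np.asarray(stack.data, dtype=np.float32),
        description=_META_PREFIX + json.dumps(meta),
        photometric="minisblack",
    )


def read_stack(
    path: str | Path,
    frame_interval: float | None = None,
    channel_roles: dict[str, int] | None = None,
) -> FrameStack:
    """Read a TCYX TIFF written by :func:`write_stack` or any TCYX stack.

    Metadata embedded by :func:`write_stack` is recovered automatically;
    explicit ``frame_interval`` / ``channel_roles`` arguments override it
    (and are required for foreign TIFFs without embedded metadata).
    """
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description or ""
    meta: dict = {}
    if desc.startswith(_META_PREFIX):
        meta = json.loads(desc[len(_META_PREFIX):])
    if data.ndim == 3:  # single-channel TYX -> insert channel axis
        data = data[:, None]
    if data.ndim != 4:
        raise ValueError(f"cannot interpret TIFF with shape {data.shape} as TCYX")
    interval = frame_interval if frame_interval is not None else meta.get(
        "frame_interval", 2.0
    )
    roles = channel_roles if channel_roles is not None else meta.get("channel_roles")
    if roles is None:
        roles = {"reference": 0, "reporter": 1} if data.shape[1] >= 2 else {
            "reporter": 0
        }
    roles = {k: int(v) for k, v in roles.items()}
    return FrameStack(
        data=data,
        frame_interval=float(interval),
        pixel_size=meta.get("pixel_size"),
        channel_roles=roles,
    )
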