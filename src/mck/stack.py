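"""FrameStack: a calibrated multi-channel 2D time-lapse, and its TIFF I/O.

The in-memory layout is a single array of shape (T, C, H, W); the physical
calibration (nm/pixel, s/frame) travels with the data. On disk a stack is a
multi-page TIFF whose ImageDescription carries a small JSON record with the
calibration and channel names, so a write/read round trip is lossless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

_DESCRIPTION_KEY = "mck_stack"


@dataclass
class FrameStack:
    data: np.ndarray                      # (T, C, H, W)
    channel_names: list[str]
    pixel_size: float                     # nm / pixel
    frame_interval: float                 # s / frame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("FrameStack data must be (T, C, H, W)")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must match axis 1")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def channel_index(self, channel: str | int) -> int:
        if isinstance(channel, (int, np.integer)):
            return int(channel)
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise KeyError(f"unknown channel {channel!r}; "
                           f"have {self.channel_names}") from None

    def frame(self, t: int, channel: str | int) -> np.ndarray:
        """One 2D intensity grid."""
        return self.data[t, self.channel_index(channel)]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


def write_stack(stack: FrameStack, path: str | Path) -> Path:
    """Write a FrameStack as multi-page TIFF (dimension order TCYX)."""
    path = Path(path)
    desc = json.dumps({
        _DESCRIPTION_KEY: {
            "pixel_size_nm": stack.pixel_size,
            "frame_interval_s": stack.frame_interval,
            "channel_names": stack.channel_names,
            "axes": "TCYX",
            "metadata": stack.metadata,
        }
    }, sort_keys=True)
    tifffile.imwrite(path, stack.data, description=desc,
                     photometric="minisblack")
    return path


def read_stack(path: str | Path,
               pixel_size: float | None = None,
               frame_interval: float | None = None,
               channel_names: list[str] | None = None) -> FrameStack:
    """Read a TIFF/OME-TIFF into a FrameStack with axes normalized to TCYX.

    Calibration is taken from the file's own metadata (stacks written by
    :func:`write_stack`, or OME pixel sizes) and can be overridden by the
    explicit arguments. A file with no recoverable calibration and no
    override is rejected with an actionable message.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        arr = series.asarray()
        axes = series.axes  # e.g. "TCYX", "YX", "QYX"
        own = None
        desc = tif.pages[0].description or ""
        if _DESCRIPTION_KEY in desc:
            try:
                own = json.loads(desc)[_DESCRIPTION_KEY]
            except (json.JSONDecodeError, KeyError):
                own = None
        ome_px = None
        ome_dt = None
        if tif.ome_metadata:
            # cheap scrape of OME PhysicalSizeX (um) and TimeIncrement (s)
            import re
            m = re.search(r'PhysicalSizeX="([\d.eE+-]+)"', tif.ome_metadata)
            if m:
                ome_px = float(m.group(1)) * 1000.0
            m = re.search(r'TimeIncrement="([\d.eE+-]+)"', tif.ome_metadata)
            if m:
                ome_dt = float(m.group(1))

    if own is not None:
        n_c = len(own["channel_names"])
        data = arr.reshape((-1, n_c) + arr.shape[-2:])
        names = channel_names or own["channel_names"]
        px = pixel_size or own["pixel_size_nm"]
        dt = frame_interval or own["frame_interval_s"]
        return FrameStack(data, list(names), px, dt,
                          metadata=own.get("metadata", {}))

    # generic TIFF: normalize dimensions to TCYX
    if arr.ndim == 2:
        data = arr[None, None]
    elif arr.ndim == 3:
        if "C" in axes and "T" not in axes:
            data = arr[None]            # CYX
        else:
            data = arr[:, None]         # TYX (or unknown leading axis)
    elif arr.ndim == 4:
        if axes.startswith("CT"):
            data = np.swapaxes(arr, 0, 1)
        else:
            data = arr                  # assume TCYX
    else:
        raise ValueError(f"cannot interpret {arr.ndim}-dimensional TIFF "
                         f"{path} as (T)(C)YX")

    px = pixel_size if pixel_size is not None else ome_px
    dt = frame_interval if frame_interval is not None else ome_dt
    if px is None or dt is None:
        raise ValueError(
            f"{path} carries no pixel size / frame interval metadata; pass "
            "pixel_size= (nm) and frame_interval= (s) explicitly")
    names = channel_names or [f"ch{i}" for i in range(data.shape[1])]
    return FrameStack(data, list(names), px, dt)
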