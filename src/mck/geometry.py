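"""Polylines and the pixel/physical coordinate convention.

Convention used throughout the package: arrays are indexed ``[row, col]``;
the physical position of pixel ``(row, col)`` is its centre,
``x = (col + 0.5) * pixel_size`` and ``y = (row + 0.5) * pixel_size``,
with all distances in nm and times in s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


def px_to_nm(index: np.ndarray | float, pixel_size: float) -> np.ndarray | float:
    """Pixel index (row or col) to physical coordinate of the pixel centre."""
    return (np.asarray(index, dtype=float) + 0.5) * pixel_size


def nm_to_px(coord: np.ndarray | float, pixel_size: float) -> np.ndarray | float:
    """Physical coordinate to fractional pixel index (pixel-centre origin)."""
    return np.asarray(coord, dtype=float) / pixel_size - 0.5


@dataclass
class Polyline:
    """An ordered planar polyline in physical coordinates.

    Parameters
    ----------
    vertices : array of shape (n, 2)
        Vertex positions ``(x, y)`` in nm; at least two vertices.
    sampling_step : float
        Spacing of sample points along the arc, in nm.
    """

    vertices: np.ndarray
    sampling_step: float = 32.0
    line_id: str = "line"

    def __post_init__(self):
        self.vertices = np.atleast_2d(np.asarray(self.vertices, dtype=float))
        if self.vertices.shape[0] < 2 or self.vertices.shape[1] != 2:
            raise ValueError("polyline needs >=2 (x, y) vertices")
        if self.sampling_step <= 0:
            raise ValueError("sampling_step must be > 0")
        if self.length <= 0:
            raise ValueError("polyline arc length must be > 0")

    @property
    def _seg_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)

    @property
    def length(self) -> float:
        """Total arc length in nm."""
        return float(self._seg_lengths.sum())

    def arc_positions(self) -> np.ndarray:
        """Evenly spaced arc positions 0, step, 2*step, ... <= length."""
        n = int(np.floor(self.length / self.sampling_step + 1e-9)) + 1
        return np.arange(n) * self.sampling_step

    def points_at(self, arc: np.ndarray) -> np.ndarray:
        """Interpolate (x, y) positions at the given arc positions (nm)."""
        arc = np.asarray(arc, dtype=float)
        cum = np.concatenate([[0.0], np.cumsum(self._seg_lengths)])
        x = np.interp(arc, cum, self.vertices[:, 0])
        y = np.interp(arc, cum, self.vertices[:, 1])
        return np.column_stack([x, y])

    def sample_points(self) -> np.ndarray:
        """(x, y) positions at :meth:`arc_positions`."""
        return self.points_at(self.arc_positions())

    def tangents_at(self, arc: np.ndarray) -> np.ndarray:
        """Unit tangent vectors at the given arc positions."""
        arc = np.asarray(arc, dtype=float)
        cum = np.concatenate([[0.0], np.cumsum(self._seg_lengths)])
        seg = np.clip(np.searchsorted(cum, arc, side="right") - 1, 0,
                      len(self._seg_lengths) - 1)
        d = np.diff(self.vertices, axis=0)
        t = d[seg]
        norm = np.linalg.norm(t, axis=1, keepdims=True)
        return t / np.where(norm == 0, 1.0, norm)


def polylines_to_csv(lines: list[Polyline], path: str | Path,
                     pixel_size: float) -> None:
    """Write polylines as CSV with columns line_id, vertex_index, x_px, y_px."""
    rows = []
    for line in lines:
        for i, (x, y) in enumerate(line.vertices):
            rows.append({"line_id": line.line_id, "vertex_index": i,
                         "x_px": nm_to_px(x, pixel_size),
                         "y_px": nm_to_px(y, pixel_size)})
    pd.DataFrame(rows).to_csv(path, index=False)


def polylines_from_csv(path: str | Path, pixel_size: float,
                       sampling_step: float = 32.0) -> list[Polyline]:
    """Read polylines from the CSV dialect written by :func:`polylines_to_csv`."""
    df = pd.read_csv(path)
    lines = []
    for line_id, grp in df.groupby("line_id", sort=False):
        grp = grp.sort_values("vertex_index")
        verts = np.column_stack([px_to_nm(grp["x_px"].to_numpy(), pixel_size),
                                 px_to_nm(grp["y_px"].to_numpy(), pixel_size)])
        lines.append(Polyline(verts, sampling_step, line_id=str(line_id)))
    return lines


def polylines_from_json(path: str | Path,
                        sampling_step: float = 32.0) -> list[Polyline]:
    """Read polylines from a JSON list of {line_id, vertices_nm} objects."""
    with open(path) as fh:
        data = json.load(fh)
    return [Polyline(np.asarray(entry["vertices_nm"], dtype=float),
                     sampling_step, line_id=str(entry.get("line_id", i)))
            for i, entry in enumerate(data)]
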