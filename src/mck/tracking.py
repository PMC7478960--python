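"""Single-particle tracks: detection, linking, velocities, cross-correlation,
mean squared displacement with anomalous-exponent fitting, and kymographs.

The motion statistic of interest is the time-averaged MSD
``MSD(tau) = <|r(t + tau) - r(t)|^2>_t`` and its power-law exponent alpha
(log-log slope over short lags): alpha = 1 for free diffusion, alpha = 2 for
ballistic motion, alpha > 1 for directed/superdiffusive transport such as
motor-driven nucleoid movement. Coupling between a dynamic tubule tip and a
nucleoid riding in the tubule is quantified as the zero-lag Pearson
correlation of their frame-to-frame speed sequences, with a companion
position correlation reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import BoundsError, DegenerateProfileError, DegenerateTrackError
from .geometry import Polyline, px_to_nm
from .stack import FrameStack


@dataclass
class Track:
    """Time-indexed planar positions of one tracked object.

    ``frames`` are strictly increasing integer frame indices; ``xy`` holds
    the positions in nm; ``frame_interval`` converts frame gaps to seconds.
    """

    object_id: str
    frames: np.ndarray
    xy: np.ndarray                        # (n, 2) nm
    frame_interval: float                 # s

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float).reshape(len(self.frames), 2)
        if len(self.frames) and np.any(np.diff(self.frames) <= 0):
            raise ValueError("track frames must be strictly increasing")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return self.frames * self.frame_interval

    def position_at(self, frame: int) -> np.ndarray:
        i = np.searchsorted(self.frames, frame)
        if i >= len(self.frames) or self.frames[i] != frame:
            raise KeyError(f"frame {frame} not in track {self.object_id!r}")
        return self.xy[i]


def tracks_to_csv(tracks: list[Track], path: str | Path) -> None:
    """Write tracks as CSV with columns object_id, frame, x_nm, y_nm."""
    rows = [{"object_id": t.object_id, "frame": int(f),
             "x_nm": x, "y_nm": y}
            for t in tracks for f, (x, y) in zip(t.frames, t.xy)]
    pd.DataFrame(rows, columns=["object_id", "frame", "x_nm", "y_nm"]) \
        .to_csv(path, index=False)


def tracks_from_csv(path: str | Path, frame_interval: float) -> list[Track]:
    df = pd.read_csv(path)
    out = []
    for oid, grp in df.groupby("object_id", sort=False):
        grp = grp.sort_values("frame")
        out.append(Track(str(oid), grp["frame"].to_numpy(),
                         grp[["x_nm", "y_nm"]].to_numpy(), frame_interval))
    return out


# --------------------------------------------------------------------------
# detection and linking

def detect_spots(frame: np.ndarray, expected_sigma: float,
                 min_quality: float, pixel_size: float) -> pd.DataFrame:
    """Scale-matched Laplacian-of-Gaussian blob detection with sub-pixel
    quadratic peak refinement.

    Quality is the peak's scale-normalized LoG response relative to the
    strongest response in the frame (1.0 for the brightest spot); detections
    below ``min_quality`` are dropped. Returns a DataFrame with columns
    x_nm, y_nm, quality (possibly empty).
    """
    if expected_sigma <= 0:
        raise ValueError("expected_sigma must be > 0")
    img = np.asarray(frame, dtype=float)
    sigma_px = expected_sigma / pixel_size
    # bright blobs give positive scale-normalized response
    resp = -(sigma_px ** 2) * ndimage.gaussian_laplace(img, sigma_px)
    max_resp = resp.max()
    if not np.isfinite(max_resp) or max_resp <= 0:
        return pd.DataFrame(columns=["x_nm", "y_nm", "quality"])
    # local maxima over a neighbourhood matched to the blob scale
    size = max(3, 2 * int(np.ceil(sigma_px)) + 1)
    footprint_max = ndimage.maximum_filter(resp, size=size, mode="nearest")
    peaks = np.argwhere((resp == footprint_max)
                        & (resp >= min_quality * max_resp)
                        & (resp > 0))
    # non-maximum suppression: plateau ties yield several equal peaks
    order = np.argsort(-resp[peaks[:, 0], peaks[:, 1]], kind="stable")
    kept: list[np.ndarray] = []
    for p in peaks[order]:
        if all(max(abs(p[0] - q[0]), abs(p[1] - q[1])) >= size for q in kept):
            kept.append(p)
    rows = []
    for r, c in kept:
        dr = dc = 0.0
        if 0 < r < resp.shape[0] - 1:
            denom = resp[r - 1, c] - 2 * resp[r, c] + resp[r + 1, c]
            if denom < 0:
                dr = float(np.clip(0.5 * (resp[r - 1, c] - resp[r + 1, c])
                                   / denom, -0.5, 0.5))
        if 0 < c < resp.shape[1] - 1:
            denom = resp[r, c - 1] - 2 * resp[r, c] + resp[r, c + 1]
            if denom < 0:
                dc = float(np.clip(0.5 * (resp[r, c - 1] - resp[r, c + 1])
                                   / denom, -0.5, 0.5))
        rows.append({"x_nm": px_to_nm(c + dc, pixel_size),
                     "y_nm": px_to_nm(r + dr, pixel_size),
                     "quality": resp[r, c] / max_resp})
    return pd.DataFrame(rows, columns=["x_nm", "y_nm", "quality"])


def link_tracks(detections: list[np.ndarray], max_disp: float,
                frame_interval: float) -> list[Track]:
    """Greedy nearest-neighbour frame-to-frame linking.

    ``detections`` is one (n_t, 2) nm array per frame. Candidate links are
    sorted by (distance, previous-point index, current-point index) and
    assigned greedily under ``max_disp``; unmatched detections start new
    tracks; a track unmatched in a frame ends (no gap closing).
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be > 0")
    next_id = 0
    active: list[tuple[int, list[int], list[np.ndarray]]] = []  # id, frames, xy
    finished: list[Track] = []

    for t, pts in enumerate(detections):
        pts = np.atleast_2d(np.asarray(pts, dtype=float)) \
            if np.size(pts) else np.empty((0, 2))
        assigned_prev: set[int] = set()
        assigned_cur: set[int] = set()
        links: dict[int, int] = {}
        if active and len(pts):
            prev_xy = np.array([trk[2][-1] for trk in active])
            d = np.linalg.norm(prev_xy[:, None, :] - pts[None, :, :], axis=2)
            cand = [(d[i, j], i, j)
                    for i in range(d.shape[0]) for j in range(d.shape[1])
                    if d[i, j] <= max_disp]
            for dist, i, j in sorted(cand):
                if i in assigned_prev or j in assigned_cur:
                    continue
                assigned_prev.add(i)
                assigned_cur.add(j)
                links[i] = j
        still_active = []
        for i, trk in enumerate(active):
            if i in links:
                trk[1].append(t)
                trk[2].append(pts[links[i]])
                still_active.append(trk)
            else:
                finished.append(trk)
        for j in range(len(pts)):
            if j not in assigned_cur:
                still_active.append((next_id, [t], [pts[j]]))
                next_id += 1
        active = still_active

    finished.extend(active)
    finished.sort(key=lambda trk: trk[0])
    return [Track(f"track_{tid}", np.asarray(frames), np.asarray(xy),
                  frame_interval)
            for tid, frames, xy in finished]


# --------------------------------------------------------------------------
# per-track statistics

def velocities(track: Track) -> np.ndarray:
    """Per-interval speeds: Euclidean displacement over elapsed time (nm/s)."""
    if len(track) < 2:
        raise ValueError("velocity needs >=2 samples")
    disp = np.linalg.norm(np.diff(track.xy, axis=0), axis=1)
    dt = np.diff(track.frames) * track.frame_interval
    return disp / dt


@dataclass
class TrajectoryCorrelation:
    speed_correlation: float
    position_correlation: float
    n_common_frames: int


def trajectory_correlation(track_a: Track,
                           track_b: Track) -> TrajectoryCorrelation:
    """Zero-lag Pearson correlation between two tracks' motion.

    Speeds are computed on the tracks restricted to their common frames; the
    reported speed correlation is the Pearson correlation of the two speed
    sequences. A companion position correlation (mean of per-axis Pearson
    correlations of the coordinates; axes without spread in either track are
    skipped) is reported alongside. Zero-variance speed sequences raise
    :class:`DegenerateTrackError`.
    """
    common = np.intersect1d(track_a.frames, track_b.frames)
    if len(common) < 3:
        raise ValueError("need >=3 common frames")
    xa = np.array([track_a.position_at(f) for f in common])
    xb = np.array([track_b.position_at(f) for f in common])
    dt = np.diff(common) * track_a.frame_interval
    sa = np.linalg.norm(np.diff(xa, axis=0), axis=1) / dt
    sb = np.linalg.norm(np.diff(xb, axis=0), axis=1) / dt
    if np.ptp(sa) == 0 or np.ptp(sb) == 0:
        raise DegenerateTrackError("speed sequence has zero variance")
    speed_r = float(np.corrcoef(sa, sb)[0, 1])
    axis_r = [float(np.corrcoef(xa[:, k], xb[:, k])[0, 1])
              for k in range(2)
              if np.ptp(xa[:, k]) > 0 and np.ptp(xb[:, k]) > 0]
    pos_r = float(np.mean(axis_r)) if axis_r else np.nan
    return TrajectoryCorrelation(speed_r, pos_r, len(common))


def msd(track: Track, max_lag: int) -> pd.DataFrame:
    """Time-averaged mean squared displacement.

    For each lag the squared displacement is averaged over every sample pair
    separated by exactly that many frames. Returns a DataFrame with columns
    lag_s and msd_nm2.
    """
    if max_lag >= len(track):
        raise ValueError("max_lag must be < track length")
    frames = track.frames
    lags, values = [], []
    if np.all(np.diff(frames) == 1):
        for lag in range(1, max_lag + 1):
            d = track.xy[lag:] - track.xy[:-lag]
            lags.append(lag * track.frame_interval)
            values.append(float(np.mean(np.sum(d * d, axis=1))))
    else:
        index = {int(f): i for i, f in enumerate(frames)}
        for lag in range(1, max_lag + 1):
            sq = [np.sum((track.xy[index[f + lag]] - track.xy[i]) ** 2)
                  for i, f in enumerate(frames) if f + lag in index]
            if sq:
                lags.append(lag * track.frame_interval)
                values.append(float(np.mean(sq)))
    return pd.DataFrame({"lag_s": lags, "msd_nm2": values})


def ensemble_msd(tracks: list[Track], max_lag: int) -> pd.DataFrame:
    """Mean across tracks of the per-track time-averaged MSD."""
    tables = [msd(t, max_lag) for t in tracks]
    merged = pd.concat(tables).groupby("lag_s", as_index=False).mean()
    return merged


@dataclass
class MsdFit:
    """Power-law fit MSD(tau) ~ tau^alpha on log-log axes."""

    lags: np.ndarray                      # s
    msd: np.ndarray                       # nm^2
    alpha: float
    log_intercept: float
    fit_range: tuple[int, int]            # [start, stop) lag indices
    r_squared: float

    def summary(self) -> dict:
        return {"alpha": self.alpha, "log_intercept": self.log_intercept,
                "fit_lags": [float(self.lags[self.fit_range[0]]),
                             float(self.lags[self.fit_range[1] - 1])],
                "r_squared": self.r_squared}


def fit_anomalous_exponent(msd_table: pd.DataFrame,
                           fit_fraction: float = 0.25,
                           min_lags: int = 4) -> MsdFit:
    """Least-squares line on (log lag, log MSD) over the first
    ``fit_fraction`` of lags; the slope is the anomalous exponent alpha.

    Restricting the fit to short lags limits the large estimator variance of
    time-averaged MSD at long lags. Any non-positive MSD in the fit range
    raises :class:`DegenerateProfileError`.
    """
    lags = np.asarray(msd_table["lag_s"], dtype=float)
    values = np.asarray(msd_table["msd_nm2"], dtype=float)
    n_fit = max(min_lags, int(np.ceil(fit_fraction * len(lags))))
    if len(lags) < min_lags:
        raise ValueError(f"need >= {min_lags} lags")
    n_fit = min(n_fit, len(lags))
    if np.any(values[:n_fit] <= 0):
        raise DegenerateProfileError("zero MSD in fit range (degenerate track)")
    lx, ly = np.log(lags[:n_fit]), np.log(values[:n_fit])
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - float(np.sum((ly - pred) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return MsdFit(lags, values, float(slope), float(intercept),
                  (0, n_fit), r2)


# --------------------------------------------------------------------------
# kymographs

@dataclass
class Kymograph:
    """Position-time intensity map along a fixed line (rows = time, moving
    top to bottom; columns = arc position)."""

    values: np.ndarray                    # (T, S)
    line: Polyline
    frame_interval: float

    def to_dataframe(self) -> pd.DataFrame:
        arc = self.line.arc_positions()
        return pd.DataFrame(self.values,
                            columns=[f"{a:.1f}" for a in arc])


def kymograph(stack: FrameStack, line: Polyline, channel: str | int,
              width: int = 1) -> Kymograph:
    """Build a kymograph: each row is the linescan of one frame, averaged
    across ``width`` perpendicular one-pixel offsets (width must be odd)."""
    if width % 2 != 1 or width < 1:
        raise ValueError("width must be a positive odd integer")
    arc = line.arc_positions()
    tangents = line.tangents_at(arc)
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    base = line.points_at(arc)
    ci = stack.channel_index(channel)
    half = width // 2
    rows = []
    for t in range(stack.n_frames):
        img = stack.data[t, ci]
        acc = np.zeros(len(arc))
        for o in range(-half, half + 1):
            pts = base + o * stack.pixel_size * normals
            acc += _sample_points(img, pts, stack.pixel_size)
        rows.append(acc / width)
    return Kymograph(np.asarray(rows), line, stack.frame_interval)


def _sample_points(image: np.ndarray, pts: np.ndarray,
                   pixel_size: float) -> np.ndarray:
    from .geometry import nm_to_px
    cols = nm_to_px(pts[:, 0], pixel_size)
    rows = nm_to_px(pts[:, 1], pixel_size)
    h, w = image.shape
    if (np.min(rows) < 0 or np.min(cols) < 0
            or np.max(rows) > h - 1 or np.max(cols) > w - 1):
        raise BoundsError("kymograph line (with width offsets) leaves the "
                          "interpolable image area")
    return ndimage.map_coordinates(np.asarray(image, dtype=float),
                                   [rows, cols], order=1)
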