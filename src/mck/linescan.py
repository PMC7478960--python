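"""Linescan sampling, iterative-shift cross-correlation, and the
colocalization-frequency analysis with its randomized-localization null.

The analysis follows the shift-correlation recipe used for two-channel
super-resolution colocalization: intensity profiles of both channels are
sampled along polylines drawn through mitochondria, the Pearson correlation
between the channels is computed, then recomputed while one channel is
iteratively displaced along the arc in fixed (default 32 nm) increments and
averaged across linescans. The largest displacement at which the averaged
correlation remains significantly positive defines a distance threshold for
calling two point signals colocalized; the significance of the observed
colocalization frequency is assessed against positions redrawn uniformly
within the organelle mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .constants import CONFIDENCE, PIXEL_SIZE_NM, SHIFT_STEP_NM
from .exceptions import BoundsError, EmptyMaskError, ThresholdUndefinedError
from .geometry import Polyline, nm_to_px
from .stack import FrameStack


@dataclass
class Linescan:
    """Intensity of one or more channels sampled along a polyline.

    ``arc_positions`` are nm from the line start, strictly increasing with a
    constant step; each profile in ``channel_profiles`` is aligned to them.
    """

    arc_positions: np.ndarray
    channel_profiles: dict[str, np.ndarray]
    line_id: str = "line"

    def __post_init__(self):
        self.arc_positions = np.asarray(self.arc_positions, dtype=float)
        steps = np.diff(self.arc_positions)
        if len(steps) == 0 or np.any(steps <= 0):
            raise ValueError("arc_positions must be strictly increasing")
        if not np.allclose(steps, steps[0]):
            raise ValueError("arc_positions must have a constant step")
        n = len(self.arc_positions)
        for name, prof in self.channel_profiles.items():
            self.channel_profiles[name] = np.asarray(prof, dtype=float)
            if len(self.channel_profiles[name]) != n:
                raise ValueError(f"profile {name!r} length mismatch")

    @property
    def sampling_step(self) -> float:
        return float(self.arc_positions[1] - self.arc_positions[0])

    @property
    def length(self) -> float:
        return float(self.arc_positions[-1] - self.arc_positions[0])


def sample_profile(image: np.ndarray, line: Polyline,
                   pixel_size: float) -> np.ndarray:
    """Bilinearly interpolate one 2D image along a polyline's sample points."""
    pts = line.sample_points()
    cols = nm_to_px(pts[:, 0], pixel_size)
    rows = nm_to_px(pts[:, 1], pixel_size)
    h, w = image.shape
    if (rows.min() < 0 or cols.min() < 0
            or rows.max() > h - 1 or cols.max() > w - 1):
        raise BoundsError("linescan leaves the interpolable image area")
    return ndimage.map_coordinates(np.asarray(image, dtype=float),
                                   [rows, cols], order=1)


def sample_linescan(stack: FrameStack, line: Polyline, t: int = 0,
                    channels: list[str] | None = None) -> Linescan:
    """Sample a :class:`Linescan` from one frame of a stack.

    Intensities are bilinearly interpolated at evenly spaced arc positions;
    positions are physical (nm) via the stack's pixel size.
    """
    channels = channels if channels is not None else list(stack.channel_names)
    profiles = {c: sample_profile(stack.frame(t, c), line, stack.pixel_size)
                for c in channels}
    return Linescan(line.arc_positions(), profiles, line_id=line.line_id)


@dataclass
class ShiftCurve:
    """Mean Pearson correlation versus lateral shift along the linescan arc.

    ``shift_distances`` covers 0 and +/- multiples of ``step``;
    ``dispersion`` is the standard error of the mean across linescans.
    """

    shift_distances: np.ndarray           # nm, signed, ascending
    mean_correlation: np.ndarray
    dispersion: np.ndarray                # SEM across linescans
    n_used: np.ndarray                    # linescans contributing per shift
    n_linescans: int
    step: float
    confidence: float = CONFIDENCE
    threshold_distance: float | None = None
    exclusions: list = field(default_factory=list)

    def at(self, shift_nm: float) -> tuple[float, float]:
        """(mean correlation, SEM) at a given signed shift."""
        i = int(np.argmin(np.abs(self.shift_distances - shift_nm)))
        if not np.isclose(self.shift_distances[i], shift_nm):
            raise KeyError(f"shift {shift_nm} nm not on the curve")
        return float(self.mean_correlation[i]), float(self.dispersion[i])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"shift_nm": self.shift_distances,
                             "mean_r": self.mean_correlation,
                             "sem": self.dispersion,
                             "n": self.n_used})


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Plain Pearson correlation; NaN when either side has zero variance."""
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def shift_correlation_curve(linescans: list[Linescan],
                            channel_a: str, channel_b: str,
                            max_shift: float,
                            step: float = SHIFT_STEP_NM) -> ShiftCurve:
    """Iterative-shift cross-correlation averaged across linescans.

    For each shift ``s`` (0, +/-step, +/-2*step, ...), channel-B intensities
    are displaced by ``s`` along the arc and the Pearson correlation with
    channel A is computed on the overlapping support of each linescan, then
    averaged across linescans; the per-shift dispersion is the standard error
    across linescans. The zero-shift value is exactly the plain (unshifted)
    Pearson correlation average. Linescans with a zero-variance profile on an
    overlap are excluded from that shift's average and logged.
    """
    if len(linescans) == 0:
        raise ValueError("need at least one linescan")
    for ls in linescans:
        if ls.length <= 2 * max_shift:
            raise ValueError(
                f"linescan {ls.line_id!r} ({ls.length:.0f} nm) must be "
                f"longer than twice max_shift ({2 * max_shift:.0f} nm)")
    steps_per_shift = []
    for ls in linescans:
        k = step / ls.sampling_step
        if abs(k - round(k)) > 1e-9 or round(k) < 1:
            raise ValueError("shift step must be a positive integer multiple "
                             "of the linescan sampling step")
        steps_per_shift.append(int(round(k)))

    n_shifts = int(np.floor(max_shift / step + 1e-9))
    shifts = np.arange(-n_shifts, n_shifts + 1)
    mean_r = np.full(len(shifts), np.nan)
    sem = np.full(len(shifts), np.nan)
    n_used = np.zeros(len(shifts), dtype=int)
    exclusions: list = []

    for idx, m in enumerate(shifts):
        vals = []
        for ls, k in zip(linescans, steps_per_shift):
            j = m * k
            a = ls.channel_profiles[channel_a]
            b = ls.channel_profiles[channel_b]
            n = len(a)
            # shift s pairs a[i] with b[i + s/step]: a channel displaced
            # forward by k steps peaks at +k*step
            if j >= 0:
                a_part, b_part = a[:n - j] if j else a, b[j:]
            else:
                a_part, b_part = a[-j:], b[:n + j]
            r = _pearson(a_part, b_part)
            if np.isnan(r):
                exclusions.append((ls.line_id, float(m * step)))
            else:
                vals.append(r)
        if vals:
            vals = np.asarray(vals)
            mean_r[idx] = vals.mean()
            sem[idx] = (vals.std(ddof=1) / np.sqrt(len(vals))
                        if len(vals) > 1 else 0.0)
            n_used[idx] = len(vals)

    return ShiftCurve(shifts * step, mean_r, sem, n_used,
                      n_linescans=len(linescans), step=step,
                      exclusions=exclusions)


def colocalization_threshold(curve: ShiftCurve,
                             confidence: float = CONFIDENCE) -> float:
    """Distance threshold: the largest shift ``d`` such that at every shift
    ``|s| <= d`` the lower bound of the confidence interval of the mean
    correlation (mean - z*SEM) stays above 0. Contiguity from zero prevents
    spurious far-shift crossings. Raises :class:`ThresholdUndefinedError`
    when already the zero-shift CI includes 0 (distinct from returning 0).
    """
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    d = curve.shift_distances
    lower = curve.mean_correlation - z * curve.dispersion

    def ok(shift_nm: float) -> bool:
        i = int(np.argmin(np.abs(d - shift_nm)))
        return (np.isclose(d[i], shift_nm) and np.isfinite(lower[i])
                and lower[i] > 0)

    if not ok(0.0):
        raise ThresholdUndefinedError(
            "zero-shift confidence interval includes 0; "
            "no colocalization threshold is defined")
    n_max = int(round(d.max() / curve.step))
    threshold = 0.0
    for m in range(1, n_max + 1):
        s = m * curve.step
        if ok(s) and ok(-s):
            threshold = s
        else:
            break
    curve.threshold_distance = threshold
    curve.confidence = confidence
    return threshold


def colocalization_frequency(points_a: np.ndarray, points_b: np.ndarray,
                             threshold: float) -> float:
    """Fraction of A-points whose nearest B-neighbour lies strictly within
    ``threshold`` (nm). Empty B yields 0 with a warning."""
    points_a = np.atleast_2d(np.asarray(points_a, dtype=float))
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if points_a.size == 0:
        raise ValueError("points_a must be nonempty")
    points_b = np.asarray(points_b, dtype=float)
    if points_b.size == 0:
        warnings.warn("points_b is empty; colocalization frequency is 0",
                      stacklevel=2)
        return 0.0
    points_b = np.atleast_2d(points_b)
    dist, _ = cKDTree(points_b).query(points_a)
    return float(np.mean(dist < threshold))


@dataclass
class ColocResult:
    """Observed colocalization frequency against a randomized-position null."""

    observed_fraction: float
    observed_per_image: np.ndarray
    null_fractions: np.ndarray            # one per permutation
    p_value: float
    threshold_used: float
    n_points: int

    @property
    def null_mean(self) -> float:
        return float(self.null_fractions.mean())

    def to_dict(self) -> dict:
        return {"observed_fraction": self.observed_fraction,
                "observed_per_image": list(map(float, self.observed_per_image)),
                "null_mean": self.null_mean,
                "null_sd": float(self.null_fractions.std(ddof=1))
                if len(self.null_fractions) > 1 else 0.0,
                "n_perm": len(self.null_fractions),
                "p_value": self.p_value,
                "threshold_nm": self.threshold_used,
                "n_points": self.n_points}


def _as_image_list(points) -> list[np.ndarray]:
    arr = np.asarray(points, dtype=object)
    if isinstance(points, np.ndarray) and points.ndim == 2:
        return [np.asarray(points, dtype=float)]
    if isinstance(points, (list, tuple)) and len(points) \
            and np.asarray(points[0]).ndim == 2:
        return [np.asarray(p, dtype=float) for p in points]
    return [np.atleast_2d(np.asarray(points, dtype=float))]


def randomized_frequency(points_a, points_b, region_mask: np.ndarray,
                         threshold: float, n_perm: int, seed: int = 0,
                         pixel_size: float = PIXEL_SIZE_NM) -> ColocResult:
    """Colocalization frequency against a randomized-localization null.

    For each permutation the B-points of every image are redrawn uniformly
    within ``region_mask`` (count preserved) and the colocalization frequency
    is recomputed. Significance is a two-tailed unpaired Student's t-test
    between the per-image observed fractions and the per-permutation null
    fractions; with a single image the test degenerates to a one-sample
    t-test of the null fractions against the observed value.

    ``points_a``/``points_b`` may be single (n, 2) nm arrays or sequences of
    such arrays (one per image).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    region_mask = np.asarray(region_mask).astype(bool)
    rows, cols = np.nonzero(region_mask)
    if len(rows) == 0:
        raise EmptyMaskError("region_mask is empty")
    a_list = _as_image_list(points_a)
    b_list = _as_image_list(points_b)
    if len(a_list) != len(b_list):
        raise ValueError("points_a and points_b must have the same number "
                         "of images")
    for b in b_list:
        if len(rows) < len(b):
            raise ValueError("region_mask has fewer pixels than B points "
                             "to place")

    observed = np.array([colocalization_frequency(a, b, threshold)
                         for a, b in zip(a_list, b_list)])
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for p in range(n_perm):
        fracs = []
        for a, b in zip(a_list, b_list):
            idx = rng.integers(0, len(rows), size=len(b))
            u = rng.random((len(b), 2))
            pts = np.column_stack([(cols[idx] + u[:, 0]) * pixel_size,
                                   (rows[idx] + u[:, 1]) * pixel_size])
            fracs.append(colocalization_frequency(a, pts, threshold))
        null[p] = np.mean(fracs)

    if len(observed) >= 2:
        t = stats.ttest_ind(observed, null)
    else:
        t = stats.ttest_1samp(null, observed[0])
    return ColocResult(observed_fraction=float(observed.mean()),
                       observed_per_image=observed,
                       null_fractions=null,
                       p_value=float(t.pvalue),
                       threshold_used=float(threshold),
                       n_points=int(sum(len(a) for a in a_list)))
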