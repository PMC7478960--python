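"""Synthetic fluorescence time-lapse scenes with ground truth.

The generator emulates the imaging situations the analysis stages assume:
tubular mitochondria (80-350 nm diameters) and ER-like tubule meshes drawn
as polylines, ~100-nm nucleoid spots, scripted tubule-extension (MDT) events
with coupled, unsynchronized, or retained nucleoid motion, a 32 nm pixel
grid, an isotropic Gaussian PSF (default sigma 42 nm, ~97 nm FWHM), and a
Poisson-Gaussian (sCMOS-style) noise model. Every rendered object is
recorded in the ground truth, so each downstream stage has a recovery test.

All randomness flows from a single integer seed through deterministic
per-purpose sub-streams: identical (spec, seed) inputs give bit-identical
images and ground truth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.linalg import cholesky

from .constants import (PIXEL_SIZE_NM, PSF_SIGMA_NM, TRANSPORT_WINDOW_S)
from .exceptions import BoundsError
from .geometry import Polyline, px_to_nm
from .stack import FrameStack
from .tracking import Track, tracks_to_csv

#: sentinel for noise-free rendering
NOISELESS = None


@dataclass
class SceneSpec:
    """Acquisition parameters of a simulated scene.

    ``photon_scale`` is the expected photon count at unit intensity; the
    sentinel ``None`` (module constant ``NOISELESS``) disables both shot and
    read noise. Defaults follow live-cell super-resolution practice: 32
    nm/pixel (one colocalization shift increment per pixel), 1 s/frame,
    42 nm PSF sigma.
    """

    field_size: tuple[int, int] = (256, 256)      # (height, width) pixels
    pixel_size: float = PIXEL_SIZE_NM             # nm / pixel
    frame_interval: float = 1.0                   # s
    n_frames: int = 1
    psf_sigma: float = PSF_SIGMA_NM               # nm
    photon_scale: float | None = NOISELESS
    read_noise_sd: float = 0.0                    # intensity units
    seed: int = 0

    def __post_init__(self):
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be >= 0")

    @property
    def field_nm(self) -> tuple[float, float]:
        """(height, width) of the field in nm."""
        h, w = self.field_size
        return h * self.pixel_size, w * self.pixel_size

    def rng(self, stream: int) -> np.random.Generator:
        """Deterministic per-purpose random sub-stream."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed),
                                   spawn_key=(int(stream),)))


@dataclass
class GroundTruth:
    """True positions, occupancy masks, scripted events, and motion
    parameters of every rendered object."""

    object_tracks: dict[str, Track] = field(default_factory=dict)
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    event_log: list[dict] = field(default_factory=list)
    motion_params: dict[str, dict] = field(default_factory=dict)

    def write(self, out_dir: str | Path, prefix: str = "truth") -> dict:
        """Write tracks as CSV and event log / motion params as JSON."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        tracks_path = out_dir / f"{prefix}_tracks.csv"
        tracks_to_csv(list(self.object_tracks.values()), tracks_path)
        meta_path = out_dir / f"{prefix}_events.json"
        with open(meta_path, "w") as fh:
            json.dump({"event_log": self.event_log,
                       "motion_params": self.motion_params}, fh, indent=2,
                      sort_keys=True)
        return {"tracks": tracks_path, "events": meta_path}


# --------------------------------------------------------------------------
# rendering

def _deposit_spots(canvas: np.ndarray, pts: np.ndarray, amps: np.ndarray,
                   spec: SceneSpec) -> None:
    """Add Gaussian intensity profiles (total mass = amplitude) in place."""
    h, w = canvas.shape
    px = spec.pixel_size
    sigma = spec.psf_sigma
    if sigma == 0:
        # bilinear splat of the full mass onto the four nearest pixels
        for (x, y), a in zip(pts, amps):
            cx, cy = x / px - 0.5, y / px - 0.5
            c0, r0 = int(np.floor(cx)), int(np.floor(cy))
            fx, fy = cx - c0, cy - r0
            for dr, dc, wgt in ((0, 0, (1 - fy) * (1 - fx)),
                                (0, 1, (1 - fy) * fx),
                                (1, 0, fy * (1 - fx)),
                                (1, 1, fy * fx)):
                r, c = r0 + dr, c0 + dc
                if 0 <= r < h and 0 <= c < w:
                    canvas[r, c] += a * wgt
        return
    half = int(np.ceil(5 * sigma / px)) + 1
    norm = px * px / (2 * np.pi * sigma * sigma)
    for (x, y), a in zip(pts, amps):
        cc, cr = x / px - 0.5, y / px - 0.5
        r0 = max(0, int(np.floor(cr)) - half)
        r1 = min(h, int(np.ceil(cr)) + half + 1)
        c0 = max(0, int(np.floor(cc)) - half)
        c1 = min(w, int(np.ceil(cc)) + half + 1)
        if r1 <= r0 or c1 <= c0:
            continue
        rows = (np.arange(r0, r1) - cr) * px
        cols = (np.arange(c0, c1) - cc) * px
        g = np.exp(-(rows[:, None] ** 2 + cols[None, :] ** 2)
                   / (2 * sigma * sigma))
        canvas[r0:r1, c0:c1] += a * norm * g


def render(spec: SceneSpec,
           positions: dict[str, np.ndarray | list] | None = None,
           masks: dict[str, np.ndarray] | None = None,
           amplitudes: float | dict[str, float] = 1.0,
           channel_order: list[str] | None = None) -> FrameStack:
    """Render point sets and occupancy masks into a calibrated FrameStack.

    ``positions`` maps channel name -> per-frame point sets ((T, n, 2) array
    or list of (n_t, 2) arrays, nm); each point contributes a Gaussian
    profile of sd ``psf_sigma`` whose total intensity equals its amplitude.
    ``masks`` maps channel name -> (H, W) or (T, H, W) binary occupancy,
    rendered as the occupancy convolved with the PSF. Noise is Poisson on
    ``photon_scale * intensity`` plus Gaussian read noise, in photon units;
    it is off when ``photon_scale`` is the noiseless sentinel.
    """
    positions = positions or {}
    masks = masks or {}
    names = channel_order or (list(positions) + [m for m in masks
                                                 if m not in positions])
    h, w = spec.field_size
    sigma_px = spec.psf_sigma / spec.pixel_size
    data = np.zeros((spec.n_frames, len(names), h, w), dtype=np.float32)

    def amp_for(name):
        return amplitudes.get(name, 1.0) if isinstance(amplitudes, dict) \
            else float(amplitudes)

    for ci, name in enumerate(names):
        for t in range(spec.n_frames):
            canvas = np.zeros((h, w), dtype=float)
            if name in masks:
                m = np.asarray(masks[name])
                m2 = m[t] if m.ndim == 3 else m
                ideal = m2.astype(float) * amp_for(name)
                if sigma_px > 0:
                    ideal = ndimage.gaussian_filter(ideal, sigma_px,
                                                    mode="constant")
                canvas += ideal
            if name in positions:
                per_frame = positions[name]
                pts = np.asarray(per_frame[t], dtype=float) \
                    if not isinstance(per_frame, np.ndarray) \
                    or per_frame.ndim == 3 else np.asarray(per_frame)
                pts = np.atleast_2d(pts)
                if pts.size:
                    amps = np.full(len(pts), amp_for(name))
                    _deposit_spots(canvas, pts, amps, spec)
            data[t, ci] = canvas

    if spec.photon_scale is not NOISELESS:
        rng = spec.rng(0xF0)
        photons = rng.poisson(np.clip(data, 0, None)
                              * spec.photon_scale).astype(np.float32)
        if spec.read_noise_sd > 0:
            photons += rng.normal(0.0, spec.read_noise_sd,
                                  size=data.shape).astype(np.float32)
        data = photons

    return FrameStack(data, list(names), spec.pixel_size,
                      spec.frame_interval,
                      metadata={"seed": spec.seed,
                                "psf_sigma_nm": spec.psf_sigma})


# --------------------------------------------------------------------------
# tube rasterization

def _segment_distance_grid(spec: SceneSpec, lines: list[Polyline]) -> np.ndarray:
    """Exact distance (nm) from every pixel centre to the nearest polyline."""
    h, w = spec.field_size
    xs = px_to_nm(np.arange(w), spec.pixel_size)
    ys = px_to_nm(np.arange(h), spec.pixel_size)
    gx, gy = np.meshgrid(xs, ys)
    dist = np.full((h, w), np.inf)
    for line in lines:
        v = line.vertices
        for p, q in zip(v[:-1], v[1:]):
            d = q - p
            seg_len2 = float(d @ d)
            if seg_len2 == 0:
                px_, py_ = p
                dd = np.hypot(gx - px_, gy - py_)
            else:
                t = ((gx - p[0]) * d[0] + (gy - p[1]) * d[1]) / seg_len2
                t = np.clip(t, 0.0, 1.0)
                dd = np.hypot(gx - (p[0] + t * d[0]), gy - (p[1] + t * d[1]))
            np.minimum(dist, dd, out=dist)
    return dist


def rasterize_tubes(spec: SceneSpec, lines: list[Polyline],
                    diameter: float) -> np.ndarray:
    """Binary occupancy of tubes of the given diameter along the polylines:
    a pixel is occupied when its centre lies within diameter/2 of a line."""
    return _segment_distance_grid(spec, lines) <= diameter / 2.0


def _check_layout_in_field(spec: SceneSpec, lines: list[Polyline],
                           radius: float) -> None:
    hn, wn = spec.field_nm
    for line in lines:
        v = line.vertices
        if (np.min(v[:, 0]) - radius < 0 or np.max(v[:, 0]) + radius > wn
                or np.min(v[:, 1]) - radius < 0
                or np.max(v[:, 1]) + radius > hn):
            raise BoundsError(
                f"layout polyline {line.line_id!r} (with tube radius "
                f"{radius:.0f} nm) leaves the {hn:.0f} x {wn:.0f} nm field")


def generate_tubular_scene(spec: SceneSpec, tubule_diameter: float,
                           layout: Polyline | list[Polyline],
                           channel: str = "mito"
                           ) -> tuple[FrameStack, GroundTruth]:
    """A static scene of tubes of the stated diameter along the layout.

    The unblurred occupancy is recorded in the ground truth; the rendered
    channel is that occupancy convolved with the PSF (plus noise if the spec
    asks for it).
    """
    if not 40 <= tubule_diameter <= 1000:
        raise ValueError("tubule_diameter must be within [40, 1000] nm")
    lines = [layout] if isinstance(layout, Polyline) else list(layout)
    _check_layout_in_field(spec, lines, tubule_diameter / 2.0)
    mask = rasterize_tubes(spec, lines, tubule_diameter)
    stack = render(spec, masks={channel: mask})
    gt = GroundTruth(masks={channel: mask},
                     event_log=[{"type": "tubular_scene",
                                 "diameter_nm": tubule_diameter,
                                 "n_lines": len(lines)}])
    return stack, gt


# --------------------------------------------------------------------------
# spot pairs

def generate_spot_pair_scene(spec: SceneSpec, n_pairs: int, offset_sd: float,
                             margin: float | None = None,
                             channels: tuple[str, str] = ("spots_a", "spots_b")
                             ) -> tuple[FrameStack, GroundTruth]:
    """Two-channel paired point scene: channel-A spots at positions ``p_i``,
    channel-B spots at ``p_i + delta_i`` with isotropic Gaussian offsets of
    sd ``offset_sd`` (nm). A density warning is logged in the event log when
    the mean nearest-neighbour spacing of the A spots falls below
    ``4 * offset_sd`` (pair identity becomes ambiguous)."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if offset_sd < 0:
        raise ValueError("offset_sd must be >= 0")
    hn, wn = spec.field_nm
    if margin is None:
        margin = 5 * spec.psf_sigma + 4 * offset_sd + spec.pixel_size
    if 2 * margin >= min(hn, wn):
        raise BoundsError("field too small for the requested margin")
    rng = spec.rng(0xA0)
    a = np.column_stack([rng.uniform(margin, wn - margin, n_pairs),
                         rng.uniform(margin, hn - margin, n_pairs)])
    delta = rng.normal(0.0, offset_sd, (n_pairs, 2)) if offset_sd > 0 \
        else np.zeros((n_pairs, 2))
    b = a + delta

    event_log = [{"type": "spot_pair_scene", "n_pairs": n_pairs,
                  "offset_sd_nm": offset_sd}]
    if n_pairs >= 2 and offset_sd > 0:
        from scipy.spatial import cKDTree
        d, _ = cKDTree(a).query(a, k=2)
        if float(np.mean(d[:, 1])) < 4 * offset_sd:
            event_log.append({"type": "warning",
                              "reason": "pair_identity_ambiguous",
                              "mean_nn_spacing_nm": float(np.mean(d[:, 1]))})

    ca, cb = channels
    frames = np.arange(spec.n_frames)
    tracks = {}
    for name, pts in ((ca, a), (cb, b)):
        for i, p in enumerate(pts):
            tid = f"{name}_{i}"
            tracks[tid] = Track(tid, frames, np.tile(p, (spec.n_frames, 1)),
                                spec.frame_interval)
    stack = render(spec,
                   positions={ca: np.tile(a, (spec.n_frames, 1, 1)),
                              cb: np.tile(b, (spec.n_frames, 1, 1))},
                   channel_order=[ca, cb])
    gt = GroundTruth(object_tracks=tracks, event_log=event_log)
    return stack, gt


# --------------------------------------------------------------------------
# motion models

def fractional_gaussian_increments(n: int, hurst: float,
                                   rng: np.random.Generator,
                                   _cache: dict = {}) -> np.ndarray:
    """Unit-scale fractional Gaussian noise of length ``n`` (Cholesky of the
    exact fGn covariance; exact target MSD exponent 2H)."""
    if not 0 < hurst <= 1:
        raise ValueError("hurst must be in (0, 1]")
    if abs(hurst - 0.5) < 1e-12:
        return rng.standard_normal(n)
    if abs(hurst - 1.0) < 1e-12:
        return np.full(n, rng.standard_normal())
    key = (n, round(hurst, 12))
    if key not in _cache:
        k = np.arange(n)
        gamma = 0.5 * (np.abs(k + 1) ** (2 * hurst)
                       - 2 * np.abs(k) ** (2 * hurst)
                       + np.abs(k - 1) ** (2 * hurst))
        cov = gamma[np.abs(np.subtract.outer(k, k))]
        cov[np.diag_indices(n)] += 1e-10
        _cache[key] = cholesky(cov, lower=True)
    return _cache[key] @ rng.standard_normal(n)


def generate_track(spec: SceneSpec, model: str, D: float = 0.0,
                   v: float = 0.0, alpha_true: float = 1.0,
                   n_frames: int | None = None,
                   origin: tuple[float, float] = (0.0, 0.0),
                   direction: tuple[float, float] | None = None,
                   object_id: str = "track",
                   rng: np.random.Generator | None = None) -> Track:
    """Simulate one track under a named motion model.

    brownian: independent Gaussian increments with per-axis variance
    ``2 D dt``; ballistic: constant-velocity straight path at speed ``v``;
    anomalous: fractional-Brownian motion with Hurst ``alpha_true / 2`` so
    the 2D MSD follows ``4 D tau^alpha_true`` exactly.
    """
    if model not in ("brownian", "ballistic", "anomalous"):
        raise ValueError(f"unknown motion model {model!r}")
    if D < 0 or v < 0:
        raise ValueError("D and v must be >= 0")
    n = n_frames if n_frames is not None else spec.n_frames
    rng = rng if rng is not None else spec.rng(0xB0)
    dt = spec.frame_interval
    t = np.arange(n)
    origin = np.asarray(origin, dtype=float)

    if model == "ballistic":
        if direction is None:
            ang = rng.uniform(0, 2 * np.pi)
            u = np.array([np.cos(ang), np.sin(ang)])
        else:
            u = np.asarray(direction, dtype=float)
            u = u / np.linalg.norm(u)
        xy = origin + np.outer(t * dt * v, u)
        params = {"model": model, "v": v}
    elif model == "brownian":
        inc = rng.normal(0.0, np.sqrt(2 * D * dt), (n - 1, 2)) if n > 1 \
            else np.empty((0, 2))
        xy = origin + np.vstack([[0.0, 0.0], np.cumsum(inc, axis=0)])
        params = {"model": model, "D": D}
    else:
        if not 0 < alpha_true <= 2:
            raise ValueError("alpha_true must be in (0, 2]")
        hurst = alpha_true / 2.0
        scale = np.sqrt(2 * D) * dt ** (alpha_true / 2.0)
        cols = []
        for _ in range(2):
            inc = fractional_gaussian_increments(n - 1, hurst, rng) if n > 1 \
                else np.empty(0)
            cols.append(np.concatenate([[0.0], np.cumsum(inc)]) * scale)
        xy = origin + np.column_stack(cols)
        params = {"model": model, "D": D, "alpha_true": alpha_true}

    track = Track(object_id, t, xy, dt)
    track.motion_params = params
    return track


# --------------------------------------------------------------------------
# scripted MDT events

def generate_mdt_event(spec: SceneSpec, tip_speed: float, coupling: str,
                       *, onset_frame: int = 0,
                       tubule_diameter: float = 160.0,
                       body_diameter: float = 400.0,
                       coupled_gap: float = 0.0,
                       lag_factor: float = 0.5,
                       burst: tuple[int, int] = (10, 20),
                       burst_factor: float = 1.5,
                       stop_gap: float | None = None,
                       speed_modulation: float = 0.0,
                       modulation_period_s: float = 20.0,
                       render_images: bool = True
                       ) -> tuple[FrameStack | None, GroundTruth]:
    """A scripted tubule-extension (MDT) event with a nucleoid.

    A tubule extends from a mitochondrial body at ``tip_speed`` (nm/s) along
    +x, optionally with a deterministic sinusoidal speed modulation. The
    nucleoid is, per ``coupling``:

    - ``coupled``: locked ``coupled_gap`` nm behind the tip;
    - ``unsynchronized``: moves at ``lag_factor * tip speed`` before the
      ``burst`` frame window, ``burst_factor *`` tip speed inside it, and
      tip speed after, never passing the tip, and stopping ``stop_gap`` nm
      behind the final tip position when ``stop_gap`` is given;
    - ``retained``: stationary at the initiation site for the whole window.

    The event log records onset frame, mode, and script parameters, and a
    warning when the window is shorter than the 2-min observation needed for
    a transported/retained call downstream.
    """
    if tip_speed <= 0:
        raise ValueError("tip_speed must be > 0")
    if coupling not in ("coupled", "unsynchronized", "retained"):
        raise ValueError(f"unknown coupling mode {coupling!r}")
    hn, wn = spec.field_nm
    dt = spec.frame_interval
    n = spec.n_frames
    body_x = max(1500.0, body_diameter)
    init = np.array([body_x, hn / 2.0])

    # integrate tip extension (deterministic script)
    ext = np.zeros(n)
    for t in range(1, n):
        if t <= onset_frame:
            continue
        tau = (t - 1 - onset_frame) * dt
        speed = tip_speed * (1.0 + speed_modulation
                             * np.sin(2 * np.pi * tau / modulation_period_s))
        ext[t] = ext[t - 1] + speed * dt
    tip = init + np.column_stack([ext, np.zeros(n)])
    if tip[:, 0].max() + tubule_diameter / 2 > wn - spec.pixel_size:
        raise BoundsError("tubule tip leaves the field; enlarge field_size "
                          "or lower tip_speed / n_frames")

    # nucleoid script
    nuc_ext = np.zeros(n)
    if coupling == "coupled":
        nuc_ext = np.maximum(ext - coupled_gap, 0.0)
    elif coupling == "unsynchronized":
        for t in range(1, n):
            if t <= onset_frame:
                continue
            tau_frames = t - 1
            tip_inst = (ext[t] - ext[t - 1]) / dt
            if burst[0] <= tau_frames < burst[1]:
                f = burst_factor
            elif tau_frames < burst[0]:
                f = lag_factor
            else:
                f = 1.0
            nuc_ext[t] = min(nuc_ext[t - 1] + f * tip_inst * dt, ext[t])
        if stop_gap is not None:
            nuc_ext = np.minimum(nuc_ext, max(ext[-1] - stop_gap, 0.0))
    nucleoid = init + np.column_stack([nuc_ext, np.zeros(n)])

    frames = np.arange(n)
    tip_track = Track("tip", frames, tip, dt)
    nuc_track = Track("nucleoid", frames, nucleoid, dt)

    event = {"type": "mdt_event", "onset_frame": onset_frame,
             "mode": coupling, "tip_speed_nm_s": tip_speed,
             "initiation_site_nm": [float(init[0]), float(init[1])],
             "tubule_diameter_nm": tubule_diameter,
             "burst_frames": list(burst), "burst_factor": burst_factor,
             "lag_factor": lag_factor, "coupled_gap_nm": coupled_gap,
             "stop_gap_nm": stop_gap,
             "speed_modulation": speed_modulation}
    event_log = [event]
    if (n - 1) * dt < TRANSPORT_WINDOW_S:
        warnings.warn("event window shorter than the 2-min observation "
                      "needed for transported/retained classification",
                      stacklevel=2)
        event_log.append({"type": "warning", "reason": "window_lt_2min",
                          "window_s": (n - 1) * dt})

    gt = GroundTruth(object_tracks={"tip": tip_track,
                                    "nucleoid": nuc_track},
                     event_log=event_log,
                     motion_params={"tip": {"model": "scripted",
                                            "v": tip_speed},
                                    "nucleoid": {"model": "scripted",
                                                 "coupling": coupling}})
    stack = None
    if render_images:
        body_line = Polyline(np.array([[body_x, hn * 0.25],
                                       [body_x, hn * 0.75]]),
                             sampling_step=spec.pixel_size, line_id="body")
        masks = np.zeros((n, *spec.field_size), dtype=bool)
        body_mask = rasterize_tubes(spec, [body_line], body_diameter)
        for t in range(n):
            masks[t] = body_mask
            if ext[t] > 0:
                tub = Polyline(np.array([init, tip[t]]),
                               sampling_step=spec.pixel_size, line_id="tub")
                masks[t] |= rasterize_tubes(spec, [tub], tubule_diameter)
        gt.masks["mito"] = masks
        stack = render(spec, positions={"nucleoid": nucleoid[:, None, :]},
                       masks={"mito": masks},
                       channel_order=["mito", "nucleoid"])
    return stack, gt
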