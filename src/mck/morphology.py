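"""Tubule diameters, transport-event classification, and nucleoid
distribution statistics.

Apparent tubule diameters are measured as the FWHM of a Gaussian fitted to
an intensity cross-section and corrected for the microscope PSF in
quadrature (``d = sqrt(fwhm^2 - psf_fwhm^2)``). Tubules at or below 200 nm
corrected diameter are classified thin (the nanotunnel size range), above
200 nm thick. Scripted or tracked tubule-extension events are scored
transported/retained from the nucleoid's along-tubule displacement over a
>= 2 min window, with a tip-located call from the final nucleoid-to-tip
distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from .constants import (ENLARGED_CUTOFF_NM, FWHM_PER_SIGMA, PROXIMITY_RADIUS_NM,
                        THIN_THICK_BOUNDARY_NM, TIP_TOLERANCE_NM,
                        TRANSPORT_WINDOW_S, TRAVEL_MIN_NM)
from .exceptions import UnscorableEventError
from .geometry import Polyline
from .linescan import sample_profile
from .tracking import Track


@dataclass
class DiameterMeasurement:
    """One cross-section diameter measurement."""

    position: tuple[float, float]         # (x, y) nm of the fitted peak
    fwhm: float                           # apparent FWHM, nm
    corrected_diameter: float             # PSF-corrected, nm
    psf_fwhm: float
    fit_quality: float                    # R^2 of the Gaussian fit
    valid: bool = True


def _gaussian_with_offset(x, base, amp, mu, sigma):
    return base + amp * np.exp(-((x - mu) ** 2) / (2 * sigma ** 2))


def tubule_diameter(frame: np.ndarray, cross_section: Polyline,
                    psf_fwhm: float, pixel_size: float,
                    quality_floor: float = 0.8) -> DiameterMeasurement:
    """Fit a Gaussian to a cross-section profile and report the
    PSF-corrected diameter ``sqrt(max(0, fwhm^2 - psf_fwhm^2))``.

    The cross-section polyline should run roughly perpendicular to the
    tubule axis and reach background on both sides. Fit failure, a flat
    profile, or fit quality below ``quality_floor`` flags the measurement
    invalid rather than raising.
    """
    arc = cross_section.arc_positions()
    profile = sample_profile(frame, cross_section, pixel_size)
    invalid = DiameterMeasurement((np.nan, np.nan), np.nan, np.nan,
                                  psf_fwhm, 0.0, valid=False)
    if np.ptp(profile) == 0 or len(arc) < 5:
        return invalid
    base0 = float(profile.min())
    amp0 = float(profile.max() - profile.min())
    mu0 = float(arc[np.argmax(profile)])
    sigma0 = max(cross_section.sampling_step, psf_fwhm / FWHM_PER_SIGMA
                 if psf_fwhm > 0 else cross_section.sampling_step)
    try:
        popt, _ = curve_fit(
            _gaussian_with_offset, arc, profile,
            p0=[base0, amp0, mu0, sigma0],
            bounds=([-np.inf, 0.0, arc[0], 1e-3],
                    [np.inf, np.inf, arc[-1], arc[-1] - arc[0]]),
            maxfev=5000)
    except (RuntimeError, ValueError):
        return invalid
    base, amp, mu, sigma = popt
    pred = _gaussian_with_offset(arc, *popt)
    ss_tot = float(np.sum((profile - profile.mean()) ** 2))
    r2 = 1.0 - float(np.sum((profile - pred) ** 2)) / ss_tot \
        if ss_tot > 0 else 0.0
    if r2 < quality_floor or amp <= 0:
        invalid.fit_quality = r2
        return invalid
    fwhm = FWHM_PER_SIGMA * sigma
    corrected = float(np.sqrt(max(0.0, fwhm ** 2 - psf_fwhm ** 2)))
    pos = cross_section.points_at(np.array([mu]))[0]
    return DiameterMeasurement((float(pos[0]), float(pos[1])),
                               float(fwhm), corrected, psf_fwhm, r2)


def classify_tubule(diameter: float,
                    boundary: float = THIN_THICK_BOUNDARY_NM) -> str:
    """Thin/thick partition of tubule diameters: thin when the diameter is
    at or below the boundary (default 200 nm, the nanotunnel size range),
    thick above it."""
    if not diameter > 0:
        raise ValueError("diameter must be > 0")
    return "thin" if diameter <= boundary else "thick"


def proximity_fraction(sites: np.ndarray, targets: np.ndarray,
                       radius: float = PROXIMITY_RADIUS_NM) -> float:
    """Fraction of sites with at least one target within ``radius``
    (inclusive). Empty targets yield 0 with a warning."""
    sites = np.atleast_2d(np.asarray(sites, dtype=float))
    if sites.size == 0:
        raise ValueError("sites must be nonempty")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    targets = np.asarray(targets, dtype=float)
    if targets.size == 0:
        warnings.warn("targets empty; proximity fraction is 0", stacklevel=2)
        return 0.0
    targets = np.atleast_2d(targets)
    dist, _ = cKDTree(targets).query(sites)
    return float(np.mean(dist <= radius))


@dataclass
class MdtEvent:
    """One tubule-extension event with its tip track and candidate
    nucleoid tracks.

    ``transport_labels`` / ``tip_located`` are filled by
    :func:`classify_transport`; ``scorable`` is False when the observation
    window is shorter than the 2-min minimum."""

    onset_frame: int
    initiation_site: tuple[float, float]
    tip_track: Track
    nucleoid_tracks: list[Track]
    window: float                          # s
    transport_labels: dict[str, str] = field(default_factory=dict)
    tip_located: dict[str, bool] = field(default_factory=dict)
    scorable: bool | None = None

    @property
    def any_transported(self) -> bool:
        return any(v == "transported" for v in self.transport_labels.values())


def classify_transport(event: MdtEvent,
                       proximity_radius: float = PROXIMITY_RADIUS_NM,
                       travel_min: float = TRAVEL_MIN_NM,
                       tip_tolerance: float = TIP_TOLERANCE_NM) -> MdtEvent:
    """Label each nucleoid of an event transported or retained.

    A nucleoid (considered only if it starts within ``proximity_radius`` of
    the initiation site) is *transported* when its displacement from the
    initiation site projected on the tubule axis exceeds ``travel_min`` at
    any time in the window, else *retained*. A transported nucleoid is
    *tip located* when its final distance to the final tip position is at
    most ``tip_tolerance``. Events observed for less than 2 min are marked
    unscorable and labels are withheld.
    """
    if event.window < TRANSPORT_WINDOW_S:
        event.scorable = False
        event.transport_labels = {}
        event.tip_located = {}
        return event
    event.scorable = True
    init = np.asarray(event.initiation_site, dtype=float)
    tip_final = event.tip_track.xy[-1]
    axis = tip_final - init
    norm = np.linalg.norm(axis)
    axis = axis / norm if norm > 0 else np.array([1.0, 0.0])
    for trk in event.nucleoid_tracks:
        start_dist = np.linalg.norm(trk.xy[0] - init)
        if start_dist > proximity_radius:
            continue
        along = (trk.xy - init) @ axis
        label = "transported" if np.max(along) > travel_min else "retained"
        event.transport_labels[trk.object_id] = label
        if label == "transported":
            final_gap = float(np.linalg.norm(trk.xy[-1] - tip_final))
            event.tip_located[trk.object_id] = final_gap <= tip_tolerance
    return event


def transport_event_fraction(events: list[MdtEvent]) -> float:
    """Fraction of scorable events with at least one transported nucleoid."""
    scorable = [e for e in events if e.scorable]
    if not scorable:
        raise UnscorableEventError("no scorable events")
    return float(np.mean([e.any_transported for e in scorable]))


def nucleoid_density(points: np.ndarray, zone_mask: np.ndarray,
                     pixel_size: float) -> float:
    """Nucleoid count per um^2 of a zone mask.

    Points (nm) are assigned to the pixel containing them; the density is
    the in-zone count over the zone area in um^2.
    """
    zone_mask = np.asarray(zone_mask).astype(bool)
    n_pix = int(zone_mask.sum())
    if n_pix == 0:
        raise ValueError("zone_mask is empty")
    area_um2 = n_pix * pixel_size ** 2 * 1e-6
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        return 0.0
    points = np.atleast_2d(points)
    cols = np.floor(points[:, 0] / pixel_size).astype(int)
    rows = np.floor(points[:, 1] / pixel_size).astype(int)
    h, w = zone_mask.shape
    inside = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    count = int(np.sum(zone_mask[rows[inside], cols[inside]]))
    return count / area_um2


def flag_enlarged_nucleoids(measurements: list[DiameterMeasurement],
                            cutoff: float = ENLARGED_CUTOFF_NM
                            ) -> list[DiameterMeasurement]:
    """Subset of measurements with corrected diameter strictly above the
    cutoff (default 1 um), the enlarged-nucleoid criterion."""
    return [m for m in measurements
            if m.valid and m.corrected_diameter > cutoff]


def diameters_to_dataframe(measurements: list[DiameterMeasurement]
                           ) -> pd.DataFrame:
    return pd.DataFrame([{
        "x_nm": m.position[0], "y_nm": m.position[1], "fwhm_nm": m.fwhm,
        "corrected_diameter_nm": m.corrected_diameter,
        "psf_fwhm_nm": m.psf_fwhm, "fit_quality": m.fit_quality,
        "valid": m.valid,
        "class": (classify_tubule(m.corrected_diameter)
                  if m.valid and m.corrected_diameter > 0 else "")}
        for m in measurements])
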