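"""Numeric defaults shared across the pipeline.

Each constant that mirrors a fixed analysis parameter is defined exactly once
here and referenced by name everywhere else.
"""

#: Lateral shift increment of the linescan cross-correlation analysis (nm).
SHIFT_STEP_NM: float = 32.0

#: Default pixel size of simulated scenes (nm/pixel). Chosen equal to the
#: shift increment so one shift step is exactly one pixel in fixtures.
PIXEL_SIZE_NM: float = 32.0

#: Confidence level for the shift-curve colocalization threshold.
CONFIDENCE: float = 0.95

#: Gaussian PSF sigma of simulated scenes (nm); 42 nm sigma is ~97 nm FWHM,
#: the lateral resolution of GI-SIM live-cell imaging.
PSF_SIGMA_NM: float = 42.0

#: FWHM corresponding to PSF_SIGMA_NM (nm), used for diameter correction.
PSF_FWHM_NM: float = 97.0

#: Radius linking an MDT initiation site to nearby nucleoids (nm; 1 um).
PROXIMITY_RADIUS_NM: float = 1000.0

#: Minimum observation window for a transported/retained call (s; 2 min).
TRANSPORT_WINDOW_S: float = 120.0

#: Thin/thick tubule boundary diameter (nm); thin is <= boundary.
THIN_THICK_BOUNDARY_NM: float = 200.0

#: Nucleoid diameter above which a nucleoid counts as enlarged (nm; 1 um).
ENLARGED_CUTOFF_NM: float = 1000.0

#: Default minimum along-tubule displacement for a "transported" label (nm).
#: The source analysis scored transport visually; this is a documented knob.
TRAVEL_MIN_NM: float = 500.0

#: Default max distance between nucleoid and tubule tip for a "tip located"
#: label (nm); ~2.5 nucleoid diameters. Documented knob, see docs/methods.md.
TIP_TOLERANCE_NM: float = 250.0

#: Gaussian-to-FWHM conversion factor 2*sqrt(2 ln 2).
FWHM_PER_SIGMA: float = 2.3548200450309493
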