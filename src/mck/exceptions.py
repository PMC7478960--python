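"""Exception types used across the package."""


class MckError(Exception):
    """Base class for package errors."""


class BoundsError(MckError, ValueError):
    """A geometric object (polyline, layout, point) leaves the image field."""


class ThresholdUndefinedError(MckError):
    """The zero-shift confidence interval already includes 0; no
    colocalization distance threshold can be defined (distinct from a
    threshold of 0)."""


class EmptyMaskError(MckError, ValueError):
    """An operation requiring a nonempty binary mask received an empty one."""


class DegenerateProfileError(MckError, ValueError):
    """An intensity profile cannot support the requested fit (flat,
    non-unimodal, or zero MSD in the fit range)."""


class DegenerateTrackError(MckError, ValueError):
    """A track has zero variance where a correlation or fit needs spread."""


class UnscorableEventError(MckError, ValueError):
    """No scorable event is available for an event-level summary."""


class StageError(MckError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
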