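"""Exception hierarchy for the lnulm pipeline.

Every stage raises a typed error carrying a short machine-readable ``code``
so the CLI can map failures to per-stage exit codes.
"""


class LnulmError(Exception):
    """Base class for all pipeline errors."""

    code = "error"


class InvalidParameterError(LnulmError, ValueError):
    code = "invalid-parameter"


class OutOfBoundsError(LnulmError, ValueError):
    """Raised when track or localization coordinates leave the field of view.

    ``track_ids`` lists the offending tracks when known.
    """

    code = "out-of-bounds"

    def __init__(self, message, track_ids=None):
        super().__init__(message)
        self.track_ids = list(track_ids) if track_ids is not None else []


class DegenerateRegionError(LnulmError, ValueError):
    code = "degenerate-region"


class UnboundedProfileError(LnulmError, ValueError):
    code = "unbounded-profile"


class InvalidTrackError(LnulmError, ValueError):
    code = "invalid-track"


class InvalidRoiError(LnulmError, ValueError):
    code = "invalid-roi"


class ShapeMismatchError(LnulmError, ValueError):
    code = "shape-mismatch"


class NoSignalError(LnulmError, ValueError):
    code = "no-signal"


class HilumRequiredError(LnulmError, ValueError):
    code = "hilum-required"


class UndefinedCorrelationError(LnulmError, ValueError):
    code = "undefined-correlation"


class SampleSizeError(LnulmError, ValueError):
    code = "sample-size"


class DegenerateVarianceError(LnulmError, ValueError):
    code = "degenerate-variance"
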