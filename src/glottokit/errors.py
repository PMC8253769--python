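"""Exception hierarchy for the analysis pipeline.

Every stage raises a subclass of :class:`GlottokitError` so that the
pipeline driver can attach the stage name while re-raising.
"""


class GlottokitError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(GlottokitError, ValueError):
    """A configuration value is outside its valid range."""


class TriggerNotFoundError(GlottokitError):
    """No pulsed-to-quiescent transition found in the reference channel."""


class InsufficientPulsesError(GlottokitError):
    """Fewer than two camera frame pulses detected."""


class InvalidRoiError(GlottokitError, ValueError):
    """Region of interest is empty or outside the frame bounds."""


class TooFewCyclesError(GlottokitError):
    """Not enough oscillation cycles for the requested computation."""


class MidlineUndefinedError(GlottokitError):
    """The mask has no preferred axis (degenerate symmetry)."""


class UndefinedMeasureError(GlottokitError):
    """A parameter is undefined for the given input (e.g. silent signal)."""


class BundleIOError(GlottokitError, IOError):
    """A recording-bundle member is missing or corrupt."""
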