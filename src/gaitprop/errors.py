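"""Exception hierarchy for the gaitprop pipeline."""


class GaitPropError(Exception):
    """Base class for all gaitprop errors."""


class FormatError(GaitPropError):
    """A file does not match the expected schema or dialect."""


class UnsupportedFileError(GaitPropError):
    """A file is structurally valid but cannot be used (e.g. too few force plates)."""


class ParameterError(GaitPropError, ValueError):
    """An argument violates a precondition (bad sampling rate, mass <= 0, ...)."""


class DetectionError(GaitPropError):
    """Gait-event detection failed (degenerate trajectories, non-alternating events)."""
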