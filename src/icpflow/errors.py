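"""Exception hierarchy for the icpflow pipeline.

Every stage failure that excludes a window (rather than aborting the run)
raises a subclass of :class:`WindowExcluded`, so the pipeline driver can
catch one type and keep exact accounting of why each window was dropped.
"""


class IcpflowError(Exception):
    """Base class for all icpflow errors."""


class InvalidMorphologyError(IcpflowError, ValueError):
    """Pulse morphology parameters violate their invariants."""


class TooShortError(IcpflowError, ValueError):
    """Recording or window shorter than the minimum usable duration."""


class DegenerateSignalError(IcpflowError, ValueError):
    """Signal is flat, non-finite, or otherwise carries no usable power."""


class NoFundamentalError(IcpflowError, ValueError):
    """No cardiac fundamental found in the search band."""


class WindowExcluded(IcpflowError):
    """Base for per-window exclusions (window is dropped, run continues)."""


class InsufficientBeatsError(WindowExcluded):
    """Fewer than the minimum number of clean beats survived curation."""


class LandmarkFailureError(WindowExcluded):
    """No P1/P2 landmark candidates found on the mean pulse."""


class NotAcceptedError(IcpflowError, ValueError):
    """Feature extraction requested for a window the quality gate rejected."""


class FormatError(IcpflowError, ValueError):
    """Malformed input file (missing columns, irregular sampling, ...)."""
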