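"""Exception types shared across the package."""


class KCFBSError(Exception):
    """Base class for package errors."""


class FormatError(KCFBSError, ValueError):
    """A file or stream could not be decoded into the expected format."""


class TrackingError(KCFBSError, ValueError):
    """Tracking could not proceed (e.g. an initial box outside the frame)."""


class GeometryError(KCFBSError, ValueError):
    """A camera-geometry computation is degenerate or out of range."""


class NumericError(KCFBSError, ArithmeticError):
    """A numeric invariant was violated (non-finite response, etc.)."""
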