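"""Exception hierarchy for citrusyield.

All package errors derive from :class:`CitrusYieldError` so callers can catch
one type; most also derive from the matching builtin (``ValueError``/``KeyError``)
so generic handling keeps working.
"""


class CitrusYieldError(Exception):
    """Base class for all citrusyield errors."""


class InvalidParameterError(CitrusYieldError, ValueError):
    """A numeric parameter violates its domain (e.g. non-positive altitude)."""


class FormatError(CitrusYieldError, ValueError):
    """An image does not meet the expected 8-bit, 3-channel layout."""


class ColorSpaceError(FormatError):
    """An operation received an image in the wrong color space."""


class DegenerateHistogramError(CitrusYieldError, ValueError):
    """Automatic thresholding was asked for on a constant-valued map."""


class InsufficientDataError(CitrusYieldError, ValueError):
    """A statistic was requested on a sample too small to support it."""


class AlignmentError(CitrusYieldError, ValueError):
    """Two tables that must share (altitude, label) keys do not."""


class DuplicateKeyError(CitrusYieldError, ValueError):
    """A (label, altitude) key appears more than once in an input table."""


class PackingError(CitrusYieldError, RuntimeError):
    """Scene generation could not place non-overlapping crowns in the field."""


class ConfigError(CitrusYieldError, ValueError):
    """A configuration file contains unknown keys or invalid values."""
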