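"""Exception types shared across the pipeline."""


class CypritrackError(Exception):
    """Base class for all package errors."""


class InvalidInputError(CypritrackError, ValueError):
    """Raised on empty sequences, shape mismatches or malformed tables."""


class DegenerateGeometryError(CypritrackError, ValueError):
    """Raised when an ellipse cannot be fitted (too few or collinear pixels)."""
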