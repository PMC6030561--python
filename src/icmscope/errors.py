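"""Exception hierarchy for icmscope.

All errors raised by the library derive from :class:`IcmScopeError` so that
callers (and the CLI) can distinguish configuration problems from data
problems with a single except clause.
"""


class IcmScopeError(Exception):
    """Base class for all icmscope errors."""


class ConfigError(IcmScopeError):
    """Invalid configuration or parameter values."""


class DataError(IcmScopeError):
    """Input data violates a precondition."""


class CalibrationError(DataError):
    """Pixel size missing from both image metadata and override."""


class FormatError(DataError):
    """Image layout does not match the declared channel configuration."""


class RegistrationRequiredError(DataError):
    """Measurement requested on a field whose channels were never aligned."""


class DegenerateGeometryError(DataError):
    """Geometry too degenerate to analyse (collinear landmarks, point skeleton)."""


class PlacementError(DataError):
    """Synthetic scene could not place all requested cells without overlap."""

    def __init__(self, placed: int, requested: int):
        self.placed = placed
        self.requested = requested
        super().__init__(
            f"placed only {placed} of {requested} cells without overlap; "
            "enlarge the field or reduce n_cells"
        )


class AllForegroundError(DataError):
    """No extracellular pixels left to estimate the background from."""


class InsufficientDataError(DataError):
    """Too few observations for the requested statistic."""


class PairingError(DataError):
    """Keys of two paired data sets do not match."""

    def __init__(self, unmatched):
        self.unmatched = sorted(unmatched)
        super().__init__(f"unmatched pairing keys: {self.unmatched}")


class NewickParseError(DataError):
    """Malformed Newick text."""
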