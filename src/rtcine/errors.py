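"""Exception hierarchy for the toolkit.

Config errors (bad parameters, invalid run configuration) map to CLI exit
code 2, data errors (unreadable/inconsistent series, degenerate inputs) to
exit code 3.
"""


class RtcineError(Exception):
    """Base class for all toolkit errors."""


class ConfigError(RtcineError):
    """Invalid configuration or parameter values."""


class DataError(RtcineError):
    """Invalid, inconsistent or unreadable data."""


class MissingVencError(DataError):
    """A flow series is requested but no velocity-encoding limit is available."""


class InconsistentGeometryError(DataError):
    """Slice spacing/positions in a series are not mutually consistent."""


class UnreadableSeriesError(DataError):
    """Files on disk could not be parsed as an image series."""


class EmptySeriesError(DataError):
    """A series or mask stack contains no usable data."""


class NoRespiratoryEventsError(DataError):
    """One or more slices have no respiratory events of the requested phase."""

    def __init__(self, slices):
        self.slices = list(slices)
        super().__init__(
            f"no respiratory events of the requested phase for slices {self.slices}"
        )


class ZeroVarianceError(DataError):
    """A statistic is undefined because the data have no variance."""
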