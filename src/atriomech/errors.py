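"""Exception hierarchy for atriomech.

Errors are split into parameter problems (bad arguments), data problems
(malformed or physically impossible recordings), and numerical problems
(calibration or integration failures), so that callers and the CLI can
distinguish usage errors from runtime failures.
"""


class AtriomechError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(AtriomechError, ValueError):
    """An argument or parameter value violates its contract."""


class DataError(AtriomechError, ValueError):
    """A recording or table is malformed or physically impossible."""


class ProtocolError(AtriomechError, ValueError):
    """A protocol specification or protocol-level precondition is violated."""


class ResolutionError(AtriomechError, RuntimeError):
    """The time grid is too coarse for a stable/accurate integration."""


class CalibrationError(AtriomechError, RuntimeError):
    """Root finding for parameter calibration failed to converge."""

    def __init__(self, message, unmet_targets=()):
        super().__init__(message)
        self.unmet_targets = tuple(unmet_targets)


class DialectError(DataError):
    """Base class for trace-file format violations."""


class MissingColumnError(DialectError):
    pass


class NonUniformTimeError(DialectError):
    pass


class MetadataMismatchError(DialectError):
    pass


class TraceParseError(DialectError):
    pass


class DegenerateTwitchError(AtriomechError, ValueError):
    """Raised when an operation requires a non-degenerate twitch."""
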