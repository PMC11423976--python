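"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: usage errors are handled by click (2),
:class:`ValidationError` family maps to 3, :class:`CorruptionError` to 4.
"""


class SynaptomeError(Exception):
    """Base class for all package errors."""


class ValidationError(SynaptomeError, ValueError):
    """A domain object violates one of its invariants."""


class ConfigurationError(SynaptomeError, ValueError):
    """A configuration is internally inconsistent or infeasible."""


class CapabilityError(SynaptomeError):
    """An analysis was requested that the model level cannot support
    (e.g. synaptic densities from a topology-only record set)."""


class EncodingError(SynaptomeError, ValueError):
    """A value cannot be represented in the requested byte widths."""


class RangeError(SynaptomeError, ValueError):
    """A coordinate lies outside the encoded volume extent."""


class FormatError(SynaptomeError):
    """A byte stream is not a recognisable synaptome file."""


class CorruptionError(FormatError):
    """A byte stream is recognisable but truncated or inconsistent.

    Parameters
    ----------
    message : str
    byte_offset : int
        Offset into the stream at which the problem was detected.
    record_index : int, optional
        Index of the record being read when the stream ended.
    """

    def __init__(self, message: str, byte_offset: int, record_index: int | None = None):
        self.byte_offset = byte_offset
        self.record_index = record_index
        detail = f" (byte offset {byte_offset}"
        if record_index is not None:
            detail += f", record {record_index}"
        detail += ")"
        super().__init__(message + detail)


class SizeError(SynaptomeError):
    """A graph is too large for exhaustive enumeration."""
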