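"""Shared exception types."""


class DtibenchError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DtibenchError):
    """A file does not conform to the expected layout."""


class ParseError(DtibenchError):
    """A value inside an otherwise well-formed file cannot be interpreted."""


class ConsistencyError(DtibenchError):
    """Two pieces of input contradict each other (duplicate ids, dangling references)."""


class InputError(DtibenchError):
    """An argument violates a precondition."""


class DimensionError(DtibenchError):
    """Vector or matrix shapes do not line up."""


class InfeasibleSplitError(DtibenchError):
    """No train/test assignment can satisfy the requested constraints."""

    def __init__(self, message: str, achievable_fractions=None):
        super().__init__(message)
        self.achievable_fractions = achievable_fractions or []
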