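"""Exception types shared across the package."""


class PodometryError(Exception):
    """Base class for all package errors."""


class FormatError(PodometryError, ValueError):
    """A table or file does not follow the expected schema."""


class ValidationError(PodometryError, ValueError):
    """A record violates a domain invariant."""


class DegenerateStatisticError(PodometryError, ValueError):
    """A statistic is undefined for the given data (e.g. zero margin)."""


class UnclassifiableError(PodometryError, ValueError):
    """A patient cannot be assigned a response label from the available data."""
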