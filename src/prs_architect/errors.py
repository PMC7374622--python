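"""Exception hierarchy shared across the package."""


class PrsArchitectError(Exception):
    """Base class for all package errors."""


class FormatError(PrsArchitectError):
    """A file could not be parsed in the expected format."""


class ValidationError(PrsArchitectError, ValueError):
    """An input violated a documented invariant."""


class GenerationError(PrsArchitectError):
    """A synthetic-data request is infeasible."""
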