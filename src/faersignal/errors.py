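"""Exception hierarchy shared across the package."""


class FaersSignalError(Exception):
    """Base class for all package errors."""


class SchemaError(FaersSignalError, ValueError):
    """A flat file's header does not match any known FAERS table layout."""


class EmptyInputError(FaersSignalError, ValueError):
    """An input file or record set is empty where data is required."""


class ConfigurationError(FaersSignalError, ValueError):
    """An option, dictionary or config field is invalid."""


class ValidationError(FaersSignalError, ValueError):
    """A field value violates a domain invariant (e.g. negative age)."""


class ReconstructionError(FaersSignalError, ValueError):
    """A contingency table cannot be recovered from published statistics."""


class FittingError(FaersSignalError, RuntimeError):
    """Numerical model fitting failed or the data are degenerate."""
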