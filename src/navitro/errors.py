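"""Exception hierarchy shared across the toolkit."""


class NavitroError(Exception):
    """Base class for all toolkit errors."""


class InvalidValueError(NavitroError, ValueError):
    """A numeric argument is outside its admissible domain (non-finite, wrong sign, ...)."""


class DegenerateInputError(NavitroError, ValueError):
    """Input is structurally valid but statistically unusable (n < 2, zero mean, no controls)."""


class InsufficientDataError(NavitroError, ValueError):
    """Too few points to fit the requested model."""


class SchemaError(NavitroError, ValueError):
    """A file or config violates the declared dialect/schema."""

    def __init__(self, message: str, location: str | None = None):
        super().__init__(message if location is None else f"{location}: {message}")
        self.location = location


class NotFoundError(NavitroError, KeyError):
    """A requested endpoint/compound/medium does not exist in the dataset."""


class ConflictError(NavitroError, ValueError):
    """Duplicate keys where uniqueness is required."""


class BlockedStateError(NavitroError, RuntimeError):
    """An operation requires a pending workflow step (e.g. third rater) to complete first."""


class NoEC50Error(NavitroError, ValueError):
    """The fitted curve has no usable EC50 (flat or censored)."""
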