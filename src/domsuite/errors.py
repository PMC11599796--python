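"""Exception hierarchy shared across the package."""


class DomsuiteError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DomsuiteError):
    """A file does not conform to the documented tabular dialect."""


class ValidationError(DomsuiteError):
    """Input violates a documented precondition or invariant."""


class UnmeasurableError(DomsuiteError):
    """A quantity is undefined for the given data (e.g., a group with
    zero decisive interactions has no David's score or DCI)."""
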