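"""Exception hierarchy shared across the package."""


class EwsfdError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EwsfdError, ValueError):
    """Input violates a documented precondition or invariant."""


class UnsupportedFormatError(EwsfdError, ValueError):
    """File exists but is not a supported lossless integer image stack."""


class StackIOError(EwsfdError, OSError):
    """Stack file could not be read or written."""
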