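"""Exception types shared across the package."""


class CnvmirError(Exception):
    """Base class for package errors."""


class FormatError(CnvmirError):
    """An input file does not match the expected layout."""


class ValidationError(CnvmirError):
    """Input values violate a documented invariant."""


class StateError(CnvmirError):
    """An operation was called before its prerequisites were satisfied."""
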