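"""Exception types shared across the package."""


class HeloError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(HeloError, ValueError):
    """An input violated a structural or numeric invariant."""
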