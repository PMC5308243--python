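"""Exception hierarchy used across the package."""


class IntronsigError(Exception):
    """Base class for all package errors."""


class ValidationError(IntronsigError, ValueError):
    """An input object violates a structural invariant."""


class FormatError(IntronsigError, ValueError):
    """A file could not be parsed under its declared format."""


class InconsistencyError(IntronsigError, ValueError):
    """Two inputs that must agree (e.g. annotation vs CDS length) do not."""
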