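"""Exception hierarchy shared across the package."""


class SeqrecodeError(Exception):
    """Base class for all package-specific errors."""


class LengthMismatchError(SeqrecodeError):
    """Two sequences of unequal length were passed to a positional distance."""


class DegenerateInputError(SeqrecodeError):
    """An input is constant / zero-variance where a correlation is required."""


class EncodingMismatchError(SeqrecodeError):
    """A chunk assignment does not reproduce the sequence it claims to encode."""


class ConstraintError(SeqrecodeError):
    """A design-constraint check or search failed."""


class ConfigError(SeqrecodeError):
    """Invalid run configuration."""
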