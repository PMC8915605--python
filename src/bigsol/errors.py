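"""Exception types shared across bigsol modules."""


class BigsolError(Exception):
    """Base class for all bigsol errors."""


class SchemaError(BigsolError):
    """A required column is missing or the column mapping is inconsistent."""


class ParseError(BigsolError):
    """A cell could not be parsed; message names the row and column."""


class ValidationError(BigsolError):
    """A record violates a domain invariant."""


class SingularDesignError(BigsolError):
    """The design matrix is rank-deficient; message names dependent columns."""


class ConfigurationError(BigsolError):
    """A model preset or configuration value is missing or invalid."""


class NoCrossoverError(BigsolError):
    """Two solubility lines are parallel and never intersect."""
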