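"""Exception hierarchy shared across the package."""


class AgealignError(Exception):
    """Base class for all package-specific errors."""


class ParseError(AgealignError):
    """A file could not be parsed (malformed line, wrong column set...)."""


class ValidationError(AgealignError, ValueError):
    """Parsed content violates an invariant (bad score, unknown label...)."""


class DomainError(AgealignError, ValueError):
    """Numeric arguments outside the mathematical domain of an operation."""
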