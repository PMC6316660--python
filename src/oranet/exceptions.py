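"""Exception hierarchy for oranet."""


class OranetError(Exception):
    """Base class for all oranet errors."""


class ValidationError(OranetError):
    """Input data violates a documented precondition or invariant."""


class DomainError(OranetError, ValueError):
    """A statistical quantity was requested outside its mathematical domain."""
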