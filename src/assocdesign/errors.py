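"""Exception hierarchy shared across the toolkit.

Exit-code convention for the CLI: validation problems map to exit code 2,
numerical failures to exit code 3.
"""


class AssocDesignError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(AssocDesignError, ValueError):
    """Malformed or inconsistent input (frequencies, tables, configs)."""


class DomainError(AssocDesignError, ValueError):
    """Mathematically valid input outside an operation's domain
    (e.g. a monomorphic locus passed to an LD statistic)."""


class NumericalError(AssocDesignError, ArithmeticError):
    """A numerical routine failed to reach its requested tolerance."""
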