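"""Exception hierarchy shared across the package.

``InputError`` maps to CLI exit code 2 (bad or inconsistent input),
``NumericalError`` to exit code 3 (fit or inversion failure).
"""


class EpistabError(Exception):
    """Base class for all package-specific errors."""


class InputError(EpistabError, ValueError):
    """Invalid, inconsistent or missing input data."""


class NumericalError(EpistabError, RuntimeError):
    """A numerical procedure failed (non-identifiable fit, no solution)."""
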