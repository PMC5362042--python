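"""Exception hierarchy.

``InputError`` (exit code 1 from the CLI) covers malformed or inconsistent
inputs and configuration; ``NumericalError`` (exit code 2) covers solver
failures on well-formed inputs.
"""


class MFCParcError(Exception):
    """Base class for all package errors."""


class InputError(MFCParcError, ValueError):
    """Malformed, inconsistent or out-of-range input."""


class ConfigError(InputError):
    """A configuration object violates one of its invariants."""


class DegenerateInputError(InputError):
    """Structurally valid input that is statistically unusable
    (e.g. a zero-variance vertex)."""


class NumericalError(MFCParcError, RuntimeError):
    """A numerical routine (eigensolver, optimiser) failed."""
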