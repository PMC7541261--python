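"""Exception hierarchy.

``InputError`` maps to CLI exit code 2, ``InvariantError`` to exit code 3.
"""


class QuadrecError(Exception):
    """Base class for all package errors."""


class InputError(QuadrecError):
    """Malformed or missing input data (bad PED line, unknown sample, ...)."""


class InvariantError(QuadrecError):
    """An internal invariant was violated (inconsistent pedigree, bad counts)."""


class ClassificationError(QuadrecError):
    """A variant could not be assigned a functional category."""
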