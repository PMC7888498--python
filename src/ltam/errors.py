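"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes (usage errors are handled by click
itself): :class:`ValidationError` -> 3, :class:`NumericalError` -> 4.
"""


class LtamError(Exception):
    """Base class for all package errors."""


class FormatError(LtamError):
    """A file could not be parsed (missing columns, bad rows)."""


class ValidationError(LtamError):
    """Input data violates a model or pedigree invariant."""


class PedigreeCycleError(ValidationError):
    """An animal is its own ancestor; carries the offending cycle."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__(
            "pedigree cycle detected: " + " -> ".join(map(str, self.cycle))
        )


class NumericalError(LtamError):
    """A covariance matrix lost positive definiteness or a conditional
    variance became non-positive during sampling."""
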