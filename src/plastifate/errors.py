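"""Package-specific exceptions and warnings."""


class PlastifateError(Exception):
    """Base class for domain errors raised by plastifate."""


class CompleteDegradationError(PlastifateError):
    """The observed mass loss is total, so the surface-recession velocity is
    only bounded from below and cannot be computed."""


class InfiniteResidenceError(PlastifateError):
    """The fate model has a compartment (or loop of compartments) with no loss
    pathway, so the steady-state residence time is infinite."""


class CanonicalLookupError(KeyError, PlastifateError):
    """A characterization-factor query did not match any canonical record."""


class NegativeSignalWarning(UserWarning):
    """A blank-corrected CO2 signal fell below zero and was clamped to zero."""
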