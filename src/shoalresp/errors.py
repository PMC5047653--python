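"""Exception types shared across the pipeline."""


class ShoalrespError(Exception):
    """Base class for all package-specific errors."""


class TraceFormatError(ShoalrespError):
    """A trace file does not conform to the expected CSV layout."""


class TraceValidationError(ShoalrespError):
    """A parsed trace violates a structural invariant (e.g. non-monotone time)."""


class PhysicallyImpossibleError(ShoalrespError):
    """A simulation configuration implies oxygen below zero or a fish larger than its chamber."""


class InsufficientDataError(ShoalrespError):
    """Too few usable observations for the requested statistic."""


class SingularFitError(ShoalrespError):
    """A regression cannot be fitted (e.g. all timestamps identical)."""


class InvalidIntervalError(ShoalrespError):
    """A time interval with non-positive length was supplied."""
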