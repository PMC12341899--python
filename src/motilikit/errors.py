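"""Exception hierarchy shared across the toolkit."""


class MotilikitError(Exception):
    """Base class for all toolkit errors."""


class FormatError(MotilikitError):
    """A track file does not conform to the declared dialect."""


class ValidationError(MotilikitError):
    """Input violates a structural invariant (e.g. frame gaps)."""


class DegenerateInputError(MotilikitError):
    """Input is too short or constant for the requested operation."""


class DegenerateCurveError(MotilikitError):
    """A fluctuation/MSD curve is identically zero and cannot be fit."""


class ConfigError(MotilikitError):
    """A configuration value is outside its admissible domain."""


class GenerationError(MotilikitError):
    """A stochastic generator could not produce a valid realization."""


class TooShortError(DegenerateInputError):
    """Series shorter than the minimum length required by the estimator."""


class ToleranceUndefinedError(MotilikitError):
    """SD-fractional ApEn tolerance requested on a zero-variance series."""
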