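"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A physical or geometric parameter is outside its valid range."""


class InsufficientDataError(ValueError):
    """Not enough observations to run the requested estimator."""


class TooShortTrackError(InsufficientDataError):
    """Trajectory has too few points for the requested analysis."""


class DegenerateGeometryError(ValueError):
    """Point configuration does not admit the requested geometric construction."""


class FitFailureError(RuntimeError):
    """A nonlinear fit did not converge or produced an unusable result."""


class DivisionGuardError(ZeroDivisionError):
    """A normalization denominator reached zero (e.g. reference trace)."""
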