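"""Exception and warning types used across hemogam."""


class HemogamError(Exception):
    """Base class for hemogam errors."""


class DegenerateCovariateError(HemogamError):
    """Covariate has too few distinct values to support a spline basis."""


class InvalidKnotsError(HemogamError):
    """Knot sequence is not strictly increasing or is too short."""


class IdentifiabilityError(HemogamError):
    """Model terms are confounded (rank-deficient unpenalized span)."""


class TooFewObservationsError(HemogamError):
    """Not enough observations to fit the requested model."""


class WrongModelError(HemogamError):
    """A downstream statistic was requested from an incompatible fit."""


class MissingCovariateError(HemogamError):
    """A covariate required by the design is absent from the data."""


class NoConfidentEstimateError(HemogamError):
    """Spectral peak not distinguishable from background power."""


class HemogamWarning(UserWarning):
    """Base class for hemogam warnings."""
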