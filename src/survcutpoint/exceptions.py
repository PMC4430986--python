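"""Typed errors raised by the estimation pipeline.

The split matters for the CLI contract: input-validation problems exit
with code 2, estimation failures (degenerate data, unstable bootstrap)
with code 3.
"""


class SurvCutpointError(Exception):
    """Base class for every error raised by this package."""


class InvalidInputError(SurvCutpointError, ValueError):
    """Malformed or out-of-contract input (bad CSV row, tau <= 0, ...)."""


class EstimationError(SurvCutpointError):
    """The data were well-formed but the requested estimate does not exist."""


class EmptyStratumError(EstimationError):
    """A Kaplan-Meier stratum contains no subjects."""


class DegenerateCutpointError(EstimationError):
    """A candidate cut-point leaves one marker group empty."""


class NoEventsBeforeHorizonError(EstimationError):
    """No observed events by the horizon: sensitivity is undefined."""


class NoSurvivorsAtHorizonError(EstimationError):
    """Estimated survival at the horizon is zero in both marker groups."""


class ConstantMarkerError(EstimationError):
    """Fewer than two distinct marker values: no cut-point exists."""


class NoAdmissibleCutpointError(EstimationError):
    """Every candidate cut-point was degenerate or undefined."""


class BootstrapUnstableError(EstimationError):
    """More than half of the bootstrap replicates failed to estimate."""


class LogitBoundaryError(EstimationError):
    """FPF or TPF is exactly 0 or 1; the logit-scale ellipse is undefined."""
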