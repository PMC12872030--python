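"""Error types raised by crtbayes.

All errors derive from :class:`CrtBayesError` so callers can catch the
package's failures with a single except clause.
"""


class CrtBayesError(Exception):
    """Base class for all crtbayes errors."""


class InvalidDesignError(CrtBayesError, ValueError):
    """A trial design violates its constraints (non-finite or out-of-range
    parameters, ICC outside [0, 1), non-positive counts)."""


class InvalidDataError(CrtBayesError, ValueError):
    """Participant-level data violate the cluster-randomization structure."""


class DegenerateDesignError(CrtBayesError, ValueError):
    """Too few clusters per arm to estimate variance components."""


class EstimationFailureError(CrtBayesError, RuntimeError):
    """The mixed-model fit did not converge or produced no finite standard
    error. Carries ``replicate`` when raised inside a simulation loop."""

    def __init__(self, message: str, replicate: int | None = None):
        super().__init__(message)
        self.replicate = replicate


class UndefinedIccError(CrtBayesError, ValueError):
    """ICC requested when both variance components are zero."""


class InvalidIccError(CrtBayesError, ValueError):
    """ICC outside the half-open interval [0, 1)."""


class ImproperPriorError(CrtBayesError, ValueError):
    """Fraction b = 0 would yield an improper (infinite-variance) prior."""


class UndefinedPmpError(CrtBayesError, ValueError):
    """All Bayes factors in a hypothesis set are zero."""


class InvalidAlternativeError(CrtBayesError, ValueError):
    """A power criterion requires a positive effect size under H1."""


class SimulationUnstableError(CrtBayesError, RuntimeError):
    """More than the allowed share of replicates failed to fit."""


class SampleSizeNotFoundError(CrtBayesError, RuntimeError):
    """The search cap was reached before the power criterion was met.
    Carries the search trace for diagnosis."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace or []
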