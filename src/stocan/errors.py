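"""Exception hierarchy for stocan."""


class StocanError(Exception):
    """Base class for all stocan errors."""


class SchemaError(StocanError):
    """Malformed model description (undeclared id, bad expression, ...)."""


class EvaluationError(StocanError):
    """A rate law or derivative evaluated to an invalid value."""


class SolverError(StocanError):
    """Steady-state solver failed to converge."""


class StabilityError(StocanError):
    """The steady state is not asymptotically stable (Jacobian not Hurwitz)."""


class SimulationError(StocanError):
    """Stochastic simulation failed (negative propensity, blow-up, ...)."""


class DesignError(StocanError):
    """A control-design request could not be interpreted."""
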