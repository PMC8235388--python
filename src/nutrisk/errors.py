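"""Exception hierarchy for the nutrisk pipeline."""


class NutriskError(Exception):
    """Base class for all pipeline errors."""


class InfeasibleWorldError(NutriskError):
    """A world specification implies a negative or degenerate flow."""


class CalibrationError(NutriskError):
    """The benchmark SAM cannot be calibrated (bad structure or flows)."""


class SolverError(NutriskError):
    """The equilibrium solver failed to converge.

    Carries the best residual reached so callers never mistake a partial
    answer for a solution.
    """

    def __init__(self, message: str, best_residual: float = float("nan")):
        super().__init__(message)
        self.best_residual = best_residual


class BatchError(NutriskError):
    """Too many failed solves for a Monte Carlo batch to be trusted."""


class ConfigError(NutriskError):
    """Invalid run configuration."""
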