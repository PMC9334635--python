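"""Exception hierarchy shared by all modules."""


class CavityDemixError(Exception):
    """Base class for package errors."""


class DomainError(CavityDemixError):
    """A physical or geometric precondition is violated (e.g. e >= 1)."""


class ConfigurationError(CavityDemixError):
    """A run/solver configuration is inconsistent or out of range."""


class DataError(CavityDemixError):
    """Input data violate an operation's contract (grids, masks, signs)."""


class SolverError(CavityDemixError):
    """Iterative solver failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class TrackingError(DataError):
    """A movie frame could not be tracked (e.g. zero total intensity)."""


class FitError(CavityDemixError):
    """A statistical fit could not be performed (too few events, all-degenerate)."""


class SimulationError(CavityDemixError):
    """Brownian-dynamics step violated an invariant (particle escaped mask)."""
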