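"""Exception hierarchy. Errors carry enough context to name the offending input."""


class MarkerCoverError(Exception):
    """Base class for all package errors."""


class DataError(MarkerCoverError):
    """Malformed or inconsistent input data (dimension mismatch, duplicate IDs...)."""


class InfeasibleError(MarkerCoverError):
    """Covering constraints cannot be met; carries a diagnostic.

    Attributes
    ----------
    max_feasible_rate : float or None
        Largest covering rate attainable with the full candidate set, so the
        caller can raise alpha or lower the depth.
    """

    def __init__(self, message, max_feasible_rate=None):
        super().__init__(message)
        self.max_feasible_rate = max_feasible_rate


class SolverError(MarkerCoverError):
    """The MILP back-end failed for a reason other than infeasibility."""
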