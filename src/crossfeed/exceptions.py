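"""Exception hierarchy for solver and contract failures."""


class CrossfeedError(Exception):
    """Base class for all package errors."""


class ModelFormatError(CrossfeedError):
    """A model or annotation file could not be parsed under the named dialect."""


class ContractError(CrossfeedError):
    """An operation was called with arguments violating its preconditions."""


class InfeasibleError(CrossfeedError):
    """The optimization problem has an empty feasible region.

    Carries a human-readable summary of the constraints that were applied,
    so that infeasible strain constructions can be diagnosed (and, in the
    pipeline, logged and skipped rather than aborting a scan).
    """

    def __init__(self, message: str, constraints: dict | None = None):
        super().__init__(message)
        self.constraints = dict(constraints or {})


class UnboundedError(CrossfeedError):
    """The LP objective is unbounded; ``witness`` names the objective reaction."""

    def __init__(self, message: str, witness: str | None = None):
        super().__init__(message)
        self.witness = witness


class SolverTimeoutError(CrossfeedError):
    """A MILP hit its time limit before proving optimality.

    The best bound found so far is attached; a suboptimal incumbent is never
    silently returned as if it were the distance.
    """

    def __init__(self, message: str, best_bound: float | None = None):
        super().__init__(message)
        self.best_bound = best_bound
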