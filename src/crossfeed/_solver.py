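"""Thin LP/MILP layer over scipy's HiGHS interfaces.

All optimization in the package funnels through :func:`solve_lp` and
:func:`solve_milp` so that tolerances, status handling and error reporting
are uniform.  Feasibility/optimality tolerances of 1e-9 are requested from
the solver; downstream contracts assert at 1e-6, which leaves headroom for
the count-based flux-change classification (a near-zero must be cleanly
below the activity threshold of 1e-3).
"""
from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .exceptions import InfeasibleError, SolverTimeoutError, UnboundedError

#: tolerance requested from HiGHS
SOLVER_TOL = 1e-9
#: tolerance at which returned solutions are asserted to satisfy constraints
ASSERT_TOL = 1e-6

_LP_OPTIONS = {
    "primal_feasibility_tolerance": SOLVER_TOL,
    "dual_feasibility_tolerance": SOLVER_TOL,
    "presolve": True,
}


def solve_lp(
    c: np.ndarray,
    A_eq: sp.spmatrix,
    b_eq: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    *,
    A_ub: sp.spmatrix | None = None,
    b_ub: np.ndarray | None = None,
    context: str = "LP",
    witness: str | None = None,
) -> np.ndarray:
    """Minimize ``c @ x`` subject to ``A_eq x = b_eq``, optional ``A_ub x <= b_ub``
    and box bounds.  Returns the optimal ``x``.

    Raises :class:`InfeasibleError` / :class:`UnboundedError` with *context*
    in the message on the corresponding HiGHS status.
    """
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options=_LP_OPTIONS,
    )
    if res.status == 2:
        raise InfeasibleError(f"{context}: problem is infeasible")
    if res.status == 3:
        raise UnboundedError(f"{context}: objective is unbounded", witness=witness)
    if res.status != 0:
        raise RuntimeError(f"{context}: solver failed with status {res.status}: {res.message}")
    return np.asarray(res.x, dtype=float)


def feasible_point(
    A_eq: sp.spmatrix,
    b_eq: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    *,
    A_ub: sp.spmatrix | None = None,
    b_ub: np.ndarray | None = None,
) -> np.ndarray | None:
    """Return any feasible point, or None if the region is empty."""
    if np.any(lb > ub + 1e-12):
        return None
    try:
        return solve_lp(
            np.zeros(A_eq.shape[1]), A_eq, b_eq, lb, ub, A_ub=A_ub, b_ub=b_ub,
            context="feasibility check",
        )
    except InfeasibleError:
        return None


def solve_milp(
    c: np.ndarray,
    A_eq: sp.spmatrix | None,
    b_eq: np.ndarray | None,
    A_ub: sp.spmatrix | None,
    b_ub: np.ndarray | None,
    lb: np.ndarray,
    ub: np.ndarray,
    integrality: np.ndarray,
    *,
    time_limit: float | None = None,
    context: str = "MILP",
) -> tuple[np.ndarray, float]:
    """Minimize ``c @ x`` over the mixed-integer set; returns ``(x, objective)``.

    The MILP is solved to proven optimality (``mip_rel_gap = 0``); hitting the
    time limit raises :class:`SolverTimeoutError` carrying HiGHS's best bound
    rather than returning an unproven incumbent.
    """
    constraints = []
    if A_eq is not None and A_eq.shape[0] > 0:
        constraints.append(LinearConstraint(A_eq, b_eq, b_eq))
    if A_ub is not None and A_ub.shape[0] > 0:
        constraints.append(LinearConstraint(A_ub, -np.inf, b_ub))
    options: dict = {"mip_rel_gap": 0.0}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    res = milp(
        c,
        constraints=constraints,
        bounds=Bounds(lb, ub),
        integrality=integrality,
        options=options,
    )
    # scipy.milp statuses: 0 optimal, 1 iteration/time limit, 2 infeasible, 3 unbounded
    if res.status == 2:
        raise InfeasibleError(f"{context}: problem is infeasible")
    if res.status == 3:
        raise UnboundedError(f"{context}: objective is unbounded")
    if res.status == 1:
        raise SolverTimeoutError(
            f"{context}: time limit reached before proven optimality",
            best_bound=getattr(res, "mip_dual_bound", None),
        )
    if res.status != 0 or res.x is None:
        raise RuntimeError(f"{context}: solver failed with status {res.status}: {res.message}")
    return np.asarray(res.x, dtype=float), float(res.fun)


def solver_description() -> dict:
    """Identify the backend for provenance records."""
    import scipy

    return {"solver": "highs", "via": f"scipy {scipy.__version__}",
            "feasibility_tol": SOLVER_TOL, "assert_tol": ASSERT_TOL}
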