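"""Minimal-flux-change optimizers: ROOM, ROOM-het, and MoMA.

The metabolic distance between two strains is the number of internal
reactions whose steady-state flux differs by more than a threshold beta
(default 0.001 mmol gDW^-1 h^-1).  ROOM minimizes this count against a fixed
reference flux distribution; ROOM-het finds *two* flux distributions
simultaneously — one satisfying an ancestor constraint set, one an evolved
constraint set — minimizing the count of internal reactions on which they
differ, which models a phenotypically heterogeneous ancestral population.
MoMA is the quadratic comparison method (minimal squared Euclidean flux
adjustment).

Both MILPs use one binary indicator f_i per counted internal reaction and two
linear big-M constraints per indicator, with the big-M implied by the flux
bounds, so any MILP backend can solve them.  For ROOM the constraints are

    e_i - f_i (u_i - (a_i + beta)) <= a_i + beta
    e_i - f_i (l_i - (a_i - beta)) >= a_i - beta

so that f_i = 0 forces a_i - beta <= e_i <= a_i + beta and f_i = 1 relaxes
the pair to the plain bounds.  For ROOM-het, where the reference a is itself
a variable, the equivalent exact linearization

    e_i - a_i <= beta + M_i f_i,   a_i - e_i <= beta + M'_i f_i

is used with M_i = u^e_i - l^a_i - beta and M'_i = u^a_i - l^e_i - beta.
MILPs are solved to proven optimality; indicators are rounded to {0,1} after
the solve and the implied constraints re-verified at 1e-6.

The optimal *distance* (objective value) is the contract of these methods.
The identity of the changed reactions is one optimal solution among possibly
many and is flagged as such in provenance.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import LinearConstraint, minimize

from ._solver import ASSERT_TOL, feasible_point, solve_milp, solver_description
from .exceptions import ContractError, InfeasibleError
from .fba_core import (ChemostatEnvironment, FluxDistribution,
                       apply_environment, check_steady_state)
from .model_io import ROLE_INTERNAL, MetabolicModel

DEFAULT_BETA = 0.001
DEFAULT_ACTIVITY_THRESHOLD = 0.001


def _counted_indices(model: MetabolicModel,
                     counted_reactions: list[str] | None) -> np.ndarray:
    if counted_reactions is None:
        return model.internal_indices()
    idx = []
    for rid in counted_reactions:
        j = model.rxn_index(rid)
        if model.reaction_roles[j] != ROLE_INTERNAL:
            raise ContractError(
                f"counted reaction {rid!r} is not an internal reaction")
        idx.append(j)
    return np.asarray(sorted(idx), dtype=int)


@dataclass
class RoomProblem:
    """A ROOM instance: fixed reference fluxes plus evolved-strain bounds.

    ``evolved_lb``/``evolved_ub`` are full bound vectors for the evolved
    strain (environment plus strain constraints already applied);
    ``counted_reactions`` restricts the indicator objective (defaults to all
    internal reactions — exchange and biomass fluxes stay constrained but do
    not enter the distance).
    """

    reference: FluxDistribution
    evolved_lb: np.ndarray
    evolved_ub: np.ndarray
    beta: float = DEFAULT_BETA
    counted_reactions: list[str] | None = None

    def __post_init__(self):
        if not self.beta > 0:
            raise ContractError("beta must be > 0")
        self.evolved_lb = np.asarray(self.evolved_lb, dtype=float)
        self.evolved_ub = np.asarray(self.evolved_ub, dtype=float)

    @classmethod
    def from_overrides(cls, model: MetabolicModel, env: ChemostatEnvironment,
                       reference: FluxDistribution,
                       overrides: dict[str, tuple[float, float]],
                       beta: float = DEFAULT_BETA,
                       counted_reactions: list[str] | None = None) -> "RoomProblem":
        lb, ub = apply_environment(model, env, overrides)
        return cls(reference, lb, ub, beta, counted_reactions)


@dataclass
class HetProblem:
    """A ROOM-het instance: ancestor and evolved bound sets, no fixed reference."""

    ancestor_lb: np.ndarray
    ancestor_ub: np.ndarray
    evolved_lb: np.ndarray
    evolved_ub: np.ndarray
    beta: float = DEFAULT_BETA
    counted_reactions: list[str] | None = None

    def __post_init__(self):
        if not self.beta > 0:
            raise ContractError("beta must be > 0")
        for name in ("ancestor_lb", "ancestor_ub", "evolved_lb", "evolved_ub"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))


@dataclass
class ChangeClassification:
    """Partition of the changed reactions (|e - a| > beta) into three kinds.

    A reaction is *active* iff its absolute flux exceeds
    ``activity_threshold``.  ``turned_on``: inactive in the ancestor, active in
    the evolved strain; ``turned_off``: the reverse; ``magnitude_change``: the
    remaining changed reactions (typically active in both).  The three sets
    are pairwise disjoint and their union is exactly the changed set.
    """

    turned_on: frozenset[str]
    turned_off: frozenset[str]
    magnitude_change: frozenset[str]
    beta: float = DEFAULT_BETA
    activity_threshold: float = DEFAULT_ACTIVITY_THRESHOLD

    @property
    def n_changed(self) -> int:
        return len(self.turned_on) + len(self.turned_off) + len(self.magnitude_change)

    @property
    def changed(self) -> frozenset[str]:
        return self.turned_on | self.turned_off | self.magnitude_change


def classify_changes(
    a: FluxDistribution,
    e: FluxDistribution,
    beta: float = DEFAULT_BETA,
    activity_threshold: float = DEFAULT_ACTIVITY_THRESHOLD,
    reactions: list[str] | None = None,
    tol: float = ASSERT_TOL,
) -> ChangeClassification:
    """Classify flux changes between a reference *a* and an evolved *e*.

    ``reactions`` restricts the classification (e.g. to the internal reactions
    counted by ROOM); by default all shared reactions are classified.  A
    reaction counts as changed iff |e - a| > beta, evaluated with the same
    numeric tolerance the solvers are verified at, so that solutions sitting
    exactly on the a +/- beta boundary are not spuriously counted.  Raises
    :class:`ContractError` if the two distributions are over different
    reaction sets.
    """
    if a.reaction_ids != e.reaction_ids:
        raise ContractError("flux distributions are over different reaction sets")
    ids = a.reaction_ids if reactions is None else list(reactions)
    on, off, mag = set(), set(), set()
    for rid in ids:
        av, ev = a[rid], e[rid]
        if abs(ev - av) <= beta + tol:
            continue
        a_active = abs(av) > activity_threshold
        e_active = abs(ev) > activity_threshold
        if not a_active and e_active:
            on.add(rid)
        elif a_active and not e_active:
            off.add(rid)
        else:
            mag.add(rid)
    return ChangeClassification(frozenset(on), frozenset(off), frozenset(mag),
                                beta, activity_threshold)


@dataclass
class RoomResult:
    """Outcome of a ROOM or ROOM-het solve."""

    evolved: FluxDistribution
    distance: int
    changed_reactions: frozenset[str]
    ancestor: FluxDistribution | None = None
    provenance: dict = field(default_factory=dict)


def _verify_indicators(diff: np.ndarray, f: np.ndarray, beta: float) -> None:
    unchanged = f < 0.5
    if unchanged.any() and np.abs(diff[unchanged]).max() > beta + ASSERT_TOL:
        raise RuntimeError(
            "indicator verification failed: a reaction marked unchanged moved "
            f"by {np.abs(diff[unchanged]).max():.3g} > beta")


def room(model: MetabolicModel, problem: RoomProblem,
         time_limit: float | None = None) -> RoomResult:
    """Regulatory on/off minimization against a fixed reference distribution.

    Returns the evolved flux distribution and the proven-minimal number of
    counted internal reactions whose flux differs from the reference by more
    than beta.
    """
    a = problem.reference.values
    if a.size != model.n_reactions:
        raise ContractError("reference distribution does not match the model")
    lb, ub = problem.evolved_lb, problem.evolved_ub
    beta = problem.beta
    counted = _counted_indices(model, problem.counted_reactions)
    r, k, m = model.n_reactions, counted.size, model.n_metabolites

    # variables: [e (r), f (k)]
    A_eq = sp.hstack([model.S, sp.csc_matrix((m, k))], format="csc")
    rows_ub = []
    rhs_ub = []
    e_part = sp.identity(r, format="csr")
    # e_i - (u_i - a_i - beta) f_i <= a_i + beta
    coef_up = -(ub[counted] - (a[counted] + beta))
    up = sp.hstack([e_part[counted], sp.diags(coef_up)], format="csr")
    rows_ub.append(up)
    rhs_ub.append(a[counted] + beta)
    # e_i - f_i (l_i - (a_i - beta)) >= a_i - beta, negated into <= form:
    # -e_i + (l_i - a_i + beta) f_i <= -(a_i - beta)
    coef_lo = lb[counted] - (a[counted] - beta)
    lo = sp.hstack([-e_part[counted], sp.diags(coef_lo)], format="csr")
    rows_ub.append(lo)
    rhs_ub.append(-(a[counted] - beta))
    A_ub = sp.vstack(rows_ub, format="csc")
    b_ub = np.concatenate(rhs_ub)
    c = np.concatenate([np.zeros(r), np.ones(k)])
    lo_x = np.concatenate([lb, np.zeros(k)])
    hi_x = np.concatenate([ub, np.ones(k)])
    integrality = np.concatenate([np.zeros(r), np.ones(k)])
    try:
        x, obj = solve_milp(c, A_eq, np.zeros(m), A_ub, b_ub, lo_x, hi_x,
                            integrality, time_limit=time_limit, context="ROOM")
    except InfeasibleError:
        raise InfeasibleError(
            "ROOM: evolved strain constraints are infeasible "
            "(no steady-state flux satisfies the imposed bounds)")
    e, f = x[:r], np.round(x[r:])
    _verify_indicators(e[counted] - a[counted], f, beta)
    check_steady_state(model, e, lb, ub)
    distance = int(round(f.sum()))
    prov = {"method": "room", "beta": beta, "distance": distance,
            "optimality_gap": 0.0,
            "changed_set_note": "one optimal solution among possibly many"}
    prov.update(solver_description())
    evolved = FluxDistribution(list(model.reaction_ids), e, prov)
    changed = frozenset(model.reaction_ids[j]
                        for j, fj in zip(counted, f) if fj > 0.5)
    return RoomResult(evolved, distance, changed, provenance=prov)


def room_het(model: MetabolicModel, problem: HetProblem,
             time_limit: float | None = None) -> RoomResult:
    """ROOM-het: ancestor and evolved flux distributions found jointly.

    Minimizes the number of counted internal reactions on which the two
    distributions differ by more than beta, with each distribution satisfying
    its own constraint set.  The result's distance is never larger than the
    ROOM distance computed against any fixed ancestor satisfying the ancestor
    constraints (that ancestor is a feasible choice of ``a`` here).
    """
    la, ua = problem.ancestor_lb, problem.ancestor_ub
    le, ue = problem.evolved_lb, problem.evolved_ub
    beta = problem.beta
    counted = _counted_indices(model, problem.counted_reactions)
    r, k, m = model.n_reactions, counted.size, model.n_metabolites

    # variables: [a (r), e (r), f (k)]
    Z = sp.csc_matrix((m, r))
    Zf = sp.csc_matrix((m, k))
    A_eq = sp.vstack([
        sp.hstack([model.S, Z, Zf]),
        sp.hstack([Z, model.S, Zf]),
    ], format="csc")
    ident = sp.identity(r, format="csr")
    Ic = ident[counted]
    big_up = np.maximum(ue[counted] - la[counted] - beta, 0.0)
    big_lo = np.maximum(ua[counted] - le[counted] - beta, 0.0)
    # e - a - M f <= beta ;  a - e - M' f <= beta
    A_ub = sp.vstack([
        sp.hstack([-Ic, Ic, sp.diags(-big_up)]),
        sp.hstack([Ic, -Ic, sp.diags(-big_lo)]),
    ], format="csc")
    b_ub = np.full(2 * k, beta)
    c = np.concatenate([np.zeros(2 * r), np.ones(k)])
    lo_x = np.concatenate([la, le, np.zeros(k)])
    hi_x = np.concatenate([ua, ue, np.ones(k)])
    integrality = np.concatenate([np.zeros(2 * r), np.ones(k)])
    try:
        x, obj = solve_milp(c, A_eq, np.zeros(2 * m), A_ub, b_ub, lo_x, hi_x,
                            integrality, time_limit=time_limit,
                            context="ROOM-het")
    except InfeasibleError:
        raise InfeasibleError(
            "ROOM-het: ancestor or evolved constraint set is infeasible")
    a, e, f = x[:r], x[r:2 * r], np.round(x[2 * r:])
    _verify_indicators(e[counted] - a[counted], f, beta)
    check_steady_state(model, a, la, ua)
    check_steady_state(model, e, le, ue)
    distance = int(round(f.sum()))
    prov = {"method": "room_het", "beta": beta, "distance": distance,
            "optimality_gap": 0.0,
            "changed_set_note": "one optimal solution among possibly many"}
    prov.update(solver_description())
    ancestor = FluxDistribution(list(model.reaction_ids), a, dict(prov, role="ancestor"))
    evolved = FluxDistribution(list(model.reaction_ids), e, dict(prov, role="evolved"))
    changed = frozenset(model.reaction_ids[j]
                        for j, fj in zip(counted, f) if fj > 0.5)
    return RoomResult(evolved, distance, changed, ancestor=ancestor,
                      provenance=prov)


def moma(model: MetabolicModel, reference: FluxDistribution,
         evolved_lb: np.ndarray, evolved_ub: np.ndarray) -> FluxDistribution:
    """Minimization of metabolic adjustment (quadratic variant).

    Finds the evolved flux vector minimizing the squared Euclidean distance
    to the reference, subject to steady state and the evolved bounds.  The
    objective is strictly convex, so the minimizer is unique in flux space.
    """
    a = np.asarray(reference.values, dtype=float)
    lb = np.asarray(evolved_lb, dtype=float)
    ub = np.asarray(evolved_ub, dtype=float)
    if a.size != model.n_reactions:
        raise ContractError("reference distribution does not match the model")
    x0 = feasible_point(model.S, np.zeros(model.n_metabolites), lb, ub)
    if x0 is None:
        raise InfeasibleError("MoMA: evolved strain constraints are infeasible")
    S = model.S.tocsr()

    def objective(x):
        d = x - a
        return float(d @ d)

    def grad(x):
        return 2.0 * (x - a)

    hess = sp.identity(model.n_reactions, format="csr") * 2.0
    res = minimize(
        objective, x0, jac=grad, hess=lambda x: hess,
        method="trust-constr",
        constraints=[LinearConstraint(S, 0.0, 0.0)],
        bounds=np.column_stack([lb, ub]),
        options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 3000, "verbose": 0},
    )
    v = np.asarray(res.x, dtype=float)
    check_steady_state(model, v, lb, ub, tol=1e-5)
    prov = {"method": "moma", "objective_value": objective(v)}
    prov.update(solver_description())
    prov["solver"] = "trust-constr"
    return FluxDistribution(list(model.reaction_ids), v, prov)
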