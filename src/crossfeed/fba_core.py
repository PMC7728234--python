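"""Linear-programming primitives for chemostat steady-state modeling.

A :class:`ChemostatEnvironment` describes a glucose-limited minimal medium:
one primary carbon source with a maximal uptake rate, a set of non-limiting
inorganic exchanges opened without bound, and every other exchange closed for
uptake (secretion always remains open).  On top of the resulting bounds,
:func:`fba` maximizes (or minimizes) a flux, :func:`pfba` finds the
minimal-total-flux distribution at a fixed growth rate, and
:func:`minimize_uptake` finds the smallest uptake of a given exchange
compatible with a set of flux equalities — the construction used to pin the
glucose consumption of producer strains and the secondary-carbon consumption
of consumer strains.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ._solver import ASSERT_TOL, solve_lp, solver_description
from .exceptions import ContractError, InfeasibleError
from .model_io import ROLE_EXCHANGE, MetabolicModel

#: magnitude used to open an exchange "without bound"
OPEN_BOUND = 1000.0


@dataclass(frozen=True)
class ChemostatEnvironment:
    """Glucose-limited chemostat medium and operating point.

    dilution_rate: h^-1; at steady state the growth rate equals it.
    primary_carbon: exchange reaction id of the limiting carbon source.
    uptake_cap: maximal uptake magnitude of the primary carbon
        (mmol gDW^-1 h^-1, stated positive; applied as a negative lower bound).
    nonlimiting_inorganics: exchange ids opened unboundedly for uptake.
    """

    dilution_rate: float = 0.2
    primary_carbon: str = "EX_glc__D_e"
    uptake_cap: float = 10.0
    nonlimiting_inorganics: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.dilution_rate > 0:
            raise ContractError("dilution_rate must be > 0")
        if self.uptake_cap < 0:
            raise ContractError("uptake_cap must be >= 0")

    def summary(self) -> dict:
        return {
            "dilution_rate": self.dilution_rate,
            "primary_carbon": self.primary_carbon,
            "uptake_cap": self.uptake_cap,
            "nonlimiting_inorganics": sorted(self.nonlimiting_inorganics),
        }


def apply_environment(
    model: MetabolicModel,
    env: ChemostatEnvironment,
    overrides: dict[str, tuple[float, float]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (lb, ub) bound vectors for *model* under *env*.

    All exchange uptake is closed, then the non-limiting inorganics are opened
    unboundedly and the primary carbon opened up to its cap.  ``overrides``
    maps reaction ids to (lb, ub) pairs applied last — this is how strain
    constraints (growth equality, forced excretion, fixed uptake) are imposed.
    """
    lb, ub = model.copy_bounds()
    for rid, role in zip(model.reaction_ids, model.reaction_roles):
        if role == ROLE_EXCHANGE:
            j = model.rxn_index(rid)
            lb[j] = max(lb[j], 0.0)
    for rid in env.nonlimiting_inorganics:
        lb[model.rxn_index(rid)] = -OPEN_BOUND
    lb[model.rxn_index(env.primary_carbon)] = -float(env.uptake_cap)
    if overrides:
        for rid, (lo, hi) in overrides.items():
            j = model.rxn_index(rid)
            lb[j], ub[j] = float(lo), float(hi)
    return lb, ub


@dataclass
class FluxDistribution:
    """One steady-state flux vector with provenance.

    Invariants (checked on construction): |S v| <= 1e-6 per metabolite and
    lb - 1e-6 <= v <= ub + 1e-6 against the bounds it was solved under.
    """

    reaction_ids: list[str]
    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.reaction_ids) != self.values.size:
            raise ContractError("flux vector length does not match reaction ids")
        self._index = {r: i for i, r in enumerate(self.reaction_ids)}

    def __getitem__(self, reaction_id: str) -> float:
        try:
            return float(self.values[self._index[reaction_id]])
        except KeyError:
            raise ContractError(f"unknown reaction id {reaction_id!r}") from None

    @property
    def objective_value(self) -> float | None:
        return self.provenance.get("objective_value")

    def total_flux(self) -> float:
        return float(np.sum(np.abs(self.values)))


def check_steady_state(model: MetabolicModel, v: np.ndarray,
                       lb: np.ndarray, ub: np.ndarray,
                       tol: float = ASSERT_TOL) -> None:
    residual = np.abs(model.S @ v)
    if residual.size and residual.max() > tol:
        i = int(np.argmax(residual))
        raise RuntimeError(
            f"steady-state violated: |S v| = {residual.max():.3g} at "
            f"metabolite {model.metabolite_ids[i]!r}")
    if np.any(v < lb - tol) or np.any(v > ub + tol):
        j = int(np.argmax(np.maximum(lb - v, v - ub)))
        raise RuntimeError(
            f"bounds violated at reaction {model.reaction_ids[j]!r}")


def _make_distribution(model, v, lb, ub, method, env, extra=None) -> FluxDistribution:
    check_steady_state(model, v, lb, ub)
    prov = {"method": method, "environment": env.summary() if env else None}
    prov.update(solver_description())
    if extra:
        prov.update(extra)
    return FluxDistribution(list(model.reaction_ids), v, prov)


def _infeasibility_report(model, env, overrides, context) -> InfeasibleError:
    binding = {env.primary_carbon: f"uptake <= {env.uptake_cap}"}
    for rid in sorted(env.nonlimiting_inorganics):
        binding[rid] = "uptake open"
    for rid, (lo, hi) in (overrides or {}).items():
        binding[rid] = f"[{lo}, {hi}]"
    lines = ", ".join(f"{k}: {v}" for k, v in binding.items())
    return InfeasibleError(
        f"{context}: infeasible under environment constraints ({lines})",
        constraints=binding)


def fba(
    model: MetabolicModel,
    env: ChemostatEnvironment,
    objective: str | None = None,
    sense: str = "max",
    overrides: dict[str, tuple[float, float]] | None = None,
) -> FluxDistribution:
    """Flux balance analysis: optimize one flux under steady state and bounds.

    ``objective`` defaults to the biomass reaction.  Returns an optimal vertex
    solution with the objective value in provenance.
    """
    if sense not in ("max", "min"):
        raise ContractError(f"sense must be 'max' or 'min', got {sense!r}")
    objective = objective or model.biomass_reaction_id
    j = model.rxn_index(objective)
    lb, ub = apply_environment(model, env, overrides)
    c = np.zeros(model.n_reactions)
    c[j] = -1.0 if sense == "max" else 1.0
    try:
        v = solve_lp(c, model.S, np.zeros(model.n_metabolites), lb, ub,
                     context=f"FBA({objective})", witness=objective)
    except InfeasibleError:
        raise _infeasibility_report(model, env, overrides, f"FBA({objective})")
    return _make_distribution(
        model, v, lb, ub, "fba", env,
        {"objective": objective, "sense": sense,
         "objective_value": float(v[j])})


def pfba(
    model: MetabolicModel,
    env: ChemostatEnvironment,
    growth_rate: float,
    overrides: dict[str, tuple[float, float]] | None = None,
) -> FluxDistribution:
    """Parsimonious FBA: minimize the total absolute flux at a fixed growth rate.

    Growth is fixed as an equality (v_growth = growth_rate); absolute values
    are realized by splitting every flux into non-negative forward and reverse
    parts, so the LP stays linear.  The minimal total flux is recorded in
    provenance as ``total_flux``; individual fluxes of alternate optima are
    advisory, only the objective value and constraint satisfaction are
    contractual.
    """
    all_overrides = dict(overrides or {})
    all_overrides[model.biomass_reaction_id] = (growth_rate, growth_rate)
    lb, ub = apply_environment(model, env, all_overrides)
    r = model.n_reactions
    # forward part in [max(lb,0), max(ub,0)], reverse part in [max(-ub,0), max(-lb,0)]
    lb_f, ub_f = np.maximum(lb, 0.0), np.maximum(ub, 0.0)
    lb_r, ub_r = np.maximum(-ub, 0.0), np.maximum(-lb, 0.0)
    A_eq = sp.hstack([model.S, -model.S], format="csc")
    c = np.ones(2 * r)
    try:
        x = solve_lp(c, A_eq, np.zeros(model.n_metabolites),
                     np.concatenate([lb_f, lb_r]), np.concatenate([ub_f, ub_r]),
                     context=f"pFBA(growth={growth_rate})")
    except InfeasibleError:
        raise _infeasibility_report(model, env, all_overrides,
                                    f"pFBA(growth={growth_rate})")
    v = x[:r] - x[r:]
    total = float(np.sum(x))
    dist = _make_distribution(
        model, v, lb, ub, "pfba", env,
        {"growth_rate": growth_rate, "total_flux": total,
         "objective_value": total})
    if abs(dist[model.biomass_reaction_id] - growth_rate) > ASSERT_TOL:
        raise RuntimeError("pFBA growth equality violated beyond tolerance")
    return dist


def minimize_uptake(
    model: MetabolicModel,
    env: ChemostatEnvironment,
    exchange_id: str,
    fixed: dict[str, float] | None = None,
    overrides: dict[str, tuple[float, float]] | None = None,
) -> tuple[float, FluxDistribution]:
    """Minimal uptake magnitude through *exchange_id* subject to flux equalities.

    ``fixed`` maps reaction ids to required flux values (e.g. growth = D,
    secondary excretion = 1); ``overrides`` may additionally open or adjust
    bounds (e.g. open the secondary exchange for uptake before minimizing over
    it).  Returns ``(magnitude, distribution)`` where magnitude >= 0 is the
    uptake (negative flux) needed; 0 if the equalities are satisfiable without
    any uptake.
    """
    j = model.rxn_index(exchange_id)
    all_overrides = dict(overrides or {})
    for rid, val in (fixed or {}).items():
        all_overrides[rid] = (float(val), float(val))
    lb, ub = apply_environment(model, env, all_overrides)
    c = np.zeros(model.n_reactions)
    c[j] = -1.0  # maximize v_exchange, i.e. push uptake toward zero
    try:
        v = solve_lp(c, model.S, np.zeros(model.n_metabolites), lb, ub,
                     context=f"minimize_uptake({exchange_id})",
                     witness=exchange_id)
    except InfeasibleError:
        raise _infeasibility_report(model, env, all_overrides,
                                    f"minimize_uptake({exchange_id})")
    if v[j] >= -ASSERT_TOL:
        # no uptake needed; re-solve with the exchange closed for uptake so the
        # witness distribution itself has zero uptake
        lb2 = lb.copy()
        lb2[j] = max(lb2[j], 0.0)
        v = solve_lp(np.zeros(model.n_reactions), model.S,
                     np.zeros(model.n_metabolites), lb2, ub,
                     context=f"minimize_uptake({exchange_id})")
        magnitude = 0.0
        lb = lb2
    else:
        magnitude = float(-v[j])
    dist = _make_distribution(
        model, v, lb, ub, "minimize_uptake", env,
        {"exchange": exchange_id, "minimal_uptake": magnitude,
         "objective_value": magnitude,
         "fixed": {k: float(val) for k, val in (fixed or {}).items()}})
    return magnitude, dist
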