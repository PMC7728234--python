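"""Orchestration of the cross-feeding evolvability analysis.

For every candidate secondary carbon metabolite, the pipeline constructs the
producer strain problem (growth at the dilution rate, forced excretion of the
metabolite, glucose consumption fixed at the minimal amount compatible with
those two constraints) and the consumer strain problem (growth at the
dilution rate, no glucose consumption, uptake of the metabolite fixed at its
minimal sufficient value), computes the minimal-flux-change distance of each
to the ancestral strain with ROOM or ROOM-het, classifies the changed
reactions, ranks metabolites by total distance, measures how much different
strain problems share changed reactions, and sweeps the ancestral glucose
allowance to see how excess consumption reshapes the ranking.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .exceptions import ContractError, CrossfeedError, InfeasibleError
from .fba_core import (ChemostatEnvironment, FluxDistribution,
                       apply_environment, fba, minimize_uptake, pfba)
from .model_io import MetabolicModel
from .room_methods import (DEFAULT_BETA, ChangeClassification, HetProblem,
                           RoomProblem, classify_changes, room, room_het)

logger = logging.getLogger("crossfeed")

PRODUCER = "producer"
CONSUMER = "consumer"
ANCESTOR = "ancestor"
CONSUMER_WITH_GLUCOSE = "consumer_with_glucose"

#: default excretion rate imposed on producer strains, mmol gDW^-1 h^-1
DEFAULT_EXCRETION_RATE = 1.0


@dataclass(frozen=True)
class StrainSpec:
    """Declarative description of one evolved-strain constraint problem.

    ``glucose_policy`` for the ancestor role: ``"minimal_required"`` caps
    glucose uptake at the minimal value for growth at D, ``("fixed_cap", g)``
    caps it at g.  Producer glucose is always fixed (equality) at the minimal
    amount satisfying growth + excretion.  Consumers get glucose 0, or fixed
    at 1 mmol gDW^-1 h^-1 for the ``consumer_with_glucose`` variant.
    """

    role: str
    secondary_metabolite: str | None = None
    excretion_rate: float = DEFAULT_EXCRETION_RATE

    def __post_init__(self):
        if self.role not in (PRODUCER, CONSUMER, ANCESTOR, CONSUMER_WITH_GLUCOSE):
            raise ContractError(f"unknown strain role {self.role!r}")
        if self.role == PRODUCER and not self.excretion_rate > 0:
            raise ContractError("producer excretion_rate must be > 0")
        if self.role != ANCESTOR and self.secondary_metabolite is None:
            raise ContractError(f"{self.role} spec needs a secondary metabolite")


@dataclass
class DistanceResult:
    """One producer- or consumer-vs-ancestor comparison."""

    metabolite: str
    role: str
    distance: int
    classification: ChangeClassification
    ancestor_flux: FluxDistribution
    evolved_flux: FluxDistribution
    changed_reactions: frozenset[str]
    method: str
    glucose_equality: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.distance != self.classification.n_changed:
            raise CrossfeedError(
                f"distance {self.distance} != classified changes "
                f"{self.classification.n_changed} for {self.metabolite}/{self.role}")


@dataclass
class SweepResult:
    """Distances across a grid of ancestral glucose caps."""

    glucose_grid: list[float]
    table: pd.DataFrame  # columns: metabolite, cap, role, distance, total per cap
    rank_correlations: list[float]  # Spearman rho between consecutive caps


def ancestral_state(model: MetabolicModel,
                    env: ChemostatEnvironment) -> FluxDistribution:
    """Parsimonious-FBA flux distribution of the ancestor at growth = D."""
    return pfba(model, env, env.dilution_rate)


def minimal_glucose(model: MetabolicModel, env: ChemostatEnvironment) -> float:
    """Minimal primary-carbon uptake supporting growth at the dilution rate."""
    magnitude, _ = minimize_uptake(
        model, env, env.primary_carbon,
        fixed={model.biomass_reaction_id: env.dilution_rate})
    return magnitude


def build_strain_constraints(
    model: MetabolicModel,
    env: ChemostatEnvironment,
    spec: StrainSpec,
    ancestor_glucose_cap: float | None = None,
) -> dict[str, tuple[float, float]]:
    """Bound overrides encoding one strain's constraint problem.

    producer: growth = D, secondary excretion = excretion_rate, glucose uptake
    fixed (equality) at the minimize_uptake result for those constraints.
    consumer: growth = D, glucose uptake = 0 (or = 1 for the variant), and
    secondary uptake fixed at its minimize_uptake value, mirroring the
    producer's glucose treatment.  ancestor: growth = D, glucose uptake capped
    (not fixed) at ``ancestor_glucose_cap`` (default: the environment cap).

    Raises :class:`InfeasibleError` when the metabolite cannot support the
    role (e.g. cannot serve as sole carbon source); scans catch this and
    exclude the metabolite.
    """
    D = env.dilution_rate
    growth = {model.biomass_reaction_id: (D, D)}
    glc = env.primary_carbon
    if spec.role == ANCESTOR:
        cap = env.uptake_cap if ancestor_glucose_cap is None else ancestor_glucose_cap
        return {**growth, glc: (-float(cap), 0.0)}

    ex = exchange_for_metabolite(model, spec.secondary_metabolite)
    if spec.role == PRODUCER:
        g_min, _ = minimize_uptake(
            model, env, glc,
            fixed={model.biomass_reaction_id: D, ex: spec.excretion_rate})
        return {**growth, ex: (spec.excretion_rate, spec.excretion_rate),
                glc: (-g_min, -g_min)}

    # consumer roles: open the secondary exchange for uptake, then fix it at
    # the minimal uptake supporting growth under the glucose policy
    if spec.role == CONSUMER:
        glc_bounds = (0.0, 0.0)
    else:  # consumer_with_glucose: consumes exactly 1 mmol gDW^-1 h^-1
        glc_bounds = (-1.0, -1.0)
    u_min, _ = minimize_uptake(
        model, env, ex,
        fixed={model.biomass_reaction_id: D},
        overrides={glc: glc_bounds, ex: (-1000.0, 0.0)})
    return {**growth, glc: glc_bounds, ex: (-u_min, -u_min)}


def exchange_for_metabolite(model: MetabolicModel, metabolite: str) -> str:
    """Resolve a metabolite or exchange-reaction id to its exchange reaction."""
    if metabolite in model.reaction_ids:
        return metabolite
    for cand in (f"EX_{metabolite}", f"EX_{metabolite}_e", f"EX_{metabolite}e"):
        if cand in model.reaction_ids:
            return cand
    raise ContractError(f"no exchange reaction found for {metabolite!r}")


def candidate_metabolites(model: MetabolicModel) -> list[str]:
    """Exchangeable metabolites other than the biomass drain — a convenience
    enumerator for building candidate lists; the studied list is user input."""
    return [rid for rid in model.exchange_reactions()]


def _distance_for(model, env, ancestor, metabolite, role, method, beta,
                  ancestor_glucose_cap, time_limit=None) -> DistanceResult:
    spec = StrainSpec(role=role, secondary_metabolite=metabolite)
    overrides = build_strain_constraints(model, env, spec)
    glucose_eq = overrides.get(env.primary_carbon, (None,))[0]
    counted = model.internal_reactions()
    if method == "room":
        problem = RoomProblem.from_overrides(model, env, ancestor, overrides,
                                             beta=beta)
        res = room(model, problem, time_limit=time_limit)
        anc = ancestor
    elif method == "room_het":
        anc_spec = StrainSpec(role=ANCESTOR)
        anc_overrides = build_strain_constraints(
            model, env, anc_spec, ancestor_glucose_cap=ancestor_glucose_cap)
        la, ua = apply_environment(model, env, anc_overrides)
        le, ue = apply_environment(model, env, overrides)
        res = room_het(model, HetProblem(la, ua, le, ue, beta=beta),
                       time_limit=time_limit)
        anc = res.ancestor
    else:
        raise ContractError(f"unknown method {method!r}")
    classification = classify_changes(anc, res.evolved, beta=beta,
                                      reactions=counted)
    return DistanceResult(
        metabolite=metabolite, role=role, distance=res.distance,
        classification=classification, ancestor_flux=anc,
        evolved_flux=res.evolved, changed_reactions=res.changed_reactions,
        method=method,
        glucose_equality=None if glucose_eq is None else -glucose_eq,
        provenance=res.provenance)


def compute_distances(
    model: MetabolicModel,
    env: ChemostatEnvironment,
    metabolites: list[str],
    method: str = "room",
    beta: float = DEFAULT_BETA,
    ancestor: FluxDistribution | None = None,
    ancestor_glucose_cap: float | None = None,
    time_limit: float | None = None,
) -> list[DistanceResult]:
    """Producer and consumer distances for each metabolite.

    For ROOM the fixed reference is the pFBA ancestral state (computed here if
    not supplied).  For ROOM-het the ancestor constraint set caps glucose at
    ``ancestor_glucose_cap`` (default: the minimal glucose for growth at D,
    matching a maximally efficient ancestral population).  Metabolites
    infeasible in either role are logged and skipped, not fatal.
    """
    if method == "room" and ancestor is None:
        ancestor = ancestral_state(model, env)
    if method == "room_het" and ancestor_glucose_cap is None:
        ancestor_glucose_cap = minimal_glucose(model, env)
    results: list[DistanceResult] = []
    for metabolite in metabolites:
        for role in (PRODUCER, CONSUMER):
            try:
                results.append(_distance_for(
                    model, env, ancestor, metabolite, role, method, beta,
                    ancestor_glucose_cap, time_limit))
            except InfeasibleError as exc:
                logger.warning("%s %s infeasible, excluded: %s",
                               metabolite, role, exc)
    return results


def rank_metabolites(results: list[DistanceResult]) -> pd.DataFrame:
    """Ranking table: total distance ascending, rank 1 = most likely to evolve.

    Ties share the minimum rank (competition ranking).  Metabolites missing
    either role are omitted with a warning.
    """
    by_met: dict[str, dict[str, DistanceResult]] = {}
    for res in results:
        by_met.setdefault(res.metabolite, {})[res.role] = res
    rows = []
    for metabolite, roles in by_met.items():
        if PRODUCER not in roles or CONSUMER not in roles:
            logger.warning("metabolite %s lacks a %s result; omitted from ranking",
                           metabolite,
                           PRODUCER if PRODUCER not in roles else CONSUMER)
            continue
        prod, cons = roles[PRODUCER], roles[CONSUMER]
        rows.append({
            "metabolite": metabolite,
            "producer_distance": prod.distance,
            "consumer_distance": cons.distance,
            "total": prod.distance + cons.distance,
            "n_on": len(prod.classification.turned_on)
                    + len(cons.classification.turned_on),
            "n_off": len(prod.classification.turned_off)
                     + len(cons.classification.turned_off),
            "n_magnitude": len(prod.classification.magnitude_change)
                           + len(cons.classification.magnitude_change),
        })
    if not rows:
        raise ContractError("no metabolite has both producer and consumer results")
    table = pd.DataFrame(rows).sort_values(
        ["total", "metabolite"]).reset_index(drop=True)
    table["rank"] = table["total"].rank(method="min").astype(int)
    table.attrs["tie_rule"] = "competition (ties share the minimum rank)"
    return table


def shared_reactions(results: list[DistanceResult], role: str,
                     fraction: float | None = None) -> frozenset[str]:
    """Reactions changed in at least ``fraction`` of the results of a role.

    ``fraction=None`` gives the union, ``fraction=1`` the intersection.  The
    answer depends on which optimal change-set the MILP returned for each
    strain (alternate optima exist); interpret counts with that caveat.
    """
    sets = [res.changed_reactions for res in results if res.role == role]
    if not sets:
        raise ContractError(f"no results with role {role!r}")
    if fraction is None:
        return frozenset().union(*sets)
    if not 0 < fraction <= 1:
        raise ContractError("fraction must be in (0, 1]")
    need = fraction * len(sets)
    counts: dict[str, int] = {}
    for s in sets:
        for rid in s:
            counts[rid] = counts.get(rid, 0) + 1
    return frozenset(rid for rid, n in counts.items() if n >= need - 1e-9)


def glucose_sweep(
    model: MetabolicModel,
    env: ChemostatEnvironment,
    metabolites: list[str],
    grid: list[float],
    beta: float = DEFAULT_BETA,
    time_limit: float | None = None,
) -> SweepResult:
    """ROOM-het distances as the ancestral glucose allowance grows.

    At each grid cap the ancestor's glucose uptake is *bounded above* by the
    cap (not fixed), so the ancestral solution space only grows along the
    grid and each metabolite/role distance is non-increasing — this is
    asserted.  Spearman rank correlations of the totals between consecutive
    caps quantify how stable the ranking is.
    """
    g_min = minimal_glucose(model, env)
    if min(grid) < g_min - 1e-6:
        raise ContractError(
            f"grid values must be >= minimal glucose {g_min:.4g}")
    rows = []
    for cap in grid:
        results = compute_distances(model, env, metabolites, method="room_het",
                                    beta=beta, ancestor_glucose_cap=cap,
                                    time_limit=time_limit)
        for res in results:
            rows.append({"metabolite": res.metabolite, "cap": cap,
                         "role": res.role, "distance": res.distance})
    table = pd.DataFrame(rows)
    # per-role monotone non-increase along increasing caps
    for (metabolite, role), sub in table.groupby(["metabolite", "role"]):
        dist = sub.sort_values("cap")["distance"].to_numpy()
        if np.any(np.diff(dist) > 0):
            raise CrossfeedError(
                f"sweep distance increased with the glucose cap for "
                f"{metabolite}/{role}: {dist.tolist()}")
    totals = (table.pivot_table(index="metabolite", columns="cap",
                                values="distance", aggfunc="sum")
              .reindex(columns=sorted(grid)))
    correlations = []
    caps = sorted(grid)
    for lo, hi in zip(caps[:-1], caps[1:]):
        x, y = totals[lo].to_numpy(float), totals[hi].to_numpy(float)
        if np.all(x == x[0]) or np.all(y == y[0]) or x.size < 2:
            correlations.append(float("nan"))
        else:
            correlations.append(float(spearmanr(x, y).statistic))
    return SweepResult(glucose_grid=list(grid), table=table,
                       rank_correlations=correlations)


def focal_metabolites(ranking_room: pd.DataFrame,
                      ranking_het: pd.DataFrame,
                      reference_metabolite: str) -> list[str]:
    """The reference metabolite plus everything ranked above it by either method."""
    out = {reference_metabolite}
    for table in (ranking_room, ranking_het):
        ref_rows = table[table["metabolite"] == reference_metabolite]
        if ref_rows.empty:
            raise ContractError(
                f"{reference_metabolite!r} missing from a ranking table")
        ref_total = float(ref_rows["total"].iloc[0])
        out |= set(table[table["total"] < ref_total]["metabolite"])
    return sorted(out)
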