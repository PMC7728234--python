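"""Toy metabolic networks and brute-force oracles.

The module has two jobs.  First, it generates small stoichiometric networks
that emulate the features of a glucose-limited central carbon metabolism that
the pipeline exercises: a primary carbon source, a linear "glycolysis" chain,
a "TCA"-like cycle, an overflow branch excreting a by-product, an import
route that lets the by-product serve as sole carbon source, a biomass
reaction drawing several precursors, toy gene-protein-reaction rules, and toy
operon/regulon tables.  Second, it provides :func:`brute_force_min_change`,
an exhaustive change-set enumeration that independently computes the
minimal-flux-change distances that the ROOM and ROOM-het MILPs optimize, so
the optimizers can be validated without any external model.

What these toys deliberately do not emulate: cofactor/energy balancing,
elemental mass balance, realistic genome-scale redundancy.  They are exact
instances of the same mathematical problem class at a size where exhaustive
enumeration is possible.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from ._solver import feasible_point
from .exceptions import ContractError, CrossfeedError
from .fba_core import ChemostatEnvironment, FluxDistribution
from .model_io import (ROLE_BIOMASS, ROLE_EXCHANGE, ROLE_INTERNAL,
                       AnnotationTables, MetabolicModel, parse_gpr)

#: default flux capacity of toy reactions
TOY_CAP = 1000.0


# ---------------------------------------------------------------------------
# deterministic core fixture
# ---------------------------------------------------------------------------

def _build_model(mets, reactions, biomass_id) -> MetabolicModel:
    met_ids = list(mets)
    met_pos = {m: i for i, m in enumerate(met_ids)}
    rxn_ids, lbs, ubs, roles, gprs, subsystems = [], [], [], [], [], []
    rows, cols, vals = [], [], []
    for j, (rid, stoich, lb, ub, gpr, subsystem) in enumerate(reactions):
        rxn_ids.append(rid)
        lbs.append(lb)
        ubs.append(ub)
        gprs.append(parse_gpr(gpr))
        subsystems.append(subsystem)
        if rid == biomass_id:
            roles.append(ROLE_BIOMASS)
        elif rid.startswith(("EX_", "DM_", "SK_")):
            roles.append(ROLE_EXCHANGE)
        else:
            roles.append(ROLE_INTERNAL)
        for met, coef in stoich.items():
            rows.append(met_pos[met])
            cols.append(j)
            vals.append(float(coef))
    S = sp.csc_matrix((vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids)))
    model = MetabolicModel(
        metabolite_ids=met_ids, reaction_ids=rxn_ids, S=S,
        lb=np.array(lbs, float), ub=np.array(ubs, float),
        reaction_roles=roles, biomass_reaction_id=biomass_id,
        gpr=gprs, subsystems=subsystems)
    model.validate()
    return model


def make_core_fixture() -> MetabolicModel:
    """Deterministic ~26-reaction central-carbon toy network.

    Growth at D = 0.2 h^-1 on glucose is feasible; the network carries two
    excretable and re-importable by-products (an acetate-like overflow product
    ``ac`` off the hexose pool and a glycerol-like product ``gol`` off the
    pyruvate pool), a three-reaction futile cycle off the hexose pool, toy
    GPR rules, and subsystem labels.  Producer and consumer strain problems
    are feasible for both by-products.
    """
    mets = ["glc_e", "nh4_e", "co2_e", "ac_e", "gol_e",
            "g6p_c", "pyr_c", "accoa_c", "oaa_c", "cit_c", "akg_c",
            "nh4_c", "co2_c", "ac_c", "gol_c", "fut1_c", "fut2_c"]
    # (id, stoichiometry, lb, ub, gpr, subsystem)
    reactions = [
        ("EX_glc_e", {"glc_e": -1}, 0.0, TOY_CAP, "", "Exchange"),
        ("EX_nh4_e", {"nh4_e": -1}, 0.0, TOY_CAP, "", "Exchange"),
        ("EX_co2_e", {"co2_e": -1}, 0.0, TOY_CAP, "", "Exchange"),
        ("EX_ac_e", {"ac_e": -1}, 0.0, TOY_CAP, "", "Exchange"),
        ("EX_gol_e", {"gol_e": -1}, 0.0, TOY_CAP, "", "Exchange"),
        ("GLCpts", {"glc_e": -1, "g6p_c": 1}, 0.0, TOY_CAP,
         "g_ptsG and g_ptsH", "Transport"),
        ("NH4t", {"nh4_e": -1, "nh4_c": 1}, 0.0, TOY_CAP, "g_amtB", "Transport"),
        ("CO2t", {"co2_c": -1, "co2_e": 1}, -TOY_CAP, TOY_CAP, "", "Transport"),
        ("PYK", {"g6p_c": -1, "pyr_c": 2}, -TOY_CAP, TOY_CAP,
         "g_pykF or g_pykA", "Glycolysis"),
        ("PDH", {"pyr_c": -1, "accoa_c": 1, "co2_c": 1}, 0.0, TOY_CAP,
         "g_aceE and g_aceF and g_lpd", "Glycolysis"),
        ("CS", {"accoa_c": -1, "oaa_c": -1, "cit_c": 1}, 0.0, TOY_CAP,
         "g_gltA", "TCA"),
        ("CITDH", {"cit_c": -1, "akg_c": 1, "co2_c": 1}, 0.0, TOY_CAP,
         "g_icd", "TCA"),
        ("AKGDH", {"akg_c": -1, "oaa_c": 1, "co2_c": 1}, 0.0, TOY_CAP,
         "g_sucA and g_sucB", "TCA"),
        ("PPC", {"pyr_c": -1, "co2_c": -1, "oaa_c": 1}, 0.0, TOY_CAP,
         "g_ppc", "Anaplerotic"),
        ("ICL", {"accoa_c": -2, "oaa_c": 1}, 0.0, TOY_CAP,
         "g_aceA and g_aceB", "Glyoxylate shunt"),
        ("PCK", {"oaa_c": -1, "pyr_c": 1, "co2_c": 1}, 0.0, TOY_CAP,
         "g_pck", "Gluconeogenesis"),
        ("ACSYN", {"g6p_c": -1, "ac_c": 1}, 0.0, TOY_CAP,
         "g_pta or g_ackA", "Overflow"),
        ("ACt", {"ac_c": -1, "ac_e": 1}, -TOY_CAP, TOY_CAP,
         "g_actP", "Transport"),
        ("ACS", {"ac_c": -1, "accoa_c": 1, "co2_c": 1}, 0.0, TOY_CAP,
         "g_acs", "Overflow"),
        ("GOLSYN", {"pyr_c": -1, "gol_c": 1}, 0.0, TOY_CAP,
         "g_gpsA", "Overflow"),
        ("GOLt", {"gol_c": -1, "gol_e": 1}, -TOY_CAP, TOY_CAP,
         "g_glpF", "Transport"),
        ("GOLCAT", {"gol_c": -1, "pyr_c": 1}, 0.0, TOY_CAP,
         "g_glpK and g_glpD", "Overflow"),
        ("FUT1", {"g6p_c": -1, "fut1_c": 1}, 0.0, TOY_CAP, "g_fut1", "Futile"),
        ("FUT2", {"fut1_c": -1, "fut2_c": 1}, 0.0, TOY_CAP, "g_fut2", "Futile"),
        ("FUT3", {"fut2_c": -1, "g6p_c": 1}, 0.0, TOY_CAP, "g_fut3", "Futile"),
        ("BIOMASS", {"g6p_c": -0.5, "akg_c": -0.5, "nh4_c": -0.2},
         0.0, TOY_CAP, "", "Biomass"),
    ]
    return _build_model(mets, reactions, "BIOMASS")


def core_environment() -> ChemostatEnvironment:
    """Chemostat medium for the core fixture: glucose-limited, D = 0.2 h^-1."""
    return ChemostatEnvironment(
        dilution_rate=0.2, primary_carbon="EX_glc_e", uptake_cap=10.0,
        nonlimiting_inorganics=frozenset({"EX_nh4_e"}))


def core_annotations() -> AnnotationTables:
    """Toy operon/regulon tables matching the core fixture's GPR genes."""
    operons = {
        "g_ptsG": "ptsHI-crr", "g_ptsH": "ptsHI-crr",
        "g_aceE": "aceEF", "g_aceF": "aceEF", "g_lpd": "aceEF",
        "g_pykF": "pykF", "g_pykA": "pykA",
        "g_gltA": "gltA", "g_icd": "icd",
        "g_sucA": "sucAB", "g_sucB": "sucAB",
        "g_ppc": "ppc", "g_pck": "pck",
        "g_aceA": "aceBAK", "g_aceB": "aceBAK",
        "g_pta": "pta-ackA", "g_ackA": "pta-ackA",
        "g_acs": "acs", "g_actP": "acs",
        "g_gpsA": "gpsA", "g_glpF": "glpFK", "g_glpK": "glpFK",
        "g_glpD": "glpD", "g_amtB": "amtB",
        "g_fut1": "fut", "g_fut2": "fut", "g_fut3": "fut",
    }
    regulons = {
        "g_ptsG": {"crp"}, "g_ptsH": {"crp"},
        "g_aceE": {"pdhR"}, "g_aceF": {"pdhR"}, "g_lpd": {"pdhR", "fnr"},
        "g_pykF": {"fruR"}, "g_pykA": {"fruR"},
        "g_gltA": {"crp", "arcA"}, "g_icd": {"arcA"},
        "g_sucA": {"arcA"}, "g_sucB": {"arcA"},
        "g_aceA": {"iclR"}, "g_aceB": {"iclR"},
        "g_pta": {"fnr"}, "g_ackA": {"fnr"},
        "g_acs": {"crp"}, "g_actP": {"crp"},
        "g_gpsA": {"glpR"}, "g_glpF": {"glpR"}, "g_glpK": {"glpR"},
        "g_glpD": {"glpR"},
    }
    return AnnotationTables(
        gene_to_operon=dict(operons),
        gene_to_regulons={g: frozenset(s) for g, s in regulons.items()})


def make_futile_cycle_fixture() -> MetabolicModel:
    """Alias for the core fixture, whose FUT1-3 loop is a genuine futile cycle."""
    return make_core_fixture()


# ---------------------------------------------------------------------------
# random toy networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyNetworkSpec:
    """Parameters of a random toy network.

    ``n_internal`` counts internal reactions beyond the by-product machinery;
    the generated network always contains a feasible growth backbone
    (uptake -> chain -> biomass), one excretable/importable by-product per
    entry of ``by_products`` branching off an early chain metabolite, and,
    optionally, a futile cycle.  A fixed seed yields byte-identical output.
    """

    n_internal: int = 6
    by_products: tuple[str, ...] = ("bp1",)
    reversible_fraction: float = 0.3
    seed: int = 0
    include_futile_cycle: bool = False
    gpr_density: float = 1.0

    def __post_init__(self):
        if self.n_internal < 3:
            raise ContractError("n_internal must be >= 3")
        if not 0.0 <= self.reversible_fraction <= 1.0:
            raise ContractError("reversible_fraction must be in [0, 1]")


def make_toy_network(spec: ToyNetworkSpec) -> MetabolicModel:
    """Generate a random toy network guaranteed to support growth.

    The backbone is a linear chain S_e -> M1 -> ... -> Mk feeding a biomass
    reaction; extra internal reactions connect random chain metabolites and a
    configurable fraction of them are reversible.  Each by-product b gets a
    synthesis branch off M1, a reversible transporter, an exchange, and a
    catabolic route back into M2, so producer and consumer problems are both
    constructible.
    """
    rng = np.random.default_rng(spec.seed)
    n_chain = max(3, spec.n_internal - 1)
    chain = [f"m{i}_c" for i in range(1, n_chain + 1)]
    mets = ["s_e"] + chain
    gene_counter = itertools.count(1)

    def make_gpr() -> str:
        n = rng.poisson(spec.gpr_density)
        genes = [f"tg{next(gene_counter):03d}" for _ in range(n)]
        if not genes:
            return ""
        if len(genes) == 1:
            return genes[0]
        op = " and " if rng.random() < 0.5 else " or "
        return op.join(genes)

    reactions = [
        ("EX_s_e", {"s_e": -1}, 0.0, TOY_CAP, make_gpr(), "Exchange"),
        ("UPT", {"s_e": -1, chain[0]: 1}, 0.0, TOY_CAP, make_gpr(), "Transport"),
    ]
    for i in range(n_chain - 1):
        reactions.append((f"C{i + 1}", {chain[i]: -1, chain[i + 1]: 1},
                          0.0, TOY_CAP, make_gpr(), "Backbone"))
    # extra random internal reactions between distinct chain metabolites
    n_extra = max(0, spec.n_internal - n_chain)
    for x in range(n_extra):
        i, j = rng.choice(n_chain, size=2, replace=False)
        rev = rng.random() < spec.reversible_fraction
        reactions.append((f"X{x + 1}", {chain[i]: -1, chain[j]: 1},
                          -10.0 if rev else 0.0, TOY_CAP, make_gpr(), "Extra"))
    for b in spec.by_products:
        mets += [f"{b}_c", f"{b}_e"]
        reactions += [
            (f"{b.upper()}SYN", {chain[0]: -1, f"{b}_c": 1},
             0.0, TOY_CAP, make_gpr(), "Overflow"),
            (f"{b.upper()}t", {f"{b}_c": -1, f"{b}_e": 1},
             -TOY_CAP, TOY_CAP, make_gpr(), "Transport"),
            (f"{b.upper()}CAT", {f"{b}_c": -1, chain[1]: 1},
             0.0, TOY_CAP, make_gpr(), "Catabolism"),
            (f"EX_{b}_e", {f"{b}_e": -1}, 0.0, TOY_CAP, "", "Exchange"),
        ]
    if spec.include_futile_cycle:
        mets += ["fa_c", "fb_c"]
        reactions += [
            ("FUTA", {chain[0]: -1, "fa_c": 1}, 0.0, TOY_CAP, make_gpr(), "Futile"),
            ("FUTB", {"fa_c": -1, "fb_c": 1}, 0.0, TOY_CAP, make_gpr(), "Futile"),
            ("FUTC", {"fb_c": -1, chain[0]: 1}, 0.0, TOY_CAP, make_gpr(), "Futile"),
        ]
    reactions.append(("BIOMASS", {chain[-1]: -1.0}, 0.0, TOY_CAP, "", "Biomass"))
    model = _build_model(mets, reactions, "BIOMASS")
    env = toy_environment()
    from .fba_core import apply_environment  # local import avoids cycle at load
    lb, ub = apply_environment(model, env,
                               {model.biomass_reaction_id: (env.dilution_rate,
                                                            env.dilution_rate)})
    if feasible_point(model.S, np.zeros(model.n_metabolites), lb, ub) is None:
        raise CrossfeedError(
            f"toy network spec {spec} cannot host a feasible growth backbone")
    return model


def toy_environment(dilution_rate: float = 0.2,
                    uptake_cap: float = 10.0) -> ChemostatEnvironment:
    """Environment for generated toy networks (primary carbon ``EX_s_e``)."""
    return ChemostatEnvironment(dilution_rate=dilution_rate,
                                primary_carbon="EX_s_e",
                                uptake_cap=uptake_cap,
                                nonlimiting_inorganics=frozenset())


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_min_change(
    model: MetabolicModel,
    reference: FluxDistribution | None,
    evolved_lb: np.ndarray,
    evolved_ub: np.ndarray,
    beta: float,
    max_size: int = 4,
    ancestor_bounds: tuple[np.ndarray, np.ndarray] | None = None,
    counted_reactions: list[str] | None = None,
) -> int | None:
    """Exhaustively find the minimal number of flux changes, or None if it
    exceeds ``max_size``.

    Enumerates candidate change-sets F over the counted internal reactions in
    order of increasing size.  For a fixed reference (ROOM semantics) each F
    is tested by an LP restricted to |e_i - a_i| <= beta for every counted
    i outside F.  With ``ancestor_bounds`` instead of a reference (ROOM-het
    semantics) the LP carries joint variables (a, e) with each satisfying its
    own bound set plus the coupling |e_i - a_i| <= beta outside F.  The first
    feasible size is the oracle distance.  This deliberately shares only the
    LP solver, not the MILP formulation, with the optimizers it checks.
    """
    if (reference is None) == (ancestor_bounds is None):
        raise ContractError(
            "provide exactly one of reference (ROOM) or ancestor_bounds (het)")
    from .room_methods import _counted_indices  # shared index contract

    counted = _counted_indices(model, counted_reactions)
    evolved_lb = np.asarray(evolved_lb, float)
    evolved_ub = np.asarray(evolved_ub, float)
    m, r = model.n_metabolites, model.n_reactions

    if reference is not None:
        a = reference.values

        def feasible_with_unchanged(free: set[int]) -> bool:
            lb = evolved_lb.copy()
            ub = evolved_ub.copy()
            for i in counted:
                if i in free:
                    continue
                lb[i] = max(lb[i], a[i] - beta)
                ub[i] = min(ub[i], a[i] + beta)
            if np.any(lb > ub + 1e-12):
                return False
            return feasible_point(model.S, np.zeros(m), lb, ub) is not None
    else:
        la, ua = (np.asarray(b, float) for b in ancestor_bounds)
        Z = sp.csc_matrix((m, r))
        A_eq = sp.vstack([sp.hstack([model.S, Z]),
                          sp.hstack([Z, model.S])], format="csc")
        ident = sp.identity(r, format="csr")

        def feasible_with_unchanged(free: set[int]) -> bool:
            held = np.array([i for i in counted if i not in free], dtype=int)
            lo = np.concatenate([la, evolved_lb])
            hi = np.concatenate([ua, evolved_ub])
            if held.size:
                Ih = ident[held]
                A_ub = sp.vstack([sp.hstack([-Ih, Ih]),
                                  sp.hstack([Ih, -Ih])], format="csc")
                b_ub = np.full(2 * held.size, beta)
            else:
                A_ub = b_ub = None
            return feasible_point(A_eq, np.zeros(2 * m), lo, hi,
                                  A_ub=A_ub, b_ub=b_ub) is not None

    for size in range(0, max_size + 1):
        for combo in itertools.combinations(counted.tolist(), size):
            if feasible_with_unchanged(set(combo)):
                return size
    return None


# ---------------------------------------------------------------------------
# fixture emission (text formats only)
# ---------------------------------------------------------------------------

def write_fixture_files(out_dir: str | Path) -> dict[str, Path]:
    """Write the core fixture model (BiGG-style JSON) and annotation TSVs."""
    from .model_io import save_model

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model_path = out / "core_fixture.json"
    save_model(make_core_fixture(), model_path)
    tables = core_annotations()
    operon_path = out / "operons.tsv"
    with open(operon_path, "w") as fh:
        fh.write("gene\toperon\n")
        for gene, operon in sorted(tables.gene_to_operon.items()):
            fh.write(f"{gene}\t{operon}\n")
    regulon_path = out / "regulons.tsv"
    with open(regulon_path, "w") as fh:
        fh.write("gene\tregulon\n")
        for gene, regs in sorted(tables.gene_to_regulons.items()):
            for reg in sorted(regs):
                fh.write(f"{gene}\t{reg}\n")
    return {"model": model_path, "operons": operon_path, "regulons": regulon_path}
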