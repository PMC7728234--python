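"""Shared fixtures: the bundled toy network, its environment, and solved states.

Everything is generated programmatically; session scope keeps the LP/MILP
work per test run modest.
"""
from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

import crossfeed as cf
from crossfeed.model_io import MetabolicModel, parse_gpr


@pytest.fixture(scope="session")
def core_model() -> MetabolicModel:
    return cf.make_core_fixture()


@pytest.fixture(scope="session")
def core_env():
    return cf.core_environment()


@pytest.fixture(scope="session")
def core_ancestor(core_model, core_env):
    return cf.ancestral_state(core_model, core_env)


@pytest.fixture(scope="session")
def core_distances(core_model, core_env, core_ancestor):
    """ROOM producer+consumer results for both fixture by-products."""
    return cf.compute_distances(core_model, core_env, ["ac_e", "gol_e"],
                                method="room", ancestor=core_ancestor)


def build_tiny_model(reactions, mets, biomass_id="BIOMASS") -> MetabolicModel:
    """Hand-rolled tiny model builder for targeted LP/MILP tests.

    ``reactions`` is a list of (id, {met: coef}, lb, ub[, gpr]).
    """
    met_pos = {m: i for i, m in enumerate(mets)}
    rows, cols, vals = [], [], []
    ids, lbs, ubs, roles, gprs = [], [], [], [], []
    for j, rxn in enumerate(reactions):
        rid, stoich, lb, ub = rxn[:4]
        gpr = rxn[4] if len(rxn) > 4 else ""
        ids.append(rid)
        lbs.append(lb)
        ubs.append(ub)
        gprs.append(parse_gpr(gpr))
        if rid == biomass_id:
            roles.append("biomass")
        elif rid.startswith(("EX_", "DM_", "SK_")):
            roles.append("exchange")
        else:
            roles.append("internal")
        for met, coef in stoich.items():
            rows.append(met_pos[met])
            cols.append(j)
            vals.append(float(coef))
    S = sp.csc_matrix((vals, (rows, cols)), shape=(len(mets), len(ids)))
    model = MetabolicModel(
        metabolite_ids=list(mets), reaction_ids=ids, S=S,
        lb=np.array(lbs, float), ub=np.array(ubs, float),
        reaction_roles=roles, biomass_reaction_id=biomass_id, gpr=gprs)
    model.validate()
    return model


@pytest.fixture
def tiny_chain_model():
    """EX_a -> transport -> biomass, all capacities 10."""
    return build_tiny_model(
        [("EX_a_e", {"a_e": -1}, -10.0, 10.0),
         ("T", {"a_e": -1, "a_c": 1}, 0.0, 10.0),
         ("BIOMASS", {"a_c": -1}, 0.0, 10.0)],
        ["a_e", "a_c"])


@pytest.fixture
def tiny_env():
    return cf.ChemostatEnvironment(dilution_rate=0.2, primary_carbon="EX_a_e",
                                   uptake_cap=10.0)
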