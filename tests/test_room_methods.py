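"""ROOM / ROOM-het MILPs, MoMA, and flux-change classification."""
import numpy as np
import pytest

import crossfeed as cf
from crossfeed.exceptions import ContractError, InfeasibleError, SolverTimeoutError
from crossfeed.fba_core import FluxDistribution, apply_environment
from crossfeed.pipeline import StrainSpec, build_strain_constraints
from crossfeed.room_methods import (HetProblem, RoomProblem, classify_changes,
                                    moma, room, room_het)

from conftest import build_tiny_model


@pytest.fixture(scope="module")
def producer_problem(core_model, core_env, core_ancestor):
    overrides = build_strain_constraints(
        core_model, core_env,
        StrainSpec(role="producer", secondary_metabolite="ac_e"))
    return RoomProblem.from_overrides(core_model, core_env, core_ancestor,
                                      overrides)


class TestClassifyChanges:
    def test_identity_gives_empty_sets(self, core_ancestor):
        cls = classify_changes(core_ancestor, core_ancestor)
        assert cls.n_changed == 0

    def test_constructed_example(self):
        ids = ["r1", "r2", "r3"]
        a = FluxDistribution(ids, [0.0, 1.0, 2.0])
        e = FluxDistribution(ids, [1.0, 0.0, 2.5])
        cls = classify_changes(a, e, beta=0.001, activity_threshold=0.001)
        assert cls.turned_on == {"r1"}
        assert cls.turned_off == {"r2"}
        assert cls.magnitude_change == {"r3"}

    def test_matches_literal_reimplementation_on_random_vectors(self):
        rng = np.random.default_rng(7)
        ids = [f"r{i}" for i in range(60)]
        beta, thr = 0.001, 0.001
        for _ in range(20):
            av = rng.normal(0, 1, 60) * (rng.random(60) > 0.3)
            ev = av + rng.normal(0, 0.5, 60) * (rng.random(60) > 0.5)
            cls = classify_changes(FluxDistribution(ids, av),
                                   FluxDistribution(ids, ev),
                                   beta=beta, activity_threshold=thr, tol=0.0)
            changed = {r for r, x, y in zip(ids, av, ev) if abs(y - x) > beta}
            on = {r for r in changed
                  if abs(av[ids.index(r)]) <= thr and abs(ev[ids.index(r)]) > thr}
            off = {r for r in changed
                   if abs(av[ids.index(r)]) > thr and abs(ev[ids.index(r)]) <= thr}
            assert cls.changed == changed
            assert cls.turned_on == on
            assert cls.turned_off == off
            assert cls.magnitude_change == changed - on - off

    def test_partition_invariants(self, core_distances):
        for res in core_distances:
            cls = res.classification
            assert cls.turned_on.isdisjoint(cls.turned_off)
            assert cls.turned_on.isdisjoint(cls.magnitude_change)
            assert cls.turned_off.isdisjoint(cls.magnitude_change)
            assert res.distance == cls.n_changed

    def test_mismatched_reaction_sets_is_contract_error(self):
        a = FluxDistribution(["r1"], [0.0])
        e = FluxDistribution(["r2"], [0.0])
        with pytest.raises(ContractError):
            classify_changes(a, e)


class TestRoom:
    def test_reference_already_feasible_gives_zero(self, core_model, core_env,
                                                   core_ancestor):
        problem = RoomProblem.from_overrides(
            core_model, core_env, core_ancestor,
            {core_model.biomass_reaction_id: (0.2, 0.2)})
        res = room(core_model, problem)
        assert res.distance == 0

    def test_single_forced_flip_network(self):
        """Hand-built network where exactly one internal reaction must change."""
        model = build_tiny_model(
            [("EX_a_e", {"a_e": -1}, -10.0, 10.0),
             ("P1", {"a_e": -1, "x_c": 1}, 0.0, 10.0),
             ("P2", {"a_e": -1, "x_c": 1}, 0.0, 10.0),
             ("BIOMASS", {"x_c": -1}, 0.0, 10.0)],
            ["a_e", "x_c"])
        env = cf.ChemostatEnvironment(primary_carbon="EX_a_e", uptake_cap=10.0)
        ref = FluxDistribution(model.reaction_ids, [-1.0, 1.0, 0.0, 1.0])
        # doubled growth: raising either parallel route's flux suffices, and
        # exactly one internal reaction must change
        problem = RoomProblem.from_overrides(
            model, env, ref, {"BIOMASS": (2.0, 2.0)})
        res = room(model, problem)
        assert res.distance == 1
        assert res.changed_reactions in ({"P1"}, {"P2"})

    def test_fixture_producer_distance_is_three(self, core_model,
                                                producer_problem):
        res = room(core_model, producer_problem)
        assert res.distance == 3  # fixed by the subset-enumeration oracle
        assert res.evolved["EX_ac_e"] == pytest.approx(1.0, abs=1e-6)

    def test_unchanged_reactions_stay_within_beta(self, core_model,
                                                  producer_problem,
                                                  core_ancestor):
        res = room(core_model, producer_problem)
        beta = producer_problem.beta
        for rid in core_model.internal_reactions():
            if rid not in res.changed_reactions:
                assert abs(res.evolved[rid] - core_ancestor[rid]) <= beta + 1e-6

    def test_infeasible_evolved_constraints_raise(self, core_model, core_env,
                                                  core_ancestor):
        problem = RoomProblem.from_overrides(
            core_model, core_env, core_ancestor,
            {core_model.biomass_reaction_id: (0.2, 0.2),
             "EX_glc_e": (0.0, 0.0),
             "EX_ac_e": (0.0, 0.0)})
        with pytest.raises(InfeasibleError):
            room(core_model, problem)

    def test_beta_monotonicity(self, core_model, core_env, core_ancestor):
        """Distance is non-increasing in beta over the studied range."""
        overrides = build_strain_constraints(
            core_model, core_env,
            StrainSpec(role="consumer", secondary_metabolite="ac_e"))
        distances = []
        for beta in (0.0002, 0.001, 0.005):
            problem = RoomProblem.from_overrides(
                core_model, core_env, core_ancestor, overrides, beta=beta)
            distances.append(room(core_model, problem).distance)
        assert distances[0] >= distances[1] >= distances[2]
        assert distances[0] - distances[2] <= 2  # barely sensitive on the fixture

    def test_time_limit_raises_timeout_not_suboptimal(self, core_model,
                                                      core_env):
        overrides = build_strain_constraints(
            core_model, core_env,
            StrainSpec(role="consumer", secondary_metabolite="ac_e"))
        anc_ov = build_strain_constraints(core_model, core_env,
                                          StrainSpec(role="ancestor"),
                                          ancestor_glucose_cap=0.2)
        la, ua = apply_environment(core_model, core_env, anc_ov)
        le, ue = apply_environment(core_model, core_env, overrides)
        with pytest.raises(SolverTimeoutError):
            room_het(core_model, HetProblem(la, ua, le, ue), time_limit=1e-4)


class TestRoomHet:
    def test_identical_constraint_sets_give_zero(self, core_model, core_env):
        overrides = {core_model.biomass_reaction_id: (0.2, 0.2)}
        lb, ub = apply_environment(core_model, core_env, overrides)
        res = room_het(core_model, HetProblem(lb, ub, lb, ub))
        assert res.distance == 0

    def test_dominated_by_room_with_any_feasible_ancestor(
            self, core_model, core_env, core_ancestor, core_distances):
        """het distance <= ROOM distance for every fixture strain problem."""
        anc_ov = build_strain_constraints(
            core_model, core_env, StrainSpec(role="ancestor"),
            ancestor_glucose_cap=cf.minimal_glucose(core_model, core_env))
        la, ua = apply_environment(core_model, core_env, anc_ov)
        for res in core_distances:
            overrides = build_strain_constraints(
                core_model, core_env,
                StrainSpec(role=res.role, secondary_metabolite=res.metabolite))
            le, ue = apply_environment(core_model, core_env, overrides)
            het = room_het(core_model, HetProblem(la, ua, le, ue))
            assert het.distance <= res.distance

    def test_both_distributions_satisfy_their_constraints(self, core_model,
                                                          core_env):
        overrides = build_strain_constraints(
            core_model, core_env,
            StrainSpec(role="producer", secondary_metabolite="gol_e"))
        anc_ov = build_strain_constraints(core_model, core_env,
                                          StrainSpec(role="ancestor"),
                                          ancestor_glucose_cap=0.2)
        la, ua = apply_environment(core_model, core_env, anc_ov)
        le, ue = apply_environment(core_model, core_env, overrides)
        res = room_het(core_model, HetProblem(la, ua, le, ue))
        assert np.all(res.ancestor.values >= la - 1e-6)
        assert np.all(res.ancestor.values <= ua + 1e-6)
        assert res.evolved["EX_gol_e"] == pytest.approx(1.0, abs=1e-6)
        assert np.abs(core_model.S @ res.ancestor.values).max() <= 1e-6
        assert np.abs(core_model.S @ res.evolved.values).max() <= 1e-6


class TestMoma:
    def test_feasible_reference_is_returned_unchanged(self, core_model,
                                                      core_env, core_ancestor):
        lb, ub = apply_environment(
            core_model, core_env, {core_model.biomass_reaction_id: (0.2, 0.2)})
        e = moma(core_model, core_ancestor, lb, ub)
        assert e.provenance["objective_value"] == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(e.values, core_ancestor.values, atol=1e-4)

    def test_matches_kkt_projection_oracle(self, core_model, core_env,
                                           core_ancestor):
        """With one equality perturbation, MoMA is the Euclidean projection of
        the reference onto the feasible polytope.  On the face identified by
        the active bounds, that projection has a closed form: the KKT linear
        system of the equality-constrained restriction.  Solving it
        independently must reproduce the solver's answer."""
        t = 0.05
        lb, ub = apply_environment(core_model, core_env, {"EX_ac_e": (t, t)})
        e = moma(core_model, core_ancestor, lb, ub)
        n = core_model.n_reactions
        S = core_model.S.toarray()
        tol = 1e-7
        fixed = np.where((e.values <= lb + tol) | (e.values >= ub - tol)
                         | (lb == ub))[0]
        free = np.setdiff1d(np.arange(n), fixed)
        e_fixed = np.where(e.values[fixed] <= lb[fixed] + tol,
                           lb[fixed], ub[fixed])
        A = S[:, free]
        b = -S[:, fixed] @ e_fixed
        kkt = np.block([[np.eye(free.size), A.T],
                        [A, np.zeros((A.shape[0], A.shape[0]))]])
        rhs = np.concatenate([core_ancestor.values[free], b])
        sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
        oracle = np.empty(n)
        oracle[free] = sol[:free.size]
        oracle[fixed] = e_fixed
        assert np.all(oracle >= lb - 1e-6) and np.all(oracle <= ub + 1e-6)
        np.testing.assert_allclose(e.values, oracle, atol=1e-5)
        d = oracle - core_ancestor.values
        assert e.provenance["objective_value"] == pytest.approx(
            float(d @ d), abs=1e-7)

    def test_change_count_never_beats_room(self, core_model, core_env,
                                           core_ancestor):
        """MoMA's evolved flux is feasible for ROOM, so its change count is an
        upper bound on the ROOM distance; checked across random toy problems."""
        from crossfeed.synthetic_data import (ToyNetworkSpec, make_toy_network,
                                              toy_environment)
        for seed in range(6):
            model = make_toy_network(ToyNetworkSpec(n_internal=6, seed=seed))
            env = toy_environment()
            anc = cf.ancestral_state(model, env)
            overrides = build_strain_constraints(
                model, env, StrainSpec(role="producer",
                                       secondary_metabolite="bp1_e",
                                       excretion_rate=0.5))
            lb, ub = apply_environment(model, env, overrides)
            problem = RoomProblem(anc, lb, ub)
            d_room = room(model, problem).distance
            e = moma(model, anc, lb, ub)
            cls = classify_changes(anc, e, reactions=model.internal_reactions())
            assert cls.n_changed >= d_room

    def test_infeasible_constraints_raise(self, core_model, core_env,
                                          core_ancestor):
        lb, ub = apply_environment(
            core_model, core_env,
            {core_model.biomass_reaction_id: (0.2, 0.2),
             "EX_glc_e": (0.0, 0.0), "EX_ac_e": (0.0, 0.0)})
        with pytest.raises(InfeasibleError):
            moma(core_model, core_ancestor, lb, ub)
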