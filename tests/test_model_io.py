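"""Model loading, GPR parsing, round-trip serialization, annotations."""
import json

import numpy as np
import pytest

import crossfeed as cf
from crossfeed.exceptions import ContractError, ModelFormatError
from crossfeed.model_io import (detect_exchanges, gpr_to_string,
                                load_annotations, parse_gpr)


def _write_toy_json(path):
    doc = {
        "metabolites": [{"id": "a_e", "compartment": "e"},
                        {"id": "a_c", "compartment": "c"}],
        "reactions": [
            {"id": "EX_a_e", "metabolites": {"a_e": -1.0},
             "lower_bound": -10.0, "upper_bound": 10.0},
            {"id": "T", "metabolites": {"a_e": -1.0, "a_c": 1.0},
             "lower_bound": 0.0, "upper_bound": 10.0},
            {"id": "GROW", "metabolites": {"a_c": -1.0},
             "lower_bound": 0.0, "upper_bound": 10.0,
             "objective_coefficient": 1.0},
        ],
        "genes": [],
    }
    path.write_text(json.dumps(doc))
    return path


class TestLoadModel:
    def test_three_reaction_toy(self, tmp_path):
        """A minimal uptake -> convert -> biomass model parses to m=2, r=3."""
        model = cf.load_model(_write_toy_json(tmp_path / "toy.json"), "bigg_json")
        assert model.n_metabolites == 2
        assert model.n_reactions == 3
        assert model.biomass_reaction_id == "GROW"
        assert model.reaction_roles == ["exchange", "internal", "biomass"]

    def test_file_order_is_preserved(self, tmp_path):
        model = cf.load_model(_write_toy_json(tmp_path / "toy.json"), "bigg_json")
        assert model.reaction_ids == ["EX_a_e", "T", "GROW"]
        assert model.metabolite_ids == ["a_e", "a_c"]

    def test_round_trip_is_fixed_point(self, core_model, tmp_path):
        """load(serialize(M)) preserves every field, S/lb/ub bit-exactly."""
        p1 = tmp_path / "m1.json"
        cf.save_model(core_model, p1)
        m1 = cf.load_model(p1, "bigg_json")
        assert m1.reaction_ids == core_model.reaction_ids
        assert m1.metabolite_ids == core_model.metabolite_ids
        assert m1.reaction_roles == core_model.reaction_roles
        assert m1.biomass_reaction_id == core_model.biomass_reaction_id
        assert np.array_equal(m1.lb, core_model.lb)
        assert np.array_equal(m1.ub, core_model.ub)
        assert (m1.S != core_model.S).nnz == 0
        assert [r.genes for r in m1.gpr] == [r.genes for r in core_model.gpr]
        # serialize again: byte-identical files
        p2 = tmp_path / "m2.json"
        cf.save_model(m1, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_json_loader_agrees_with_cobra(self, core_model, tmp_path):
        """Independent reader (cobrapy) sees the same network."""
        cobra = pytest.importorskip("cobra")
        path = tmp_path / "m.json"
        cf.save_model(core_model, path)
        cm = cobra.io.load_json_model(str(path))
        assert [r.id for r in cm.reactions] == core_model.reaction_ids
        for rxn in cm.reactions:
            j = core_model.rxn_index(rxn.id)
            assert rxn.lower_bound == core_model.lb[j]
            assert rxn.upper_bound == core_model.ub[j]
            for met, coef in rxn.metabolites.items():
                i = core_model.met_index(met.id)
                assert core_model.S[i, j] == coef

    def test_missing_file_and_bad_dialect(self, tmp_path):
        with pytest.raises(ModelFormatError):
            cf.load_model(tmp_path / "nope.json", "bigg_json")
        with pytest.raises(ContractError):
            cf.load_model(_write_toy_json(tmp_path / "t.json"), "matlab")

    def test_parse_error_names_offending_element(self, tmp_path):
        doc = {"metabolites": [{"id": "x_c"}],
               "reactions": [{"id": "R1", "metabolites": {"ghost_c": 1.0},
                              "lower_bound": 0.0, "upper_bound": 1.0,
                              "objective_coefficient": 1.0}]}
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelFormatError, match="ghost_c"):
            cf.load_model(path, "bigg_json")

    def test_missing_biomass_is_model_error(self, tmp_path):
        doc = {"metabolites": [{"id": "a_e"}],
               "reactions": [{"id": "EX_a_e", "metabolites": {"a_e": -1.0},
                              "lower_bound": -1.0, "upper_bound": 1.0}]}
        path = tmp_path / "nobio.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelFormatError, match="biomass"):
            cf.load_model(path, "bigg_json")

    def test_sbml_dialect_round_trips_through_cobra(self, core_model, tmp_path):
        """SBML-FBC parsing (via libsbml) yields the same network as JSON."""
        cobra = pytest.importorskip("cobra")
        json_path = tmp_path / "m.json"
        cf.save_model(core_model, json_path)
        cm = cobra.io.load_json_model(str(json_path))
        sbml_path = tmp_path / "m.xml"
        cobra.io.write_sbml_model(cm, str(sbml_path))
        model = cf.load_model(sbml_path, "sbml_fbc")
        assert set(model.reaction_ids) == set(core_model.reaction_ids)
        for rid in core_model.reaction_ids:
            j1, j2 = model.rxn_index(rid), core_model.rxn_index(rid)
            assert model.lb[j1] == pytest.approx(core_model.lb[j2])
            assert model.ub[j1] == pytest.approx(core_model.ub[j2])


class TestGPR:
    @pytest.mark.parametrize("text,genes,kind", [
        ("b0001 and b0002", {"b0001", "b0002"}, "and"),
        ("", set(), "empty"),
        ("g1", {"g1"}, "gene"),
        ("(g1 or g2) and g3", {"g1", "g2", "g3"}, "and"),
        ("g1 or g2 and g3", {"g1", "g2", "g3"}, "or"),  # and binds tighter
    ])
    def test_parse(self, text, genes, kind):
        tree = parse_gpr(text)
        assert set(tree.genes) == genes
        assert tree.kind == kind

    @pytest.mark.parametrize("text", [
        "(g1 or g2", "g1 )", "g1 and", "and g1", "g1 or or g2"])
    def test_syntax_errors(self, text):
        with pytest.raises(ModelFormatError):
            parse_gpr(text)

    @pytest.mark.parametrize("text", [
        "(g1 or g2) and g3",
        "b0001 and b0002",
        "a or (b and c) or (d and (e or f))",
    ])
    def test_gene_sets_match_independent_parser(self, text):
        """Leaf sets agree with cobrapy's ast-based GPR parser."""
        cobra = pytest.importorskip("cobra")
        oracle = cobra.core.gene.GPR.from_string(text).genes
        assert set(parse_gpr(text).genes) == set(oracle)

    def test_string_round_trip(self):
        for text in ["(g1 or g2) and g3", "a and b and c", "x"]:
            tree = parse_gpr(text)
            assert parse_gpr(gpr_to_string(tree)).genes == tree.genes


class TestInvariants:
    def test_exchange_detection_matches_brute_force_scan(self, core_model):
        detected = set(detect_exchanges(core_model))
        assert detected == set(core_model.exchange_reactions())

    def test_validate_rejects_two_biomass(self, core_model):
        bad = cf.MetabolicModel(
            metabolite_ids=list(core_model.metabolite_ids),
            reaction_ids=list(core_model.reaction_ids),
            S=core_model.S, lb=core_model.lb, ub=core_model.ub,
            reaction_roles=["biomass" if r == "internal" else r
                            for r in core_model.reaction_roles],
            biomass_reaction_id=core_model.biomass_reaction_id)
        with pytest.raises(ModelFormatError):
            bad.validate()

    def test_validate_rejects_crossed_bounds(self, core_model):
        lb = core_model.lb.copy()
        lb[0] = core_model.ub[0] + 1.0
        bad = cf.MetabolicModel(
            metabolite_ids=list(core_model.metabolite_ids),
            reaction_ids=list(core_model.reaction_ids),
            S=core_model.S, lb=lb, ub=core_model.ub,
            reaction_roles=list(core_model.reaction_roles),
            biomass_reaction_id=core_model.biomass_reaction_id)
        with pytest.raises(ModelFormatError, match="lb > ub"):
            bad.validate()


class TestAnnotations:
    def test_three_row_operon_table(self, tmp_path):
        p = tmp_path / "op.tsv"
        p.write_text("gene\toperon\ng1\topA\ng2\topA\ng3\topB\n")
        tables = load_annotations(operon_path=p)
        assert len(tables.gene_to_operon) == 3
        assert tables.operon("g1") == "opA"
        assert tables.operon("unknown") is None

    def test_header_only_gives_empty_maps(self, tmp_path):
        p = tmp_path / "op.tsv"
        p.write_text("gene\toperon\n")
        tables = load_annotations(operon_path=p)
        assert tables.gene_to_operon == {}

    def test_duplicate_gene_is_error(self, tmp_path):
        p = tmp_path / "op.tsv"
        p.write_text("gene\toperon\ng1\topA\ng1\topB\n")
        with pytest.raises(ModelFormatError, match="duplicate"):
            load_annotations(operon_path=p)

    def test_malformed_row_reports_line_number(self, tmp_path):
        p = tmp_path / "ex.tsv"
        p.write_text("gene\tstrain\tchange\ng1\ts1\tup\ng2\ts1\tsideways\n")
        with pytest.raises(ModelFormatError, match="line 3"):
            load_annotations(expression_path=p)

    def test_regulon_rows_accumulate_per_gene(self, tmp_path):
        p = tmp_path / "reg.tsv"
        p.write_text("gene\tregulon\ng1\tcrp\ng1\tfnr\ng2\tcrp\n")
        tables = load_annotations(regulon_path=p)
        assert tables.regulons("g1") == {"crp", "fnr"}
        assert tables.regulons("missing") == frozenset()
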