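"""SBML round-trips, matrix construction, classification and summaries."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fluxscan import (
    MetabolicModel,
    Metabolite,
    Reaction,
    build_matrix,
    parse_formula,
    read_sbml,
    summarize,
    write_sbml,
)
from fluxscan.model import ModelValidationError, format_formula, steady_state_residual


def simple_model():
    m = MetabolicModel(id="mini")
    m.add_metabolite(Metabolite("A", compartment="cytosol", formula={"C": 1}))
    m.add_metabolite(Metabolite("B", compartment="cytosol", formula={"C": 1}))
    m.add_metabolite(Metabolite("x_B", compartment="external", formula={"C": 1},
                                is_external=True))
    m.add_reaction(Reaction("conv", {"A": -1, "B": 1}, reversible=False))
    m.add_reaction(Reaction("exp", {"B": -1, "x_B": 1}, reversible=True))
    m.categorize()
    return m


class TestFormulas:
    @pytest.mark.parametrize(
        "text, counts",
        [
            ("C51H98O6", {"C": 51, "H": 98, "O": 6}),
            ("CHO3", {"C": 1, "H": 1, "O": 3}),
            ("H", {"H": 1}),
            ("C21H36N7O16P3S", {"C": 21, "H": 36, "N": 7, "O": 16, "P": 3, "S": 1}),
            ("", {}),
        ],
    )
    def test_parse(self, text, counts):
        assert parse_formula(text) == counts

    @given(st.dictionaries(st.sampled_from(["C", "H", "O", "N", "P", "S", "Mg"]),
                           st.integers(min_value=1, max_value=200), min_size=1))
    @settings(max_examples=50, deadline=None)
    def test_roundtrip(self, counts):
        assert parse_formula(format_formula(counts)) == counts

    def test_bad_formula_rejected(self):
        with pytest.raises(ValueError):
            parse_formula("C51x")


class TestMatrix:
    def test_minimal_column(self):
        m = MetabolicModel()
        m.add_metabolite(Metabolite("A"))
        m.add_metabolite(Metabolite("B"))
        m.add_reaction(Reaction("r", {"A": -1, "B": 1}))
        sm = build_matrix(m)
        assert sm.shape == (2, 1)
        col = sm.matrix.toarray()[:, 0]
        assert dict(zip(sm.metabolite_ids, col)) == {"A": -1.0, "B": 1.0}

    def test_no_external_rows(self, toy_model):
        sm = build_matrix(toy_model)
        assert not any(mid.startswith("x_") for mid in sm.metabolite_ids)
        assert sm.shape[1] == len(toy_model.reactions)

    def test_residual_small_for_optimal_fluxes(self, toy_model, toy_results):
        for r in toy_results:
            assert steady_state_residual(toy_model, r.solution.flux) <= 1e-8


class TestClassification:
    def test_partition_covers_all_reactions(self, toy_model):
        s = summarize(toy_model)
        assert s.n_internal_reactions + s.n_transporters == s.n_reactions_total
        cats = [r.category for r in toy_model.reactions.values()]
        assert set(cats) <= {"internal", "transporter", "exchange"}

    def test_exchanges_touch_external(self, toy_model):
        for r in toy_model.reactions.values():
            touches_external = any(
                toy_model.metabolites[m].is_external for m in r.stoichiometry
            )
            assert (r.category == "exchange") == touches_external

    def test_empty_model_summary(self):
        s = summarize(MetabolicModel())
        assert s.n_reactions_total == 0
        assert s.n_internal_metabolites == 0
        assert s.per_compartment == {}
        assert "n_reactions_total\t0" in s.to_tsv()


class TestSBML:
    def test_roundtrip_preserves_model(self, toy_model, tmp_path):
        path = tmp_path / "toy.xml"
        write_sbml(toy_model, path)
        back = read_sbml(path)
        assert summarize(back).to_dict() == summarize(toy_model).to_dict()
        for rid, rxn in toy_model.reactions.items():
            other = back.reactions[rid]
            assert other.stoichiometry == rxn.stoichiometry
            assert other.reversible == rxn.reversible
            assert other.lower_bound == pytest.approx(rxn.lower_bound)
            assert other.upper_bound == pytest.approx(rxn.upper_bound)
            assert other.category == rxn.category
        for mid, met in toy_model.metabolites.items():
            assert back.metabolites[mid].is_external == met.is_external
            assert back.metabolites[mid].formula == met.formula
            assert back.metabolites[mid].compartment == met.compartment

    def test_roundtrip_idempotent_bytes(self, toy_model, tmp_path):
        p1, p2 = tmp_path / "a.xml", tmp_path / "b.xml"
        write_sbml(toy_model, p1)
        write_sbml(read_sbml(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_roles_resolved_from_ids(self, toy_model, tmp_path):
        path = tmp_path / "toy.xml"
        write_sbml(toy_model, path)
        back = read_sbml(path)
        for role in ("txTAG", "txHCO3", "txGlycerol", "txPhoton", "Carboxylase", "Oxygenase"):
            assert back.named_roles[role] == toy_model.named_roles[role]

    def test_zero_reaction_file(self, tmp_path):
        path = tmp_path / "empty.xml"
        path.write_text(
            '<?xml version="1.0" encoding="UTF-8"?>\n'
            '<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" '
            'level="3" version="1">\n'
            '<model id="nothing"><listOfCompartments>'
            '<compartment id="c" constant="true"/>'
            "</listOfCompartments></model></sbml>\n"
        )
        with pytest.warns(UserWarning):
            model = read_sbml(path)
        assert len(model.reactions) == 0

    def test_malformed_sbml_reports_line(self, tmp_path):
        path = tmp_path / "broken.xml"
        path.write_text("<sbml><model><unclosed></model>")
        with pytest.raises(ValueError, match="line"):
            read_sbml(path)

    def test_duplicate_reaction_id_rejected(self):
        m = simple_model()
        with pytest.raises(ModelValidationError):
            m.add_reaction(Reaction("conv", {"A": -1, "B": 1}))

    def test_unreadable_path_raises(self, toy_model, tmp_path):
        target = tmp_path / "nodir" / "deep" / "toy.xml"
        with pytest.raises(OSError):
            write_sbml(toy_model, target)
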