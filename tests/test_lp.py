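"""L1 flux minimization against the exact rational oracles."""

from fractions import Fraction

import pytest

from fluxscan import (
    CoupledCap,
    FluxConstraint,
    MetabolicModel,
    Metabolite,
    Reaction,
    STANDARD_CONDITIONS,
    enumerate_oracle,
    exact_minimum,
    minimize_total_flux,
)
from fluxscan.model import steady_state_residual


def chain_model(n=3):
    """x_in -> M1 -> ... -> M_{n-1} -> x_out as n irreversible reactions."""
    m = MetabolicModel()
    m.add_metabolite(Metabolite("x_in", is_external=True, compartment="external"))
    m.add_metabolite(Metabolite("x_out", is_external=True, compartment="external"))
    for i in range(1, n):
        m.add_metabolite(Metabolite(f"M{i}"))
    species = ["x_in"] + [f"M{i}" for i in range(1, n)] + ["x_out"]
    for i in range(n):
        m.add_reaction(Reaction(f"r{i}", {species[i]: -1, species[i + 1]: 1},
                                reversible=False))
    m.categorize()
    return m


class TestChainOracle:
    def test_forced_path_enumeration(self):
        m = chain_model(3)
        result = enumerate_oracle(m, [FluxConstraint("r2", "eq", 1.0)])
        assert result.status == "optimal"
        assert result.objective == Fraction(3)
        assert len(result.vertices) == 1
        assert result.vertices[0] == {"r0": 1, "r1": 1, "r2": 1}

    def test_solver_matches_enumeration(self):
        m = chain_model(4)
        cons = [FluxConstraint("r3", "eq", 2.0)]
        lp = minimize_total_flux(m, cons)
        ex = enumerate_oracle(m, cons)
        assert lp.status == "optimal"
        assert lp.objective == pytest.approx(float(ex.objective), abs=1e-9)

    def test_infeasible_constraints(self):
        m = chain_model(3)
        cons = [FluxConstraint("r0", "eq", 0.0), FluxConstraint("r2", "eq", 1.0)]
        assert enumerate_oracle(m, cons).status == "infeasible"
        assert minimize_total_flux(m, cons).status == "infeasible"
        assert exact_minimum(m, cons).status == "infeasible"

    def test_enumeration_refuses_large_systems(self, toy_model):
        with pytest.raises(ValueError, match="refuses"):
            enumerate_oracle(toy_model, [FluxConstraint("tx_TAG", "eq", 1.0)])

    def test_coupled_cap_respected_exactly(self):
        m = chain_model(3)
        cons = [FluxConstraint("r2", "eq", 1.0)]
        caps = [CoupledCap(("r0", "r1"), 1.5)]
        assert enumerate_oracle(m, cons, caps).status == "infeasible"
        assert minimize_total_flux(m, cons, caps).status == "infeasible"
        caps_ok = [CoupledCap(("r0", "r1"), 2.0)]
        assert enumerate_oracle(m, cons, caps_ok).objective == Fraction(3)


class TestContracts:
    def test_null_demand_gives_zero_flux(self, toy_model):
        sol = minimize_total_flux(toy_model, [FluxConstraint("tx_TAG", "eq", 0.0)])
        assert sol.status == "optimal"
        assert sol.objective == pytest.approx(0.0, abs=1e-9)
        assert sol.active_set == []

    def test_conflicting_equalities_rejected_before_solving(self, toy_model):
        cons = [FluxConstraint("tx_TAG", "eq", 1.0), FluxConstraint("tx_TAG", "eq", 2.0)]
        with pytest.raises(ValueError, match="conflicting"):
            minimize_total_flux(toy_model, cons)

    def test_unknown_reaction_rejected(self, toy_model):
        with pytest.raises(KeyError):
            minimize_total_flux(toy_model, [FluxConstraint("nope", "eq", 1.0)])

    def test_objective_equals_total_absolute_flux(self, toy_results):
        for r in toy_results:
            total = sum(abs(v) for v in r.solution.flux.values())
            assert r.solution.objective == pytest.approx(total, abs=1e-9)

    def test_solution_satisfies_steady_state_and_constraints(self, toy_model, toy_results):
        for r in toy_results:
            assert steady_state_residual(toy_model, r.solution.flux) <= 1e-8
            assert r.solution.flux["tx_TAG"] == pytest.approx(1.0, abs=1e-8)


class TestConvexityProperties:
    def test_monotone_under_tightening(self, toy_model):
        """Adding a constraint never decreases the optimum; the ±BIC/±GLY
        chain is a special case of this ordering."""
        base = [FluxConstraint("tx_TAG", "eq", 1.0)]
        close_hco3 = base + [FluxConstraint("tx_HCO3", "eq", 0.0)]
        close_both = close_hco3 + [FluxConstraint("tx_Glycerol", "eq", 0.0)]
        objs = [minimize_total_flux(toy_model, c).objective
                for c in (base, close_hco3, close_both)]
        assert objs[0] <= objs[1] + 1e-9
        assert objs[1] <= objs[2] + 1e-9

    @pytest.mark.parametrize("demand", [0.5, 2.0])
    def test_scale_equivariance_without_caps(self, toy_model, demand):
        """With no active caps the LP is positively homogeneous: scaling the
        demand scales the objective exactly."""
        unit = minimize_total_flux(toy_model, [FluxConstraint("tx_TAG", "eq", 1.0)])
        scaled = minimize_total_flux(toy_model, [FluxConstraint("tx_TAG", "eq", demand)])
        assert scaled.objective == pytest.approx(demand * unit.objective, rel=1e-7)


class TestLexicographicRefinement:
    def test_refinement_keeps_objective_and_is_deterministic(self, toy_model):
        cons = STANDARD_CONDITIONS[0].constraints(toy_model)
        plain = minimize_total_flux(toy_model, cons)
        ref1 = minimize_total_flux(toy_model, cons, lexicographic=True)
        ref2 = minimize_total_flux(toy_model, cons, lexicographic=True)
        assert ref1.objective == pytest.approx(plain.objective, rel=1e-7)
        for rid in toy_model.reactions:
            assert ref1.flux[rid] == pytest.approx(ref2.flux[rid], abs=1e-7)
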