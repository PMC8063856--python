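"""Conservation checks for metabolic models.

Three audits, matching the validation level expected of a curated
genome-scale reconstruction:

* per-reaction elemental balance from metabolite formulas (exact rational
  arithmetic; exchange reactions are the system boundary and exempt);
* a mass-conservation ("leak") test: with all exchanges closed, no boundary
  transporter can sustain nonzero export at steady state;
* an energy-conservation test: with all exchanges closed, an ATP-hydrolysis
  drain cannot sustain nonzero flux (no energy-generating cycles).

The LP-based tests return a witness flux vector on failure; the witness
itself satisfies the steady-state constraint used in the test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import ELEMENTS, MetabolicModel, Reaction, build_matrix

#: pass/fail tolerance for the conservation LPs (double-precision noise floor,
#: relative to the default bound magnitude)
CONSERVATION_TOL = 1e-9


@dataclass
class BalanceReport:
    """Elemental audit of every non-exchange reaction."""

    imbalances: dict[str, dict[str, Fraction]]  # reaction -> element -> net
    unbalanced: list[tuple[str, list[str]]]  # (reaction, offending elements)
    skipped: list[str]  # reactions with missing formulas
    elements: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.unbalanced


@dataclass
class ConservationTest:
    passed: bool
    witness: dict[str, float] | None = None
    tested: list[str] = field(default_factory=list)


@dataclass
class ConservationReport:
    leak_test: ConservationTest | None = None
    energy_test: ConservationTest | None = None


def atom_balance(
    model: MetabolicModel, elements: Sequence[str] = ELEMENTS
) -> BalanceReport:
    """Net element count of each non-exchange reaction (zero iff balanced).

    A reaction involving any metabolite with no formula annotation is
    reported as skipped rather than judged.  Imbalances are exact rationals:
    scaling a reaction by k scales its imbalance by k, so balanced stays
    balanced under rescaling.
    """
    imbalances: dict[str, dict[str, Fraction]] = {}
    unbalanced: list[tuple[str, list[str]]] = []
    skipped: list[str] = []
    for rxn in model.reactions.values():
        if rxn.category == "exchange":
            continue
        mets = [model.metabolites[m] for m in rxn.stoichiometry]
        if any(not m.formula for m in mets):
            skipped.append(rxn.id)
            continue
        net: dict[str, Fraction] = {}
        for mid, coeff in rxn.stoichiometry.items():
            formula = model.metabolites[mid].formula
            for element in elements:
                count = formula.get(element, 0)
                if count:
                    net[element] = net.get(element, Fraction(0)) + coeff * count
        net = {e: v for e, v in net.items() if v != 0}
        imbalances[rxn.id] = net
        if net:
            unbalanced.append((rxn.id, sorted(net)))
    return BalanceReport(
        imbalances=imbalances,
        unbalanced=unbalanced,
        skipped=skipped,
        elements=tuple(elements),
    )


def _closed_exchange_bounds(model: MetabolicModel, keep_open: str | None = None):
    """Variable bounds with every exchange reaction fixed to zero flux
    (except ``keep_open``)."""
    bounds = []
    for rxn in model.reactions.values():
        if rxn.category == "exchange" and rxn.id != keep_open:
            bounds.append((0.0, 0.0))
        else:
            bounds.append((rxn.lower_bound, rxn.upper_bound))
    return bounds


def _maximize_reaction(model: MetabolicModel, target: str, sense: float, bounds):
    """max sense * v_target s.t. Nv = 0 and bounds; returns (value, flux dict)."""
    sm = build_matrix(model)
    n = len(sm.reaction_ids)
    c = np.zeros(n)
    j = sm.reaction_ids.index(target)
    c[j] = -sense  # linprog minimizes
    res = linprog(
        c,
        A_eq=sm.matrix,
        b_eq=np.zeros(sm.matrix.shape[0]),
        bounds=bounds,
        method="highs",
    )
    if res.status == 3:  # unbounded: re-solve with a box to extract a direction
        boxed = [(max(lo, -1e6), min(hi, 1e6)) for lo, hi in bounds]
        res = linprog(c, A_eq=sm.matrix, b_eq=np.zeros(sm.matrix.shape[0]),
                      bounds=boxed, method="highs")
        if res.status != 0:
            return float("inf"), {}
        flux = dict(zip(sm.reaction_ids, res.x))
        return float("inf"), flux
    if res.status != 0:
        return 0.0, {}
    flux = dict(zip(sm.reaction_ids, res.x))
    return float(sense * res.x[j]), flux


def leak_test(model: MetabolicModel, tol: float | None = None) -> ConservationTest:
    """Mass-conservation check.

    With all other exchange reactions closed, each exchange reaction is asked
    to export its external metabolite(s) at steady state; any achievable
    nonzero rate means the network creates matter from nothing.
    """
    if tol is None:
        tol = CONSERVATION_TOL * max(
            1.0, max((abs(r.upper_bound) for r in model.reactions.values()), default=1.0)
        )
    tested = []
    for rxn in model.reactions.values():
        if rxn.category != "exchange":
            continue
        tested.append(rxn.id)
        bounds = _closed_exchange_bounds(model, keep_open=rxn.id)
        # only the direction(s) in which this exchange PRODUCES an external
        # metabolite are leaks; a pure import (e.g. a massless photon feed)
        # is not a mass source
        senses = set()
        for mid, coeff in rxn.stoichiometry.items():
            if model.metabolites[mid].is_external:
                senses.add(1.0 if coeff > 0 else -1.0)
        for sense in sorted(senses):
            value, flux = _maximize_reaction(model, rxn.id, sense, bounds)
            if value > tol:
                return ConservationTest(passed=False, witness=flux, tested=tested)
    return ConservationTest(passed=True, tested=tested)


def atp_drain_reaction(
    atp: str, adp: str, pi: str, h2o: str, h: str, rid: str = "ATPDrain"
) -> Reaction:
    """ATP + H2O -> ADP + Pi + H, the canonical energy-dissipation drain."""
    return Reaction(
        id=rid,
        stoichiometry={atp: Fraction(-1), h2o: Fraction(-1),
                       adp: Fraction(1), pi: Fraction(1), h: Fraction(1)},
        reversible=False,
    )


def energy_test(
    model: MetabolicModel, energy_currency: str, tol: float | None = None
) -> ConservationTest:
    """Energy-conservation check.

    ``energy_currency`` names a hydrolysis-style drain reaction already in
    the model (see :func:`atp_drain_reaction`).  With all exchanges closed,
    any sustainable drain flux exposes an energy-generating cycle, returned
    as the witness.
    """
    if energy_currency not in model.reactions:
        raise KeyError(f"energy drain reaction {energy_currency!r} not in model")
    if tol is None:
        tol = CONSERVATION_TOL * max(
            1.0, max((abs(r.upper_bound) for r in model.reactions.values()), default=1.0)
        )
    bounds = _closed_exchange_bounds(model)
    value, flux = _maximize_reaction(model, energy_currency, +1.0, bounds)
    if value > tol:
        return ConservationTest(passed=False, witness=flux, tested=[energy_currency])
    return ConservationTest(passed=True, tested=[energy_currency])


def validate_model(
    model: MetabolicModel,
    elements: Sequence[str] = ELEMENTS,
    energy_drain: str | None = None,
) -> tuple[BalanceReport, ConservationReport]:
    """Run the full validation battery.

    If ``energy_drain`` is None, a drain is synthesized automatically when
    cytosolic ATP/ADP/Pi/H2O/H+ species can be identified by name.
    """
    balance = atom_balance(model, elements)
    report = ConservationReport()
    report.leak_test = leak_test(model)

    work = model
    drain_id = energy_drain
    if drain_id is None:
        ids = _find_energy_species(model)
        if ids is not None:
            work = model.copy()
            drain_id = "ATPDrain__validation"
            work.add_reaction(atp_drain_reaction(*ids, rid=drain_id))
            work.categorize()
    if drain_id is not None:
        report.energy_test = energy_test(work, drain_id)
    return balance, report


def _find_energy_species(model: MetabolicModel):
    """Best-effort lookup of one compartment's ATP/ADP/Pi/H2O/H+ by name."""
    by_name: dict[tuple[str, str], str] = {}
    for met in model.metabolites.values():
        if met.is_external:
            continue
        by_name[(met.name.upper(), met.compartment)] = met.id
    for comp in sorted({m.compartment for m in model.metabolites.values() if not m.is_external}):
        names = []
        for want in ("ATP", "ADP", "PI", "H2O", "H"):
            found = by_name.get((want, comp))
            if found is None and want == "PI":
                found = by_name.get(("PHOSPHATE", comp)) or by_name.get(("ORTHOPHOSPHATE", comp))
            if found is None and want == "H2O":
                found = by_name.get(("WATER", comp))
            if found is None and want == "H":
                found = by_name.get(("PROTON", comp))
            names.append(found)
        if all(n is not None for n in names):
            return tuple(names)
    return None
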