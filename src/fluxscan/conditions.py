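"""Four-condition analysis: TAG production with and without bicarbonate
and glycerol.

For one unit of TAG demand the L1-minimal flux distribution is computed
under the four transporter regimes

    +BIC+GLY   both HCO3 and glycerol exchanges open (mixotrophic + HCO3)
    -BIC+GLY   HCO3 exchange fixed to zero
    +BIC-GLY   glycerol exchange fixed to zero (phototrophic + HCO3)
    -BIC-GLY   both fixed to zero

and summarized as (i) objective value and active-reaction count, (ii) the
net stoichiometry of the solution — per-external-metabolite net
consumption (negative) or production (positive) — and (iii) elemental
audits of that net exchange.  The photon transporter is left free by
default: it participates in the minimized total flux, which is what makes
light demand an output that differs between conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .lp import CoupledCap, FluxConstraint, FluxSolution, minimize_total_flux
from .model import MetabolicModel

#: net fluxes below this magnitude are omitted from net-stoichiometry tables
OMISSION_THRESHOLD = 1e-7


@dataclass(frozen=True)
class ConditionSpec:
    """One transporter regime plus the TAG demand."""

    name: str
    tag_demand: float = 1.0
    hco3_open: bool = True
    glycerol_open: bool = True
    photon_bound: float | None = None  # None = photon flux free (minimized)

    def constraints(self, model: MetabolicModel) -> list[FluxConstraint]:
        cons = [FluxConstraint(model.role("txTAG"), "eq", self.tag_demand)]
        if not self.hco3_open:
            cons.append(FluxConstraint(model.role("txHCO3"), "eq", 0.0))
        if not self.glycerol_open:
            cons.append(FluxConstraint(model.role("txGlycerol"), "eq", 0.0))
        if self.photon_bound is not None:
            cons.append(FluxConstraint(model.role("txPhoton"), "eq", self.photon_bound))
        return cons


STANDARD_CONDITIONS: tuple[ConditionSpec, ...] = (
    ConditionSpec("+BIC+GLY", hco3_open=True, glycerol_open=True),
    ConditionSpec("-BIC+GLY", hco3_open=False, glycerol_open=True),
    ConditionSpec("+BIC-GLY", hco3_open=True, glycerol_open=False),
    ConditionSpec("-BIC-GLY", hco3_open=False, glycerol_open=False),
)


def run_condition(
    model: MetabolicModel,
    spec: ConditionSpec,
    caps: Sequence[CoupledCap] = (),
    lexicographic: bool = False,
) -> FluxSolution:
    """Solve the flux-minimization LP under one condition."""
    return minimize_total_flux(
        model, spec.constraints(model), caps=caps, lexicographic=lexicographic
    )


def net_stoichiometry(
    solution: FluxSolution,
    model: MetabolicModel,
    threshold: float = OMISSION_THRESHOLD,
) -> dict[str, float]:
    """Net external-metabolite turnover of a solution.

    Computed purely from exchange-reaction fluxes: for each external
    metabolite, the sum of (coefficient x flux) over exchange reactions.
    Negative = net consumed, positive = net produced.  Entries below
    ``threshold`` in magnitude are omitted.
    """
    net: dict[str, float] = {}
    for rxn in model.reactions.values():
        if rxn.category != "exchange":
            continue
        v = solution.flux.get(rxn.id, 0.0)
        if v == 0.0:
            continue
        for mid, coeff in rxn.stoichiometry.items():
            if model.metabolites[mid].is_external:
                net[mid] = net.get(mid, 0.0) + float(coeff) * v
    return {m: x for m, x in net.items() if abs(x) > threshold}


def element_audit(
    net: Mapping[str, float],
    model: MetabolicModel,
    elements: Sequence[str] = ("C", "H", "O"),
) -> dict[str, float]:
    """Per-element sum of (net flux x formula count) over external metabolites.

    For every element balanced reaction-by-reaction in the model this is
    zero up to solver noise — conservation at the boundary is a theorem
    given per-reaction balance, so a nonzero audit flags either an
    unbalanced reaction or a solver artifact.
    """
    totals = {e: 0.0 for e in elements}
    for mid, v in net.items():
        formula = model.metabolites[mid].formula
        for e in elements:
            totals[e] += formula.get(e, 0) * v
    return totals


def carbon_into_tag(
    net: Mapping[str, float], model: MetabolicModel, tag_demand: float = 1.0
) -> float:
    """Total carbon delivered per unit TAG: minus the carbon-weighted net of
    all external metabolites other than TAG itself (consumption is negative,
    so a consumed C3 substrate contributes +3 per unit)."""
    tag_rxn = model.reactions[model.role("txTAG")]
    tag_mets = {m for m in tag_rxn.stoichiometry if model.metabolites[m].is_external}
    total = 0.0
    for mid, v in net.items():
        if mid in tag_mets:
            continue
        total -= model.metabolites[mid].formula.get("C", 0) * v
    return total / tag_demand


#: role-style regex patterns for the qualitative pathway flags
ROUTE_PATTERNS: dict[str, str] = {
    "glycerol_kinase_active": r"(?i)glycerol.?kinase|^GK$|GLYKIN",
    "g3p_dehydrogenase_active": r"(?i)g3p.?dehydrogenase|glycerol.?3.?phosphate.?dehydrogenase|G3PDH",
    "pep_pyr_carboxylase_active": r"(?i)(PEP|pyruvate).?carboxylase(?!.?kinase)",
    "photorespiration_active": r"(?i)oxygenase|glycolate.?dehydrogenase",
    "glyoxylate_shunt_active": r"(?i)malate.?synthase|isocitrate.?lyase",
}


def route_report(
    solution: FluxSolution,
    model: MetabolicModel,
    patterns: Mapping[str, str] | None = None,
) -> dict[str, bool | None]:
    """Qualitative activity flags for the named pathway routes.

    A flag is True iff some reaction matching the route's pattern carries
    flux above the support threshold; None when no reaction matches
    (pattern unresolved on this model).
    """
    import re

    pats = dict(ROUTE_PATTERNS)
    if patterns:
        pats.update(patterns)
    flags: dict[str, bool | None] = {}
    for flag, pattern in pats.items():
        rx = re.compile(pattern)
        hits = [rid for rid in model.reactions if rx.search(rid)]
        if not hits:
            flags[flag] = None
            continue
        flags[flag] = any(
            abs(solution.flux.get(rid, 0.0)) > solution.support_threshold for rid in hits
        )
    return flags


@dataclass
class ConditionResult:
    spec: ConditionSpec
    solution: FluxSolution
    net: dict[str, float]
    audit: dict[str, float]
    routes: dict[str, bool | None]


def condition_table(
    model: MetabolicModel,
    specs: Iterable[ConditionSpec] = STANDARD_CONDITIONS,
    lexicographic: bool = False,
    audit_elements: Sequence[str] = ("C", "H", "O"),
) -> list[ConditionResult]:
    """Run every condition; infeasible conditions are reported, not dropped."""
    results = []
    for spec in specs:
        sol = run_condition(model, spec, lexicographic=lexicographic)
        if sol.status == "optimal":
            net = net_stoichiometry(sol, model)
            audit = element_audit(net, model, audit_elements)
            routes = route_report(sol, model)
        else:
            net, audit, routes = {}, {}, {}
        results.append(ConditionResult(spec, sol, net, audit, routes))
    return results


def objective_frame(results: Sequence[ConditionResult]) -> pd.DataFrame:
    """Objective value and active-reaction count per condition (columns)."""
    data = {
        r.spec.name: {
            "objective": r.solution.objective,
            "n_reactions": len(r.solution.active_set) if r.solution.status == "optimal" else None,
            "status": r.solution.status,
        }
        for r in results
    }
    return pd.DataFrame(data)


def net_stoichiometry_frame(results: Sequence[ConditionResult]) -> pd.DataFrame:
    """External metabolites x conditions, net consumption negative."""
    mets: list[str] = []
    for r in results:
        for m in r.net:
            if m not in mets:
                mets.append(m)
    data = {r.spec.name: {m: r.net.get(m, 0.0) for m in mets} for r in results}
    return pd.DataFrame(data, index=mets)
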