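"""Core model types and SBML I/O.

A metabolic model is a set of metabolites partitioned into subcellular
compartments plus an ordered set of stoichiometric reactions.  Metabolites
marked *external* form the system boundary: they are excluded from the
steady-state balance, so any reaction touching one is an *exchange*
reaction and its flux contributes to the net stoichiometry of a solution.
Reactions spanning two compartments are *transporters*; everything else is
*internal*.

Stoichiometric coefficients are stored as exact rationals
(:class:`fractions.Fraction`) and only converted to floats at the LP
interface, which keeps elemental audits and the exact test oracle free of
rounding error.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

logger = logging.getLogger("fluxscan")

#: Default magnitude used for reactions whose bounds the source file leaves open.
DEFAULT_BOUND = 1.0e5

#: Id-prefix convention marking boundary species (ScrumPy-derived models).
EXTERNAL_PREFIX = "x_"

#: Elements tracked by default in formulas and balance audits.
ELEMENTS = ("C", "H", "O", "N", "P", "S", "Mg")

#: Named reaction roles the analysis needs, resolved by regex against reaction ids.
DEFAULT_ROLE_PATTERNS: dict[str, str] = {
    "txTAG": r"(?i)^tx_?TAG$|txTAG",
    "txHCO3": r"(?i)^tx_?HCO3$|txHCO3",
    "txGlycerol": r"(?i)^tx_?Glycerol$|txGLYCEROL|txGlycerol",
    "txPhoton": r"(?i)^tx_?Photon$|txPhoton|Photon_tx",
    "Carboxylase": r"(?i)^(?!.*(PEP|PYR|pyruvate|acetyl)).*carboxylase",
    "Oxygenase": r"(?i)^(?!.*mono).*oxygenase",
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a chemical formula string such as ``C51H98O6`` into an element map."""
    if not formula:
        return {}
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = match.end()
        element, digits = match.groups()
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def format_formula(counts: Mapping[str, int]) -> str:
    """Inverse of :func:`parse_formula` (Hill-ish deterministic ordering)."""
    order = sorted(counts, key=lambda e: (e != "C", e != "H", e))
    return "".join(f"{e}{counts[e] if counts[e] != 1 else ''}" for e in order if counts[e])


@dataclass
class Metabolite:
    """A chemical species localized to one compartment.

    ``is_external`` marks boundary species: they are dropped from the
    steady-state balance and correspond to the ``x_``-prefixed rows of a
    net-stoichiometry table.
    """

    id: str
    name: str = ""
    compartment: str = "cytosol"
    formula: dict[str, int] = field(default_factory=dict)
    charge: int | None = None
    is_external: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            self.name = self.id
        for element, count in self.formula.items():
            if not (isinstance(count, int) and count >= 0):
                raise ValueError(
                    f"metabolite {self.id}: element count {element}={count!r} "
                    "must be a non-negative integer"
                )


def _as_fraction(value) -> Fraction:
    if isinstance(value, Fraction):
        return value
    if isinstance(value, float):
        # SBML stores doubles; recover the small rational the model meant.
        return Fraction(value).limit_denominator(10**9)
    return Fraction(value)


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds.

    ``stoichiometry`` maps metabolite ids to signed rational coefficients
    (negative = consumed).  ``category`` is one of ``internal``,
    ``transporter`` (spans two compartments) or ``exchange`` (touches an
    external metabolite).
    """

    id: str
    stoichiometry: dict[str, Fraction]
    reversible: bool = True
    lower_bound: float | None = None
    upper_bound: float | None = None
    category: str = "internal"
    name: str = ""

    def __post_init__(self) -> None:
        if not self.stoichiometry or all(c == 0 for c in self.stoichiometry.values()):
            raise ValueError(f"reaction {self.id} has no nonzero coefficient")
        self.stoichiometry = {m: _as_fraction(c) for m, c in self.stoichiometry.items() if c != 0}
        if self.lower_bound is None:
            self.lower_bound = -DEFAULT_BOUND if self.reversible else 0.0
        if self.upper_bound is None:
            self.upper_bound = DEFAULT_BOUND
        if self.lower_bound > self.upper_bound:
            raise ValueError(f"reaction {self.id}: lower bound exceeds upper bound")
        if not self.reversible and self.lower_bound < 0:
            raise ValueError(f"reaction {self.id}: irreversible but lower bound < 0")
        if not self.name:
            self.name = self.id


class ModelValidationError(ValueError):
    """Structural problem in a model (duplicate ids, dangling references...)."""


@dataclass
class ModelSummary:
    """Deterministic counts describing a model, in the partition used for GSMs:
    internal (enzymatic) reactions vs transporters (exchange + inter-compartment,
    the flat total being their sum), and internal vs external metabolites."""

    n_reactions_total: int
    n_internal_reactions: int
    n_transporters: int
    n_exchanges: int
    n_internal_metabolites: int
    n_external_metabolites: int
    per_compartment: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "n_reactions_total": self.n_reactions_total,
            "n_internal_reactions": self.n_internal_reactions,
            "n_transporters": self.n_transporters,
            "n_exchanges": self.n_exchanges,
            "n_internal_metabolites": self.n_internal_metabolites,
            "n_external_metabolites": self.n_external_metabolites,
            "per_compartment": dict(self.per_compartment),
        }

    def to_tsv(self) -> str:
        flat = self.to_dict()
        per_comp = flat.pop("per_compartment")
        for comp, n in sorted(per_comp.items()):
            flat[f"n_metabolites_{comp}"] = n
        lines = ["field\tvalue"] + [f"{k}\t{v}" for k, v in flat.items()]
        return "\n".join(lines) + "\n"


@dataclass
class MetabolicModel:
    """Metabolites + ordered reactions + named reaction roles."""

    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    named_roles: dict[str, str] = field(default_factory=dict)
    id: str = "model"

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelValidationError(f"duplicate metabolite id {met.id}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelValidationError(f"duplicate reaction id {rxn.id}")
        for met_id in rxn.stoichiometry:
            if met_id not in self.metabolites:
                raise ModelValidationError(
                    f"reaction {rxn.id} references unknown metabolite {met_id}"
                )
        self.reactions[rxn.id] = rxn

    # -- classification ----------------------------------------------------

    def categorize(self) -> None:
        """(Re)assign reaction categories from the current metabolite flags."""
        for rxn in self.reactions.values():
            mets = [self.metabolites[m] for m in rxn.stoichiometry]
            if any(m.is_external for m in mets):
                rxn.category = "exchange"
            elif len({m.compartment for m in mets}) > 1:
                rxn.category = "transporter"
            else:
                rxn.category = "internal"

    @property
    def external_metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites.values() if m.is_external]

    @property
    def internal_metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites.values() if not m.is_external]

    @property
    def exchange_reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions.values() if r.category == "exchange"]

    def role(self, name: str) -> str:
        try:
            return self.named_roles[name]
        except KeyError:
            raise KeyError(
                f"role {name!r} is not resolved in this model; "
                "pass role_patterns to read_sbml or set named_roles explicitly"
            ) from None

    def validate(self) -> None:
        for rxn in self.reactions.values():
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise ModelValidationError(
                        f"reaction {rxn.id} references unknown metabolite {met_id}"
                    )
        for role, rxn_id in self.named_roles.items():
            if rxn_id not in self.reactions:
                raise ModelValidationError(f"role {role} points at unknown reaction {rxn_id}")

    def copy(self) -> "MetabolicModel":
        import copy as _copy

        return _copy.deepcopy(self)


def resolve_roles(
    model: MetabolicModel,
    role_patterns: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Match role names to reaction ids by regex search.

    Unresolved or ambiguous roles produce a warning, not an error, so that
    arbitrary SBML models still load.
    """
    patterns = dict(DEFAULT_ROLE_PATTERNS)
    if role_patterns:
        patterns.update(role_patterns)
    roles: dict[str, str] = {}
    for role, pattern in patterns.items():
        rx = re.compile(pattern)
        hits = [rid for rid in model.reactions if rx.search(rid)]
        if not hits:
            warnings.warn(f"role {role!r}: no reaction id matches {pattern!r}", stacklevel=2)
            continue
        if len(hits) > 1:
            warnings.warn(
                f"role {role!r}: pattern {pattern!r} matches {hits}; using {hits[0]}",
                stacklevel=2,
            )
        roles[role] = hits[0]
    return roles


# ---------------------------------------------------------------------------
# SBML I/O
# ---------------------------------------------------------------------------

def _require_libsbml():
    try:
        import libsbml
    except ImportError as exc:  # pragma: no cover
        raise ImportError("python-libsbml is required for SBML I/O") from exc
    return libsbml


def read_sbml(
    path: str | Path,
    external_convention: str = EXTERNAL_PREFIX,
    role_patterns: Mapping[str, str] | None = None,
) -> MetabolicModel:
    """Read an SBML file into a :class:`MetabolicModel`.

    External (boundary) species are recognized from the SBML
    ``boundaryCondition`` flag first, falling back to the id-prefix
    convention (default ``x_``) used by ScrumPy-derived models.  FBC flux
    bounds and chemical formulas are honored when present; otherwise bounds
    default to ``(0 | -1e5, 1e5)`` from the reversibility flag.
    """
    libsbml = _require_libsbml()
    path = Path(path)
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ValueError(
            f"malformed SBML {path.name}: line {err.getLine()}: {err.getMessage().strip()}"
        )
    sb_model = doc.getModel()
    if sb_model is None:
        raise ValueError(f"malformed SBML {path.name}: no <model> element")

    model = MetabolicModel(id=sb_model.getId() or path.stem)

    compartment_names = {
        c.getId(): (c.getName() or c.getId()) for c in sb_model.getListOfCompartments()
    }

    for sp in sb_model.getListOfSpecies():
        sid = sp.getId()
        if sid in model.metabolites:
            raise ModelValidationError(f"duplicate metabolite id {sid}")
        external = bool(sp.getBoundaryCondition())
        if external_convention and sid.startswith(external_convention):
            external = True
        formula: dict[str, int] = {}
        charge: int | None = None
        fbc_sp = sp.getPlugin("fbc")
        if fbc_sp is not None:
            if fbc_sp.isSetChemicalFormula():
                formula = parse_formula(fbc_sp.getChemicalFormula())
            if fbc_sp.isSetCharge():
                charge = fbc_sp.getCharge()
        compartment = compartment_names.get(sp.getCompartment(), sp.getCompartment())
        if external:
            compartment = "external"
        model.add_metabolite(
            Metabolite(
                id=sid,
                name=sp.getName() or sid,
                compartment=compartment,
                formula=formula,
                charge=charge,
                is_external=external,
            )
        )

    fbc_model = sb_model.getPlugin("fbc")

    def _fbc_bound(rxn, which: str) -> float | None:
        fbc_rxn = rxn.getPlugin("fbc")
        if fbc_rxn is None:
            return None
        pid = (
            fbc_rxn.getLowerFluxBound() if which == "lower" else fbc_rxn.getUpperFluxBound()
        )
        if not pid:
            return None
        param = sb_model.getParameter(pid)
        if param is None or not param.isSetValue():
            return None
        value = param.getValue()
        if not np.isfinite(value):
            return None
        return float(value)

    for rxn in sb_model.getListOfReactions():
        rid = rxn.getId()
        if rid in model.reactions:
            raise ModelValidationError(f"duplicate reaction id {rid}")
        stoich: dict[str, Fraction] = {}
        for ref in rxn.getListOfReactants():
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), Fraction(0)) - _as_fraction(
                ref.getStoichiometry()
            )
        for ref in rxn.getListOfProducts():
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), Fraction(0)) + _as_fraction(
                ref.getStoichiometry()
            )
        stoich = {m: c for m, c in stoich.items() if c != 0}
        reversible = bool(rxn.getReversible())
        lower = _fbc_bound(rxn, "lower")
        upper = _fbc_bound(rxn, "upper")
        if lower is not None and lower < 0:
            reversible = True
        model.add_reaction(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                reversible=reversible,
                lower_bound=lower,
                upper_bound=upper,
                name=rxn.getName() or rid,
            )
        )
    del fbc_model

    model.categorize()
    model.named_roles = resolve_roles(model, role_patterns)
    model.validate()
    logger.info("read %s: %d reactions, %d metabolites", path.name, len(model.reactions), len(model.metabolites))
    return model


_COMPARTMENT_CODES = {
    "cytosol": "c",
    "plastid": "p",
    "mitochondrion": "m",
    "peroxisome": "x",
    "external": "e",
}


def write_sbml(model: MetabolicModel, path: str | Path) -> None:
    """Write the model as SBML Level 3 (core + fbc bounds/formulas).

    The output is deterministic for a given model, so regenerating a fixture
    yields byte-identical files.
    """
    libsbml = _require_libsbml()
    path = Path(path)

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sb_model = doc.createModel()
    sb_model.setId(model.id)
    fbc_model = sb_model.getPlugin("fbc")
    fbc_model.setStrict(False)

    compartments = sorted({m.compartment for m in model.metabolites.values()})
    for comp in compartments:
        c = sb_model.createCompartment()
        c.setId(_COMPARTMENT_CODES.get(comp, comp))
        c.setName(comp)
        c.setConstant(True)

    for met in model.metabolites.values():
        sp = sb_model.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name)
        sp.setCompartment(_COMPARTMENT_CODES.get(met.compartment, met.compartment))
        sp.setBoundaryCondition(met.is_external)
        sp.setHasOnlySubstanceUnits(False)
        sp.setConstant(False)
        fbc_sp = sp.getPlugin("fbc")
        if met.formula:
            fbc_sp.setChemicalFormula(format_formula(met.formula))
        if met.charge is not None:
            fbc_sp.setCharge(met.charge)

    bound_params: dict[float, str] = {}

    def _bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            param = sb_model.createParameter()
            param.setId(pid)
            param.setValue(value)
            param.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions.values():
        r = sb_model.createReaction()
        r.setId(rxn.id)
        r.setName(rxn.name)
        r.setReversible(rxn.reversible)
        r.setFast(False)
        for met_id in sorted(rxn.stoichiometry):
            coeff = rxn.stoichiometry[met_id]
            ref = r.createReactant() if coeff < 0 else r.createProduct()
            ref.setSpecies(met_id)
            ref.setStoichiometry(float(abs(coeff)))
            ref.setConstant(True)
        fbc_rxn = r.getPlugin("fbc")
        fbc_rxn.setLowerFluxBound(_bound_param(float(rxn.lower_bound)))
        fbc_rxn.setUpperFluxBound(_bound_param(float(rxn.upper_bound)))

    ok = libsbml.writeSBMLToFile(doc, str(path))
    if not ok:
        raise OSError(f"could not write SBML to {path}")


# ---------------------------------------------------------------------------
# Stoichiometry matrix and summary
# ---------------------------------------------------------------------------

@dataclass
class StoichMatrix:
    """Sparse stoichiometry matrix over internal metabolites × reactions."""

    matrix: sparse.csr_matrix
    metabolite_ids: list[str]
    reaction_ids: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def build_matrix(model: MetabolicModel) -> StoichMatrix:
    """Build N with rows for internal metabolites only, columns in reaction order."""
    met_ids = model.internal_metabolite_ids
    rxn_ids = list(model.reactions)
    row_index = {m: i for i, m in enumerate(met_ids)}
    rows, cols, vals = [], [], []
    for j, rid in enumerate(rxn_ids):
        for met_id, coeff in model.reactions[rid].stoichiometry.items():
            i = row_index.get(met_id)
            if i is None:  # external row dropped
                continue
            rows.append(i)
            cols.append(j)
            vals.append(float(coeff))
    matrix = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids)), dtype=float
    )
    return StoichMatrix(matrix=matrix, metabolite_ids=met_ids, reaction_ids=rxn_ids)


def summarize(model: MetabolicModel) -> ModelSummary:
    """Count reactions and metabolites in the GSM partition (see :class:`ModelSummary`)."""
    n_internal = sum(1 for r in model.reactions.values() if r.category == "internal")
    n_transport = sum(1 for r in model.reactions.values() if r.category == "transporter")
    n_exchange = sum(1 for r in model.reactions.values() if r.category == "exchange")
    per_comp: dict[str, int] = {}
    for met in model.metabolites.values():
        if not met.is_external:
            per_comp[met.compartment] = per_comp.get(met.compartment, 0) + 1
    return ModelSummary(
        n_reactions_total=len(model.reactions),
        n_internal_reactions=n_internal,
        n_transporters=n_transport + n_exchange,
        n_exchanges=n_exchange,
        n_internal_metabolites=len(model.internal_metabolite_ids),
        n_external_metabolites=len(model.external_metabolite_ids),
        per_compartment=per_comp,
    )


def steady_state_residual(model: MetabolicModel, flux: Mapping[str, float]) -> float:
    """max |N v| over internal metabolites for a flux vector given as a dict."""
    sm = build_matrix(model)
    v = np.array([flux.get(rid, 0.0) for rid in sm.reaction_ids])
    if sm.matrix.shape[0] == 0:
        return 0.0
    return float(np.max(np.abs(sm.matrix @ v))) if len(v) else 0.0
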