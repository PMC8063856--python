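"""Deterministic synthetic fixture: a small compartmented, atom-balanced
photoautotroph/mixotroph network producing triacylglycerol (TAG).

The network spans cytosol, plastid and mitochondrion and contains every
pathway feature the condition and demand-scan analyses depend on:

* lumped photosynthetic light reactions (linear and cyclic) driving
  plastidial ATP/NADPH formation with explicit O2/water/proton terms;
* rubisco carboxylase and oxygenase plus a lumped Calvin cycle
  (PGA reduction and RuBP regeneration from triose phosphate);
* glycerol entry via glycerol kinase and glycerol-3-phosphate
  dehydrogenase, lumped lower glycolysis and pyruvate kinase;
* anaplerotic HCO3 fixation by PEP carboxylase, with PEP carboxykinase,
  pyruvate-phosphate dikinase and malic enzyme closing the C3/C4 cycles;
* the photorespiratory glycolate route (phosphoglycolate phosphatase,
  glycolate dehydrogenase) feeding the glyoxylate shunt (malate synthase);
* citrate synthase / ATP-citrate lyase supplying cytosolic acetyl-CoA,
  lumped TCA oxidation and the mitochondrial electron transport chain;
* fatty-acid synthesis and TAG assembly, and exchanges for photon, CO2,
  HCO3, glycerol, O2, water, proton and TAG.

Design constraints baked in (rather than emergent): cytosolic NADPH is
supplied only by malic enzyme, which couples reductant supply to the C4
pool and hence to anaplerosis — this is what makes HCO3 availability
change the optimal routing, mirroring the behaviour under study.  There is
no carbonic anhydrase, so closing the HCO3 exchange genuinely forbids PEP
carboxylase and forces the photorespiratory/glyoxylate-shunt alternative.

The generator is pure code with no randomness: two builds with the same
options produce identical models, and fixtures written to SBML are
byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

from .model import MetabolicModel, Metabolite, Reaction, parse_formula, resolve_roles, write_sbml

F = Fraction


class GenerationError(ValueError):
    """Inconsistent toy options (e.g. a TAG formula padding cannot close)."""


#: element maps for every species (standard neutral formulas; photon is massless)
_FORMULAS = {
    "Photon": "",
    "CO2": "CO2",
    "HCO3": "CHO3",
    "H2O": "H2O",
    "O2": "O2",
    "H": "H",
    "GLYCEROL": "C3H8O3",
    "G3P": "C3H9O6P",
    "DHAP": "C3H7O6P",
    "GAP": "C3H7O6P",
    "PGA": "C3H7O7P",
    "PEP": "C3H5O6P",
    "PYR": "C3H4O3",
    "OAA": "C4H4O5",
    "MAL": "C4H6O5",
    "CIT": "C6H8O7",
    "GLX": "C2H2O3",
    "GLYCOLATE": "C2H4O3",
    "PGLY2": "C2H5O6P",
    "RUBP": "C5H12O11P2",
    "RU5P": "C5H11O8P",
    "ATP": "C10H16N5O13P3",
    "ADP": "C10H15N5O10P2",
    "PI": "H3O4P",
    "NADP": "C21H28N7O17P3",
    "NADPH": "C21H29N7O17P3",
    "NAD": "C21H27N7O14P2",
    "NADH": "C21H28N7O14P2",
    "COA": "C21H36N7O16P3S",
    "ACCOA": "C23H38N7O17P3S",
    "FA": "C16H32O2",
    "TAG": "C51H98O6",
}

_COMPARTMENTS = {"c": "cytosol", "p": "plastid", "m": "mitochondrion"}

#: default TAG: three C16:0 acyl chains on a glycerol backbone
DEFAULT_TAG_FORMULA = "C51H98O6"


@dataclass
class ToyOptions:
    """Switches for the generated network.

    ``tag_formula`` must keep 51 carbons (3 C16 acyls + C3 backbone); its
    H and O counts may differ from the default, in which case the TAG
    assembly reaction is re-padded with water and proton terms.  With
    ``pad_water_protons`` (default) every lumped reaction carries explicit
    H2O/H+ closure so the model balances for H and O, not only C.
    """

    include_photorespiration: bool = True
    include_glyoxylate_shunt: bool = True
    include_hco3_exchange: bool = True
    include_glycerol_exchange: bool = True
    tag_formula: str = DEFAULT_TAG_FORMULA
    pad_water_protons: bool = True
    simplification: str = "lumped"  # only level supported


def _species_id(species: str, compartment: str) -> str:
    return f"x_{species}" if compartment == "x" else f"{species}_{compartment}"


def build_toy_model(options: ToyOptions | None = None) -> MetabolicModel:
    """Construct the toy model; raises :class:`GenerationError` on bad options."""
    opts = options or ToyOptions()
    if opts.simplification != "lumped":
        raise GenerationError(f"unknown simplification level {opts.simplification!r}")

    tag_counts = parse_formula(opts.tag_formula)
    if tag_counts.get("C") != 51 or set(tag_counts) - {"C", "H", "O"}:
        raise GenerationError(
            f"tag_formula {opts.tag_formula!r} must be CHO with exactly 51 carbons"
        )

    model = MetabolicModel(id="toy_phaeo")

    def met(species: str, comp: str) -> str:
        mid = _species_id(species, comp)
        if mid not in model.metabolites:
            formula = dict(parse_formula(_FORMULAS[species]))
            if species == "TAG":
                formula = dict(tag_counts)
            model.add_metabolite(
                Metabolite(
                    id=mid,
                    name=species,
                    compartment="external" if comp == "x" else _COMPARTMENTS[comp],
                    formula=formula,
                    is_external=(comp == "x"),
                )
            )
        return mid

    def rxn(rid: str, stoich: dict[str, Fraction | int], reversible: bool) -> None:
        model.add_reaction(
            Reaction(id=rid, stoichiometry={m: F(c) for m, c in stoich.items()},
                     reversible=reversible)
        )

    # ---- exchanges ------------------------------------------------------
    rxn("tx_Photon", {met("Photon", "x"): -1, met("Photon", "p"): 1}, False)
    rxn("tx_CO2", {met("CO2", "x"): -1, met("CO2", "c"): 1}, True)
    if opts.include_hco3_exchange:
        rxn("tx_HCO3", {met("HCO3", "x"): -1, met("HCO3", "c"): 1}, True)
    else:
        met("HCO3", "c")
    if opts.include_glycerol_exchange:
        rxn("tx_Glycerol", {met("GLYCEROL", "x"): -1, met("GLYCEROL", "c"): 1}, False)
    rxn("tx_O2", {met("O2", "x"): -1, met("O2", "c"): 1}, True)
    rxn("tx_Water", {met("H2O", "x"): -1, met("H2O", "c"): 1}, True)
    rxn("tx_Proton", {met("H", "x"): -1, met("H", "c"): 1}, True)
    rxn("tx_TAG", {met("TAG", "c"): -1, met("TAG", "x"): 1}, False)

    # ---- plastid: light reactions and Calvin cycle ----------------------
    # linear electron flow, 8 photons per O2, ATP:NADPH = 3:2
    rxn(
        "LightReactions",
        {
            met("Photon", "p"): -8, met("NADP", "p"): -2, met("ADP", "p"): -3,
            met("PI", "p"): -3,
            met("O2", "p"): 1, met("NADPH", "p"): 2, met("ATP", "p"): 3,
            met("H2O", "p"): 1, met("H", "p"): 2,
        },
        False,
    )
    # cyclic electron flow around PSI: ATP only
    rxn(
        "CyclicPhotophosphorylation",
        {met("Photon", "p"): -4, met("ADP", "p"): -1, met("PI", "p"): -1,
         met("ATP", "p"): 1, met("H2O", "p"): 1},
        False,
    )
    rxn(
        "RubiscoCarboxylase",
        {met("RUBP", "p"): -1, met("CO2", "p"): -1, met("H2O", "p"): -1,
         met("PGA", "p"): 2},
        False,
    )
    rxn(
        "PGAReduction",  # phosphoglycerate kinase + NADP-GAPDH, lumped
        {met("PGA", "p"): -1, met("ATP", "p"): -1, met("NADPH", "p"): -1,
         met("H", "p"): -1,
         met("GAP", "p"): 1, met("ADP", "p"): 1, met("PI", "p"): 1,
         met("NADP", "p"): 1},
        False,
    )
    # NAD-linked plastid GAPDH: lets the Calvin cycle run on imported
    # (respiratory) reductant when light is limiting
    rxn(
        "PGAReductionNADH",
        {met("PGA", "p"): -1, met("ATP", "p"): -1, met("NADH", "p"): -1,
         met("H", "p"): -1,
         met("GAP", "p"): 1, met("ADP", "p"): 1, met("PI", "p"): 1,
         met("NAD", "p"): 1},
        False,
    )
    rxn(
        "RuBPRegeneration",  # lumped sugar-phosphate shuffle + phosphoribulokinase
        {met("GAP", "p"): -5, met("ATP", "p"): -3, met("H2O", "p"): -2,
         met("RUBP", "p"): 3, met("ADP", "p"): 3, met("PI", "p"): 2},
        False,
    )
    if opts.include_photorespiration:
        rxn(
            "RubiscoOxygenase",
            {met("RUBP", "p"): -1, met("O2", "p"): -1,
             met("PGA", "p"): 1, met("PGLY2", "p"): 1},
            False,
        )
        rxn(
            "PGlycolatePhosphatase",
            {met("PGLY2", "p"): -1, met("H2O", "p"): -1,
             met("GLYCOLATE", "p"): 1, met("PI", "p"): 1},
            False,
        )
    # NADP-malate dehydrogenase: exports photosynthetic reductant (malate valve)
    rxn(
        "PlastidNADPMDH",
        {met("OAA", "p"): -1, met("NADPH", "p"): -1, met("H", "p"): -1,
         met("MAL", "p"): 1, met("NADP", "p"): 1},
        False,
    )

    # ---- cytosol: glycerol entry, glycolysis, C3/C4 cycling, lipids -----
    rxn(
        "GlycerolKinase",
        {met("GLYCEROL", "c"): -1, met("ATP", "c"): -1,
         met("G3P", "c"): 1, met("ADP", "c"): 1},
        False,
    )
    rxn(
        "G3PDehydrogenase",
        {met("G3P", "c"): -1, met("NAD", "c"): -1,
         met("DHAP", "c"): 1, met("NADH", "c"): 1, met("H", "c"): 1},
        True,
    )
    rxn("TriosePhosphateIsomerase", {met("DHAP", "c"): -1, met("GAP", "c"): 1}, True)
    # cytosolic glycolysis is truncated at phosphoglycerate; exported plastid
    # PGA re-enters here through mutase + enolase
    rxn(
        "PGAMutaseEnolase",
        {met("PGA", "c"): -1, met("PEP", "c"): 1, met("H2O", "c"): 1},
        False,
    )
    rxn(
        "GlycolysisLower",  # GAPDH + PGK + PGM + enolase, lumped
        {met("GAP", "c"): -1, met("NAD", "c"): -1, met("ADP", "c"): -1,
         met("PI", "c"): -1,
         met("PEP", "c"): 1, met("NADH", "c"): 1, met("ATP", "c"): 1,
         met("H2O", "c"): 1, met("H", "c"): 1},
        False,
    )
    rxn(
        "PyruvateKinase",
        {met("PEP", "c"): -1, met("ADP", "c"): -1,
         met("PYR", "c"): 1, met("ATP", "c"): 1},
        False,
    )
    rxn(
        "PEPCarboxylase",
        {met("PEP", "c"): -1, met("HCO3", "c"): -1, met("H", "c"): -1,
         met("OAA", "c"): 1, met("PI", "c"): 1},
        False,
    )
    rxn(
        "PEPCarboxykinase",
        {met("OAA", "c"): -1, met("ATP", "c"): -1,
         met("PEP", "c"): 1, met("CO2", "c"): 1, met("ADP", "c"): 1},
        False,
    )
    rxn(
        "PyruvatePhosphateDikinase",  # PPi hydrolysis folded in
        {met("PYR", "c"): -1, met("ATP", "c"): -2, met("H2O", "c"): -1,
         met("PEP", "c"): 1, met("ADP", "c"): 2, met("PI", "c"): 1},
        False,
    )
    rxn(
        "ATPCitrateLyase",
        {met("CIT", "c"): -1, met("ATP", "c"): -1, met("COA", "c"): -1,
         met("ACCOA", "c"): 1, met("OAA", "c"): 1, met("ADP", "c"): 1,
         met("PI", "c"): 1},
        False,
    )
    rxn(
        "CytMalateDehydrogenase",
        {met("OAA", "c"): -1, met("NADH", "c"): -1, met("H", "c"): -1,
         met("MAL", "c"): 1, met("NAD", "c"): 1},
        True,
    )
    rxn(
        "MalicEnzyme",  # NADP-dependent; sole cytosolic NADPH source
        {met("MAL", "c"): -1, met("NADP", "c"): -1,
         met("PYR", "c"): 1, met("CO2", "c"): 1, met("NADPH", "c"): 1,
         met("H", "c"): 1},
        False,
    )
    rxn(
        "FattyAcidSynthesis",  # 8 acetyl-CoA -> C16:0, ACC + FAS lumped;
        # ketoacyl reduction on NADPH, enoyl reduction on NADH
        {met("ACCOA", "c"): -8, met("ATP", "c"): -7, met("NADPH", "c"): -7,
         met("NADH", "c"): -7, met("H", "c"): -14, met("H2O", "c"): -1,
         met("FA", "c"): 1, met("COA", "c"): 8, met("ADP", "c"): 7,
         met("PI", "c"): 7, met("NADP", "c"): 7, met("NAD", "c"): 7},
        False,
    )
    rxn("TAGSynthesis", _tag_synthesis_stoich(model, met, tag_counts, opts), False)

    # ---- mitochondrion: oxidative metabolism and the glyoxylate shunt ---
    rxn(
        "PyruvateDehydrogenase",
        {met("PYR", "m"): -1, met("COA", "m"): -1, met("NAD", "m"): -1,
         met("ACCOA", "m"): 1, met("CO2", "m"): 1, met("NADH", "m"): 1,
         met("H", "m"): 1},
        False,
    )
    rxn(
        "CitrateSynthase",
        {met("OAA", "m"): -1, met("ACCOA", "m"): -1, met("H2O", "m"): -1,
         met("CIT", "m"): 1, met("COA", "m"): 1},
        False,
    )
    rxn(
        "TCAOxidation",  # full oxidation of acetyl-CoA, cycle lumped (OAA catalytic)
        {met("ACCOA", "m"): -1, met("H2O", "m"): -3, met("NAD", "m"): -4,
         met("CO2", "m"): 2, met("COA", "m"): 1, met("NADH", "m"): 4,
         met("H", "m"): 4},
        False,
    )
    rxn(
        "MitoMalateDehydrogenase",
        {met("MAL", "m"): -1, met("NAD", "m"): -1,
         met("OAA", "m"): 1, met("NADH", "m"): 1, met("H", "m"): 1},
        True,
    )
    rxn(
        "ElectronTransportChain",  # NADH oxidation + oxidative phosphorylation, P/O 2.5
        {met("NADH", "m"): -2, met("H", "m"): -2, met("O2", "m"): -1,
         met("ADP", "m"): -5, met("PI", "m"): -5,
         met("NAD", "m"): 2, met("H2O", "m"): 7, met("ATP", "m"): 5},
        False,
    )
    rxn(
        "AlternativeOxidase",  # uncoupled electron sink (no ATP)
        {met("NADH", "m"): -2, met("H", "m"): -2, met("O2", "m"): -1,
         met("NAD", "m"): 2, met("H2O", "m"): 2},
        False,
    )
    if opts.include_photorespiration:
        rxn(
            "GlycolateDehydrogenase",
            {met("GLYCOLATE", "m"): -1, met("NAD", "m"): -1,
             met("GLX", "m"): 1, met("NADH", "m"): 1, met("H", "m"): 1},
            False,
        )
    if opts.include_glyoxylate_shunt:
        rxn(
            "MalateSynthase",
            {met("GLX", "m"): -1, met("ACCOA", "m"): -1, met("H2O", "m"): -1,
             met("MAL", "m"): 1, met("COA", "m"): 1},
            False,
        )

    # ---- inter-compartment transporters ---------------------------------
    # triose-phosphate translocator: GAP/Pi antiport keeps plastid P balanced
    rxn("TxGAP_Pi_pc", {met("GAP", "p"): -1, met("PI", "c"): -1,
                        met("GAP", "c"): 1, met("PI", "p"): 1}, True)
    rxn("TxPGA_Pi_pc", {met("PGA", "p"): -1, met("PI", "c"): -1,
                        met("PGA", "c"): 1, met("PI", "p"): 1}, True)
    rxn("TxATP_pc", {met("ATP", "p"): -1, met("ADP", "c"): -1,
                     met("ATP", "c"): 1, met("ADP", "p"): 1}, True)
    rxn("TxOAA_cp", {met("OAA", "c"): -1, met("OAA", "p"): 1}, True)
    rxn("TxMAL_pc", {met("MAL", "p"): -1, met("MAL", "c"): 1}, True)
    rxn("TxCO2_cp", {met("CO2", "c"): -1, met("CO2", "p"): 1}, True)
    rxn("TxO2_pc", {met("O2", "p"): -1, met("O2", "c"): 1}, True)
    rxn("TxH2O_cp", {met("H2O", "c"): -1, met("H2O", "p"): 1}, True)
    rxn("TxH_cp", {met("H", "c"): -1, met("H", "p"): 1}, True)
    if opts.include_photorespiration:
        rxn("TxGlycolate_pc", {met("GLYCOLATE", "p"): -1, met("GLYCOLATE", "c"): 1}, False)
        rxn("TxGlycolate_cm", {met("GLYCOLATE", "c"): -1, met("GLYCOLATE", "m"): 1}, False)
    rxn("TxPyr_cm", {met("PYR", "c"): -1, met("PYR", "m"): 1}, True)
    rxn("TxCit_mc", {met("CIT", "m"): -1, met("CIT", "c"): 1}, False)
    rxn("TxOAA_cm", {met("OAA", "c"): -1, met("OAA", "m"): 1}, True)
    rxn("TxMAL_mc", {met("MAL", "m"): -1, met("MAL", "c"): 1}, True)
    rxn("MalateAspartateShuttle",  # lumped redox shuttle
        {met("NADH", "c"): -1, met("NAD", "m"): -1,
         met("NAD", "c"): 1, met("NADH", "m"): 1}, True)
    rxn("PlastidRedoxShuttle",  # lumped cytosol<->plastid NADH carrier
        {met("NADH", "c"): -1, met("NAD", "p"): -1,
         met("NAD", "c"): 1, met("NADH", "p"): 1}, True)
    rxn("AdenylateTranslocase", {met("ATP", "m"): -1, met("ADP", "c"): -1,
                                 met("ATP", "c"): 1, met("ADP", "m"): 1}, True)
    rxn("TxPi_cm", {met("PI", "c"): -1, met("PI", "m"): 1}, True)
    rxn("TxCO2_mc", {met("CO2", "m"): -1, met("CO2", "c"): 1}, True)
    rxn("TxO2_cm", {met("O2", "c"): -1, met("O2", "m"): 1}, True)
    rxn("TxH2O_mc", {met("H2O", "m"): -1, met("H2O", "c"): 1}, True)
    rxn("TxH_cm", {met("H", "c"): -1, met("H", "m"): 1}, True)

    model.categorize()
    model.named_roles = {
        "txTAG": "tx_TAG",
        "txPhoton": "tx_Photon",
        "Carboxylase": "RubiscoCarboxylase",
    }
    if opts.include_hco3_exchange:
        model.named_roles["txHCO3"] = "tx_HCO3"
    if opts.include_glycerol_exchange:
        model.named_roles["txGlycerol"] = "tx_Glycerol"
    if opts.include_photorespiration:
        model.named_roles["Oxygenase"] = "RubiscoOxygenase"
    model.validate()
    _check_generator_balance(
        model, elements=None if opts.pad_water_protons else ("C", "N", "P", "S", "Mg")
    )
    return model


def _tag_synthesis_stoich(model, met, tag_counts, opts) -> dict[str, Fraction]:
    """G3P + 3 FA + 3 ATP -> TAG + 3 ADP + 4 Pi, re-padded with H2O/H+ so
    the reaction closes for H and O under any CHO tag formula with C51."""
    lhs_h = 9 + 3 * 32 + 3 * 16  # G3P + 3 FA + 3 ATP
    lhs_o = 6 + 3 * 2 + 3 * 13
    rhs_h = tag_counts.get("H", 0) + 3 * 15 + 4 * 3  # TAG + 3 ADP + 4 Pi
    rhs_o = tag_counts.get("O", 0) + 3 * 10 + 4 * 4
    # water w and proton h on the LHS (signed): w*2 + h = rhs_h - lhs_h ; w = rhs_o - lhs_o
    w = F(rhs_o - lhs_o)
    h = F(rhs_h - lhs_h) - 2 * w
    if not opts.pad_water_protons:
        # carbon/phosphorus closure still holds; H and O are left open and
        # will show up in the elemental audit
        w = h = F(0)
    if abs(h) > 8 or abs(w) > 8:
        raise GenerationError(
            f"tag_formula {format_counts(tag_counts)} is too far from a glyceride "
            "composition for padding to close"
        )
    stoich = {
        met("G3P", "c"): F(-1), met("FA", "c"): F(-3), met("ATP", "c"): F(-3),
        met("TAG", "c"): F(1), met("ADP", "c"): F(3), met("PI", "c"): F(4),
    }
    if w:
        stoich[met("H2O", "c")] = stoich.get(met("H2O", "c"), F(0)) - w
    if h:
        stoich[met("H", "c")] = stoich.get(met("H", "c"), F(0)) - h
    return {m: c for m, c in stoich.items() if c != 0}


def format_counts(counts) -> str:
    from .model import format_formula

    return format_formula(counts)


def _check_generator_balance(model: MetabolicModel, elements=None) -> None:
    """Internal audit: every non-exchange reaction must balance for the
    given elements (all, by default), treating the massless photon as an
    all-zero formula."""
    for rxn in model.reactions.values():
        if rxn.category == "exchange":
            continue
        net: dict[str, Fraction] = {}
        for mid, coeff in rxn.stoichiometry.items():
            for element, count in model.metabolites[mid].formula.items():
                if elements is not None and element not in elements:
                    continue
                net[element] = net.get(element, F(0)) + coeff * count
        bad = {e: v for e, v in net.items() if v != 0}
        if bad:
            raise GenerationError(f"generator produced unbalanced reaction {rxn.id}: {bad}")


def write_fixture(model: MetabolicModel, path: str | Path) -> None:
    """Serialize a toy model to SBML (round-trips through read_sbml)."""
    write_sbml(model, path)


def default_scan_caps():
    """Caps under which the demand scan of the default toy shows all four
    regions (free growth, then glycerol-, photon- and rubisco-limited).

    Chosen relative to the unit-demand mixotrophic solution (25 glycerol
    per TAG, so maxG binds at demand 2.4) so that the three caps bind in
    that order as TAG demand rises.
    """
    from .scan import ScanCaps

    return ScanCaps(maxG=60.0, maxP=230.0, maxC=34.0)


def calibrate_caps(model: MetabolicModel, condition=None, fractions=(1.2, 1.5, 2.0)):
    """Suggest scan caps as multiples of the unit-demand solution's glycerol,
    photon and rubisco fluxes (helper for arbitrary models)."""
    from .conditions import STANDARD_CONDITIONS, run_condition
    from .scan import ScanCaps

    spec = condition or STANDARD_CONDITIONS[0]
    sol = run_condition(model, spec)
    if sol.status != "optimal":
        raise ValueError(f"unit-demand solve is {sol.status}; cannot calibrate caps")
    g = abs(sol.flux.get(model.named_roles.get("txGlycerol", ""), 0.0))
    p = abs(sol.flux.get(model.named_roles.get("txPhoton", ""), 0.0))
    c = abs(sol.flux.get(model.named_roles.get("Carboxylase", ""), 0.0)) + abs(
        sol.flux.get(model.named_roles.get("Oxygenase", ""), 0.0)
    )
    fg, fp, fc = fractions
    return ScanCaps(maxG=fg * max(g, 1.0), maxP=fp * max(p, 1.0), maxC=fc * max(c, 1.0))
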