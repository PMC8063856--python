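# Methods

## The flux-minimization model

The analysis treats metabolism as a stoichiometric network at steady
state: internal metabolite concentrations are constant, so admissible flux
vectors satisfy `N v = 0` with `N` the internal-metabolite × reaction
stoichiometry matrix (external, boundary metabolites are excluded from
balancing). Among all steady-state flux distributions that deliver a fixed
TAG demand, the package selects the one minimizing the summed absolute
flux over *all* reactions, transporters included. This L1 objective is a
proxy for the total enzyme capacity a cell must maintain; it is convex and
piecewise-linear in the demand, which the scan module exploits and
verifies.

The LP is solved by variable splitting (`v = p − n`, `p, n ≥ 0`, unit
costs) with the HiGHS simplex via SciPy, at primal/dual tolerance 1e-9.
Statuses are reported honestly: infeasible condition runs appear in
tables with their status rather than being dropped.

Photon flux is deliberately left free in condition runs, although the
formal problem statement fixes it: light then enters the objective like
every other transporter, and the light requirement becomes an output that
differs across conditions. Fixing it instead is supported through
`ConditionSpec.photon_bound`, but only the free-photon mode produces a
per-condition photon demand in the net-stoichiometry table, which is the
shape of result the analysis is after.

### Alternate optima

Minimal-L1 solutions can be degenerate: the objective value is unique, but
the optimal vertex — and with it the active-reaction count — need not be.
All quantitative contracts are therefore stated on the objective and on
net stoichiometries (which are unique in practice for these networks),
while active-set sizes are treated qualitatively. A deterministic
refinement (`lexicographic=True`) re-minimizes each reaction's absolute
flux in model order at fixed total flux, yielding a reproducible vertex at
the cost of one extra LP per reaction.

## Exact oracles

Two independent rational-arithmetic solvers back the tests:

* `exact_minimum` — a primal simplex on `fractions.Fraction` with Bland's
  rule (guaranteed termination, no tolerances). It shares only the
  problem construction with the float path; all pivoting is exact, so its
  optimum is the true LP minimum. It handles the full toy network
  (~60 reactions) in about a second per solve.
* `enumerate_oracle` — exhaustive enumeration of all basic feasible
  solutions, returning every optimal vertex. Its cost is binomial in the
  variable count, so it refuses systems with more than ~25 split
  variables; it serves as the ground truth for the tiny chain models in
  the unit tests and as a cross-check of the simplex.

Exhaustive enumeration on the full toy network is combinatorially out of
reach (≈C(80, 60) bases), which is why the package carries both oracles
rather than one.

## Validation battery

* **Elemental balance** uses exact rational sums of coefficient × formula
  count per element (C, H, O, N, P, S, Mg by default). Exchange reactions
  are the system boundary and exempt; reactions touching a metabolite
  with no formula annotation are reported as skipped, not judged.
* **Leak test**: with all other exchanges closed, each exchange reaction
  is asked to produce its external metabolite at steady state; any rate
  above 1e-9 × (largest bound) is a mass leak and is returned with a
  witness flux vector. Only externally *producing* directions are tested —
  a pure import such as the massless photon feed is not a mass source.
* **Energy test**: an ATP-hydrolysis drain (ATP + H2O → ADP + Pi + H⁺) is
  added and maximized with all exchanges closed; sustainable drain flux
  exposes an energy-generating cycle. This is the standard
  reconstruction-level check; thermodynamic (ΔG-based) loop analysis is
  out of scope. The drain species are auto-detected by name or supplied
  explicitly.

Both LP tests return witnesses that themselves satisfy `|N v| ≤ 1e-9`, so
a failure is always a checkable certificate.

## The synthetic network

`fluxscan.toy` builds a 62-reaction, 63-internal-metabolite network over
cytosol, plastid and mitochondrion, with exchanges for photon, CO2, HCO3,
glycerol, O2, water, proton and TAG. It is pure deterministic code — two
builds are identical and SBML fixtures are byte-stable. Design choices
that matter:

* **Lumping.** Light reactions (8 photons → 3 ATP + 2 NADPH + O2, plus a
  cyclic variant), Calvin-cycle regeneration, lower glycolysis, fatty-acid
  synthesis, TCA oxidation and the electron transport chain (P/O 2.5) are
  single reactions with small-integer stoichiometry so the rational
  oracle stays exact. Every species carries its standard neutral formula;
  each lumped reaction is closed for H and O with explicit water/proton
  terms, and the generator verifies full elemental balance at build time
  (the massless photon counts as an all-zero formula).
* **Routing motif.** Cytosolic NADPH is supplied only by NADP-malic
  enzyme, so reductant supply consumes the C4 pool and must be replenished
  anaplerotically — by PEP carboxylase when HCO3 is available, otherwise
  through the photorespiratory glycolate route feeding the glyoxylate
  shunt. There is no carbonic anhydrase, so closing the HCO3 exchange
  genuinely disables PEP carboxylase. Fatty-acid reduction draws half on
  NADPH (ketoacyl reduction) and half on NADH (enoyl reduction).
  Cytosolic acetyl-CoA comes only through citrate export and ATP-citrate
  lyase. The cytosolic oxidative pentose-phosphate route is deliberately
  omitted: with it, reductant supply would decouple from the C4 pool and
  the HCO3/photorespiration routing contrast — the behaviour under
  study — would disappear.
* **Energy flexibility.** An uncoupled alternative oxidase gives obligate
  redox production a non-phosphorylating sink; a plastid NAD-GAPDH plus a
  plastid redox shuttle lets the Calvin cycle run on respiratory
  reductant when light is capped; PGA export with cytosolic
  mutase/enolase reflects the organism's cytosolic glycolysis being
  truncated at phosphoglycerate. These are what give the demand scan its
  post-saturation reserves.
* **TAG.** Default composition C51H98O6 (three C16:0 acyls on a glycerol
  backbone) — an explicit approximation, not a measured composition.
  Custom CHO formulas with 51 carbons are supported; the assembly
  reaction is re-padded with water/protons, and padding can be disabled,
  in which case H/O imbalance is reported by the audit rather than
  hidden.
* **Reaction count.** The network is slightly larger (~62 reactions) than
  a bare pathway list would be because the scan regions require genuine
  substitution reserves (alternative oxidase, NAD-linked PGA reduction,
  PPDK, the malate valve); without them demand growth would stop the
  moment the glycerol and photon caps bind and the rubisco-limited regime
  could not exist.

What the toy does *not* emulate: biomass synthesis beyond TAG, charge and
proton-motive-force coupling across membranes (protons and small species
move freely between compartments), thermodynamic irreversibility beyond
assigned directions, and the deposited model's size and exact TAG
composition. Passing tests on the toy therefore demonstrate correctness
of the algorithms and the qualitative routing logic, not quantitative
agreement with the organism; the quantitative reproduction lives in the
deposited-model checks, which require a one-time download.

## Demand scan

The scan solves the LP on a uniform demand grid (default step 0.025 TAG
units, chosen so each region of the toy's default configuration contains
grid points while the whole scan stays around a hundred solves) under
three caps: glycerol uptake `maxG`, photon influx `maxP` and combined
rubisco flux `maxC` (carboxylase + oxygenase, as absolute values). After
the first infeasible step the feasibility limit is refined by bisection to
1e-6 and appended to the grid, so the terminal flux pattern is recorded.

A cap counts as binding when its quantity reaches cap × (1 − 1e-4); the
relative tolerance separates binding from near-binding under double
precision. Signatures must be nested along the grid — a cap un-saturating
signals degenerate alternate optima, raised as an error with the
offending demands (re-run with the lexicographic refinement). Regions are
labelled A, B, C, … in order of signature appearance.

The published scan's cap values and demand step are not stated, so caps
are required configuration. For the toy, `default_scan_caps()` fixes
(maxG, maxP, maxC) = (60, 230, 34): maxG is 2.4× the unit-demand glycerol
requirement, and the photon and rubisco caps sit inside the post-glycerol
trajectory so that the three caps bind in the order glycerol → photon →
rubisco and all four regions appear. For arbitrary models
`calibrate_caps()` suggests caps as fractions (1.2/1.5/2.0 by default) of
the unit-demand solution's fluxes. The varying-reaction count (49 on the
toy's default configuration) is a property of the configuration, not a
reproduction target.

Flux-response classification marks a reaction as varying when its
trajectory range exceeds 1e-6 × max(1, demand_max) and groups varying
reactions by the sign pattern of their per-region slopes; reactions in
one linear chain are proportional and land in the same group.

## Numerical conventions

* Default bounds for otherwise unbounded reactions: ±1e5 (0..1e5 for
  irreversible); the exact oracle treats these as infinite, which is safe
  because the L1 objective bounds every optimum away from them.
* Support threshold for "active" reactions: 1e-6 × max(1, demand).
* Net-stoichiometry omission threshold 1e-7; consumption is negative.
* Conservation tests: 1e-9 relative to the largest bound.
* SBML: Level 3 + fbc; boundary species by flag first, then the `x_`
  id-prefix convention; FBC bounds honored when present, otherwise the
  reversibility flag; named roles (txTAG, txHCO3, txGlycerol, txPhoton,
  Carboxylase, Oxygenase) resolved by configurable regex with warnings,
  not errors, for unresolved roles.

## Known limitations

* Active-reaction counts are solver-dependent under degeneracy (see
  above); only objectives and net stoichiometries are hard contracts.
* The energy test is per-currency (ATP by default); NAD(P)H drains can be
  added the same way but are not run automatically.
* The exact simplex is dense and intended for test-scale networks, not
  genome-scale ones.
* On the toy, the mixotrophic optimum at low demand meets its ATP needs
  respiratorily and consumes O2; gross photosynthetic O2 production still
  peaks in the terminal scan regions, but the net O2 exchange sign
  differs from a light-dominated system.
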