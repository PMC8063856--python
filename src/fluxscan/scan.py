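"""Parametric TAG-demand scan under capacity caps.

The flux-minimization LP is re-solved with stepwise-incremented TAG demand
under three capacity caps — glycerol uptake (maxG), photon influx (maxP)
and total rubisco flux, carboxylase + oxygenase (maxC) — until no feasible
solution exists; the feasibility limit is then refined by bisection.  As
demand rises the caps saturate one after another, and the demand axis
splits into regions distinguished by which caps are binding (the
parametric-LP breakpoints).  The optimal objective is a piecewise-linear
convex non-decreasing function of demand, which the scan verifies
numerically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .conditions import ConditionSpec, STANDARD_CONDITIONS
from .lp import CoupledCap, FluxConstraint, minimize_total_flux
from .model import MetabolicModel

#: a cap counts as binding when its constrained quantity reaches cap*(1 - tol)
SATURATION_TOL = 1e-4

#: bisection tolerance on the feasibility limit
DEMAND_MAX_TOL = 1e-6

CAP_NAMES = ("G", "P", "C")


@dataclass(frozen=True)
class ScanCaps:
    """Upper limits for the scan: glycerol uptake, photon flux, rubisco."""

    maxG: float
    maxP: float
    maxC: float

    def __post_init__(self):
        for name in ("maxG", "maxP", "maxC"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and non-negative, got {v}")


@dataclass
class ScanResult:
    demand_grid: np.ndarray  # strictly increasing feasible demands
    flux_matrix: pd.DataFrame  # reactions x demands
    objective_curve: np.ndarray
    demand_max: float
    caps: ScanCaps
    condition: ConditionSpec
    saturation_points: dict[str, float] = field(default_factory=dict)
    #: per grid point, the set of binding caps (subset of {"G","P","C"})
    binding: list[frozenset] = field(default_factory=list)


class RegionError(RuntimeError):
    """Cap signatures failed to nest (a cap un-saturated as demand grew)."""


@dataclass
class Region:
    label: str
    start: float  # demand interval (start, end]
    end: float
    signature: frozenset


@dataclass
class RegionLabels:
    regions: list[Region]

    def __iter__(self):
        return iter(self.regions)

    def __len__(self):
        return len(self.regions)

    @property
    def signatures(self) -> list[frozenset]:
        return [r.signature for r in self.regions]


def _scan_constraints(model: MetabolicModel, caps: ScanCaps, condition: ConditionSpec,
                      demand: float):
    cons = [FluxConstraint(model.role("txTAG"), "eq", demand)]
    if not condition.hco3_open:
        cons.append(FluxConstraint(model.role("txHCO3"), "eq", 0.0))
    if condition.glycerol_open:
        cons.append(FluxConstraint(model.role("txGlycerol"), "le", caps.maxG))
    else:
        cons.append(FluxConstraint(model.role("txGlycerol"), "eq", 0.0))
    cons.append(FluxConstraint(model.role("txPhoton"), "le", caps.maxP))
    rubisco = [model.role("Carboxylase")]
    if "Oxygenase" in model.named_roles:
        rubisco.append(model.role("Oxygenase"))
    coupled = [CoupledCap(tuple(rubisco), caps.maxC)]
    return cons, coupled


def _binding_signature(model: MetabolicModel, flux: dict[str, float], caps: ScanCaps,
                       condition: ConditionSpec, tol: float) -> frozenset:
    sig = set()
    if condition.glycerol_open and abs(flux.get(model.role("txGlycerol"), 0.0)) >= caps.maxG * (1 - tol):
        sig.add("G")
    if abs(flux.get(model.role("txPhoton"), 0.0)) >= caps.maxP * (1 - tol):
        sig.add("P")
    rub = abs(flux.get(model.role("Carboxylase"), 0.0))
    if "Oxygenase" in model.named_roles:
        rub += abs(flux.get(model.role("Oxygenase"), 0.0))
    if rub >= caps.maxC * (1 - tol):
        sig.add("C")
    return frozenset(sig)


def scan_demand(
    model: MetabolicModel,
    caps: ScanCaps,
    step: float = 0.25,
    condition: ConditionSpec | None = None,
    saturation_tol: float = SATURATION_TOL,
    lexicographic: bool = False,
    max_steps: int = 10_000,
) -> ScanResult:
    """Run the demand scan; see module docstring.

    The grid runs ``step, 2*step, ...`` up to the last feasible demand; the
    bisection-refined feasibility limit is appended as the final grid point
    (it is itself feasible), so the terminal flux pattern is recorded.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    condition = condition or STANDARD_CONDITIONS[0]  # mixotrophic + HCO3

    demands: list[float] = []
    objectives: list[float] = []
    fluxes: list[dict[str, float]] = []
    binding: list[frozenset] = []

    def solve(d):
        cons, coupled = _scan_constraints(model, caps, condition, d)
        return minimize_total_flux(model, cons, coupled, lexicographic=lexicographic)

    d = step
    last_feasible = 0.0
    first_infeasible = None
    for _ in range(max_steps):
        sol = solve(d)
        if sol.status != "optimal":
            first_infeasible = d
            break
        demands.append(d)
        objectives.append(sol.objective)
        fluxes.append(sol.flux)
        binding.append(_binding_signature(model, sol.flux, caps, condition, saturation_tol))
        last_feasible = d
        d += step

    if not demands:
        return ScanResult(
            demand_grid=np.array([]), flux_matrix=pd.DataFrame(),
            objective_curve=np.array([]), demand_max=0.0,
            caps=caps, condition=condition,
        )

    # refine the feasibility limit by bisection
    lo, hi = last_feasible, first_infeasible
    if hi is None:
        demand_max = last_feasible  # max_steps exhausted; report what we have
    else:
        while hi - lo > DEMAND_MAX_TOL:
            mid = 0.5 * (lo + hi)
            if solve(mid).status == "optimal":
                lo = mid
            else:
                hi = mid
        demand_max = lo
        if demand_max > last_feasible + DEMAND_MAX_TOL:
            sol = solve(demand_max)
            if sol.status == "optimal":
                demands.append(demand_max)
                objectives.append(sol.objective)
                fluxes.append(sol.flux)
                binding.append(
                    _binding_signature(model, sol.flux, caps, condition, saturation_tol)
                )

    rxn_ids = list(model.reactions)
    flux_matrix = pd.DataFrame(
        {d: [fx.get(r, 0.0) for r in rxn_ids] for d, fx in zip(demands, fluxes)},
        index=rxn_ids,
    )
    saturation_points: dict[str, float] = {}
    for cap_name in CAP_NAMES:
        for d, sig in zip(demands, binding):
            if cap_name in sig:
                saturation_points[cap_name] = d
                break
    return ScanResult(
        demand_grid=np.array(demands),
        flux_matrix=flux_matrix,
        objective_curve=np.array(objectives),
        demand_max=demand_max,
        caps=caps,
        condition=condition,
        saturation_points=saturation_points,
        binding=binding,
    )


def detect_regions(scan: ScanResult, tol: float = SATURATION_TOL) -> RegionLabels:
    """Segment the demand axis by binding-cap signature.

    Signatures must be nested (a cap never un-saturates as demand grows);
    a violation raises :class:`RegionError` naming the offending demands,
    which signals degenerate alternate optima — re-run the scan with
    ``lexicographic=True``.
    """
    if len(scan.demand_grid) == 0:
        raise ValueError("empty scan")
    labels = "ABCDEFGH"
    regions: list[Region] = []
    current_sig = None
    start = 0.0
    prev_d = 0.0
    for d, sig in zip(scan.demand_grid, scan.binding):
        if current_sig is not None and not sig >= current_sig:
            raise RegionError(
                f"cap signature {set(current_sig)} at demand {prev_d} "
                f"un-saturated to {set(sig)} at demand {d}"
            )
        if current_sig is None:
            current_sig = sig
        elif sig != current_sig:
            regions.append(Region(labels[len(regions)], start, prev_d, current_sig))
            start = prev_d
            current_sig = sig
        prev_d = d
    regions.append(Region(labels[len(regions)], start, scan.demand_max, current_sig))
    return RegionLabels(regions)


def classify_flux_patterns(
    scan: ScanResult,
    regions: RegionLabels | None = None,
    vary_tol: float | None = None,
) -> tuple[dict[tuple, list[str]], list[str]]:
    """Group varying reactions by the sign pattern of their per-region slopes.

    Returns ``(groups, varying)`` where ``groups`` maps a slope-sign tuple
    (one of -1/0/+1 per region) to the reactions showing it, and ``varying``
    lists all reactions whose flux range exceeds the variation threshold.
    Reactions in one linear chain carry proportional fluxes and land in the
    same group.
    """
    if len(scan.demand_grid) < 3:
        raise ValueError("need at least 3 grid points to classify response shapes")
    if vary_tol is None:
        vary_tol = 1e-6 * max(1.0, scan.demand_max)
    if regions is None:
        regions = detect_regions(scan)
    demands = scan.demand_grid
    varying: list[str] = []
    groups: dict[tuple, list[str]] = {}
    slope_tol = vary_tol
    for rid in scan.flux_matrix.index:
        traj = scan.flux_matrix.loc[rid].to_numpy()
        if traj.max() - traj.min() <= vary_tol:
            continue
        varying.append(rid)
        signs = []
        for region in regions:
            mask = (demands > region.start) & (demands <= region.end)
            pts = np.flatnonzero(mask)
            if len(pts) >= 2:
                slope = (traj[pts[-1]] - traj[pts[0]]) / (demands[pts[-1]] - demands[pts[0]])
            else:
                slope = 0.0
            signs.append(0 if abs(slope) <= slope_tol else (1 if slope > 0 else -1))
        groups.setdefault(tuple(signs), []).append(rid)
    return groups, varying


def convexity_defect(scan: ScanResult) -> float:
    """Most negative second difference of the objective curve on a uniform
    grid prefix (0 for a perfectly convex piecewise-linear curve)."""
    d, f = scan.demand_grid, scan.objective_curve
    if len(d) < 3:
        return 0.0
    # use only the uniform part of the grid (the appended demand_max point
    # generally breaks uniform spacing)
    steps = np.diff(d)
    n = len(d)
    if n >= 3 and not np.allclose(steps, steps[0]):
        n = len(steps[np.isclose(steps, steps[0])]) + 1
    dd = np.diff(d[:n])
    df = np.diff(f[:n])
    slopes = df / dd
    if len(slopes) < 2:
        return 0.0
    return float(min(np.diff(slopes).min(), 0.0))
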