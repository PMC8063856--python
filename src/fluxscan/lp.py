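"""L1 flux minimization.

The core operation solves

    minimize   sum_i |v_i|
    subject to N v = 0,  bounds,  user constraints (v_r = / <= / >= value),
               coupled caps (sum of |v| over a reaction group <= cap)

by splitting each flux into non-negative forward/backward parts
``v = p - n`` with unit objective weights, a standard reformulation that
keeps the problem a pure LP.  Among steady-state flux distributions meeting
the demand this selects the one with the least total enzyme commitment.

Two independent exact oracles are provided for testing: a rational
(Fraction-arithmetic) primal simplex usable on networks of toy size, and an
exhaustive basic-feasible-solution enumeration for very small systems.
Both are implemented without floats so their optima are exact.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import DEFAULT_BOUND, MetabolicModel, build_matrix

#: Primal/steady-state feasibility tolerance for all pass/fail decisions.
FEASIBILITY_TOL = 1e-9

#: Relative flux threshold below which a reaction is not counted as active.
SUPPORT_THRESHOLD = 1e-6


@dataclass(frozen=True)
class FluxConstraint:
    """A single linear constraint on one reaction's flux."""

    reaction_id: str
    relation: str  # "eq" | "le" | "ge"
    value: float

    def __post_init__(self):
        if self.relation not in ("eq", "le", "ge"):
            raise ValueError(f"unknown relation {self.relation!r}")


@dataclass(frozen=True)
class CoupledCap:
    """Cap on the summed absolute flux of a reaction group,
    e.g. carboxylase + oxygenase <= maxC for total rubisco capacity."""

    reaction_ids: tuple[str, ...]
    cap: float

    def __post_init__(self):
        object.__setattr__(self, "reaction_ids", tuple(self.reaction_ids))
        if self.cap < 0:
            raise ValueError("cap must be non-negative")


@dataclass
class FluxSolution:
    """Result of one L1-minimization solve."""

    flux: dict[str, float]
    objective: float
    status: str  # "optimal" | "infeasible" | "unbounded" | "error"
    support_threshold: float = SUPPORT_THRESHOLD

    @property
    def active_set(self) -> list[str]:
        return [r for r, v in self.flux.items() if abs(v) > self.support_threshold]

    def __getitem__(self, reaction_id: str) -> float:
        return self.flux[reaction_id]


def check_constraints(model: MetabolicModel, constraints: Iterable[FluxConstraint]) -> None:
    """Validate constraint references and reject conflicting equalities."""
    eq_seen: dict[str, float] = {}
    for con in constraints:
        if con.reaction_id not in model.reactions:
            raise KeyError(f"constraint references unknown reaction {con.reaction_id!r}")
        if con.relation == "eq":
            if con.reaction_id in eq_seen and eq_seen[con.reaction_id] != con.value:
                raise ValueError(
                    f"conflicting eq constraints on {con.reaction_id}: "
                    f"{eq_seen[con.reaction_id]} vs {con.value}"
                )
            eq_seen[con.reaction_id] = con.value


class _SplitProblem:
    """Shared split-variable construction used by both the float and exact solvers.

    Variables: for each reaction a forward part p in [max(0, lb), ub] and,
    when lb < 0, a backward part n in [0, -lb].
    """

    def __init__(
        self,
        model: MetabolicModel,
        constraints: Sequence[FluxConstraint],
        caps: Sequence[CoupledCap],
    ):
        check_constraints(model, constraints)
        self.model = model
        self.constraints = list(constraints)
        self.caps = list(caps)
        self.rxn_ids = list(model.reactions)
        self.pos_index: dict[str, int] = {}
        self.neg_index: dict[str, int] = {}
        self.var_bounds: list[tuple[float, float]] = []
        for rid in self.rxn_ids:
            rxn = model.reactions[rid]
            self.pos_index[rid] = len(self.var_bounds)
            self.var_bounds.append((max(0.0, rxn.lower_bound), max(0.0, rxn.upper_bound)))
            if rxn.lower_bound < 0:
                self.neg_index[rid] = len(self.var_bounds)
                self.var_bounds.append((max(0.0, -rxn.upper_bound), -rxn.lower_bound))
        self.n_vars = len(self.var_bounds)

    def flux_of(self, x: Sequence[float], rid: str):
        v = x[self.pos_index[rid]]
        if rid in self.neg_index:
            v = v - x[self.neg_index[rid]]
        return v


def minimize_total_flux(
    model: MetabolicModel,
    constraints: Sequence[FluxConstraint] = (),
    caps: Sequence[CoupledCap] = (),
    lexicographic: bool = False,
    support_threshold: float | None = None,
) -> FluxSolution:
    """Solve the L1 flux-minimization LP with the HiGHS backend.

    With ``lexicographic=True`` a deterministic refinement is applied after
    the optimum is found: holding the total flux at its optimal value, each
    reaction's absolute flux is minimized in turn in model order.  This
    resolves degenerate alternate optima into a reproducible vertex (the
    objective value itself is unique either way).
    """
    prob = _SplitProblem(model, constraints, caps)
    sm = build_matrix(model)

    n = prob.n_vars
    cost = np.ones(n)

    # steady state N (p - n) = 0
    rows, cols, vals = [], [], []
    coo = sm.matrix.tocoo()
    col_rxn = sm.reaction_ids
    for i, j, v in zip(coo.row, coo.col, coo.data):
        rid = col_rxn[j]
        rows.append(i)
        cols.append(prob.pos_index[rid])
        vals.append(v)
        if rid in prob.neg_index:
            rows.append(i)
            cols.append(prob.neg_index[rid])
            vals.append(-v)
    n_ss = sm.matrix.shape[0]

    eq_rows: list[dict[int, float]] = []
    eq_rhs: list[float] = []
    ub_rows: list[dict[int, float]] = []
    ub_rhs: list[float] = []

    for con in prob.constraints:
        row = {prob.pos_index[con.reaction_id]: 1.0}
        if con.reaction_id in prob.neg_index:
            row[prob.neg_index[con.reaction_id]] = -1.0
        if con.relation == "eq":
            eq_rows.append(row)
            eq_rhs.append(con.value)
        elif con.relation == "le":
            ub_rows.append(row)
            ub_rhs.append(con.value)
        else:  # ge  ->  -v <= -value
            ub_rows.append({k: -c for k, c in row.items()})
            ub_rhs.append(-con.value)

    for cap in prob.caps:
        row: dict[int, float] = {}
        for rid in cap.reaction_ids:
            if rid not in model.reactions:
                raise KeyError(f"cap references unknown reaction {rid!r}")
            row[prob.pos_index[rid]] = 1.0
            if rid in prob.neg_index:
                row[prob.neg_index[rid]] = 1.0
        ub_rows.append(row)
        ub_rhs.append(cap.cap)

    def _assemble(extra_eq=(), extra_eq_rhs=(), extra_ub=(), extra_ub_rhs=()):
        all_eq = eq_rows + list(extra_eq)
        A_eq_rows = rows + [n_ss + k for k, row in enumerate(all_eq) for _ in row]
        A_eq_cols = cols + [j for row in all_eq for j in row]
        A_eq_vals = vals + [c for row in all_eq for c in row.values()]
        A_eq = sparse.csr_matrix(
            (A_eq_vals, (A_eq_rows, A_eq_cols)), shape=(n_ss + len(all_eq), n)
        )
        b_eq = np.concatenate([np.zeros(n_ss), np.array(eq_rhs + list(extra_eq_rhs))])
        all_ub = ub_rows + list(extra_ub)
        if all_ub:
            A_ub = sparse.csr_matrix(
                (
                    [c for row in all_ub for c in row.values()],
                    (
                        [k for k, row in enumerate(all_ub) for _ in row],
                        [j for row in all_ub for j in row],
                    ),
                ),
                shape=(len(all_ub), n),
            )
            b_ub = np.array(ub_rhs + list(extra_ub_rhs))
        else:
            A_ub, b_ub = None, None
        return A_eq, b_eq, A_ub, b_ub

    def _solve(c, extra_ub=(), extra_ub_rhs=()):
        A_eq, b_eq, A_ub, b_ub = _assemble(extra_ub=extra_ub, extra_ub_rhs=extra_ub_rhs)
        return linprog(
            c,
            A_ub=A_ub,
            b_ub=b_ub,
            A_eq=A_eq,
            b_eq=b_eq,
            bounds=prob.var_bounds,
            method="highs",
            options={"presolve": True, "primal_feasibility_tolerance": FEASIBILITY_TOL,
                     "dual_feasibility_tolerance": FEASIBILITY_TOL},
        )

    res = _solve(cost)
    status = {0: "optimal", 1: "error", 2: "infeasible", 3: "unbounded", 4: "error"}.get(
        res.status, "error"
    )
    if status != "optimal":
        return FluxSolution(flux={}, objective=float("nan"), status=status)

    x = res.x
    objective = float(cost @ x)

    if lexicographic:
        # Freeze total flux at the optimum, then minimize each |v_i| in order.
        slack = max(1e-9, 1e-9 * objective)
        extra_ub = [ {j: 1.0 for j in range(n)} ]
        extra_rhs = [objective + slack]
        for rid in prob.rxn_ids:
            c2 = np.zeros(n)
            c2[prob.pos_index[rid]] = 1.0
            if rid in prob.neg_index:
                c2[prob.neg_index[rid]] = 1.0
            res2 = _solve(c2, extra_ub=extra_ub, extra_ub_rhs=extra_rhs)
            if res2.status != 0:
                break
            x = res2.x
            best = float(c2 @ x)
            row = {prob.pos_index[rid]: 1.0}
            if rid in prob.neg_index:
                row[prob.neg_index[rid]] = 1.0
            extra_ub.append(row)
            extra_rhs.append(best + slack)

    flux = {rid: float(prob.flux_of(x, rid)) for rid in prob.rxn_ids}
    objective = float(sum(abs(v) for v in flux.values()))
    demand_scale = max([1.0] + [abs(c.value) for c in prob.constraints])
    thr = support_threshold if support_threshold is not None else SUPPORT_THRESHOLD * demand_scale
    return FluxSolution(flux=flux, objective=objective, status="optimal", support_threshold=thr)


# ---------------------------------------------------------------------------
# Exact rational oracles (test-side; no floats)
# ---------------------------------------------------------------------------

@dataclass
class ExactResult:
    status: str
    objective: Fraction | None
    flux: dict[str, Fraction] = field(default_factory=dict)
    vertices: list[dict[str, Fraction]] = field(default_factory=list)


def _exact_standard_form(prob: _SplitProblem):
    """Build min c.x, A x = b, x >= 0 over Fractions.

    Finite non-default bounds and inequality constraints get slack columns;
    bounds at the default magnitude are treated as +inf (the L1 objective is
    bounded below regardless).
    """
    model = prob.model
    sm_index = {m: i for i, m in enumerate(model.internal_metabolite_ids)}
    n_ss = len(sm_index)
    ncols = prob.n_vars
    A: list[dict[int, Fraction]] = [dict() for _ in range(n_ss)]
    b: list[Fraction] = [Fraction(0)] * n_ss
    c: list[Fraction] = [Fraction(1)] * ncols

    def _col(rid: str) -> list[tuple[int, Fraction]]:
        return [(prob.pos_index[rid], Fraction(1))] + (
            [(prob.neg_index[rid], Fraction(-1))] if rid in prob.neg_index else []
        )

    for rid in prob.rxn_ids:
        rxn = model.reactions[rid]
        for met_id, coeff in rxn.stoichiometry.items():
            i = sm_index.get(met_id)
            if i is None:
                continue
            A[i][prob.pos_index[rid]] = A[i].get(prob.pos_index[rid], Fraction(0)) + coeff
            if rid in prob.neg_index:
                A[i][prob.neg_index[rid]] = A[i].get(prob.neg_index[rid], Fraction(0)) - coeff

    def _add_row(row: dict[int, Fraction], rhs: Fraction, slack_sign: int) -> None:
        nonlocal ncols
        row = dict(row)
        if slack_sign:
            row[ncols] = Fraction(slack_sign)
            c.append(Fraction(0))
            ncols += 1
        A.append(row)
        b.append(rhs)

    for con in prob.constraints:
        row = {j: s for j, s in _col(con.reaction_id)}
        rhs = Fraction(con.value).limit_denominator(10**9)
        if con.relation == "eq":
            _add_row(row, rhs, 0)
        elif con.relation == "le":
            _add_row(row, rhs, +1)
        else:
            _add_row(row, rhs, -1)

    for cap in prob.caps:
        row: dict[int, Fraction] = {}
        for rid in cap.reaction_ids:
            row[prob.pos_index[rid]] = Fraction(1)
            if rid in prob.neg_index:
                row[prob.neg_index[rid]] = Fraction(1)
        _add_row(row, Fraction(cap.cap).limit_denominator(10**9), +1)

    # finite (non-default) upper bounds on split variables
    for j, (lo, hi) in enumerate(prob.var_bounds):
        if lo > 0:
            raise NotImplementedError("exact oracle requires lower bounds <= 0 after splitting")
        if hi < DEFAULT_BOUND * (1 - 1e-12):
            _add_row({j: Fraction(1)}, Fraction(hi).limit_denominator(10**9), +1)

    return A, b, c, ncols


def _exact_simplex(A_rows, b, c, ncols):
    """Bland's-rule primal simplex on Fractions; returns (status, obj, x)."""
    m = len(A_rows)
    # dense tableau with artificial basis
    total = ncols + m
    T = [[Fraction(0)] * (total + 1) for _ in range(m)]
    for i, row in enumerate(A_rows):
        sign = 1 if b[i] >= 0 else -1
        for j, val in row.items():
            T[i][j] = val * sign
        T[i][ncols + i] = Fraction(1)
        T[i][total] = b[i] * sign
    basis = [ncols + i for i in range(m)]

    def pivot(pi, pj):
        piv = T[pi][pj]
        T[pi] = [v / piv for v in T[pi]]
        for i in range(m):
            if i != pi and T[i][pj] != 0:
                f = T[i][pj]
                T[i] = [a - f * bb for a, bb in zip(T[i], T[pi])]
        basis[pi] = pj

    def run(cost, allowed):
        while True:
            # reduced costs via basis cost vector
            cb = [cost[j] for j in basis]
            entering = -1
            for j in range(allowed):
                if j in basis:
                    continue
                red = cost[j] - sum(cb[i] * T[i][j] for i in range(m) if T[i][j] != 0)
                if red < 0:
                    entering = j  # Bland: first improving index
                    break
            if entering < 0:
                return "optimal"
            ratio_i = -1
            best = None
            for i in range(m):
                if T[i][entering] > 0:
                    r = T[i][total] / T[i][entering]
                    if best is None or r < best or (r == best and basis[i] < basis[ratio_i]):
                        best = r
                        ratio_i = i
            if ratio_i < 0:
                return "unbounded"
            pivot(ratio_i, entering)

    # Phase 1
    cost1 = [Fraction(0)] * ncols + [Fraction(1)] * m
    status = run(cost1, total)
    obj1 = sum(cost1[j] * T[i][total] for i, j in enumerate(basis))
    if obj1 != 0:
        return "infeasible", None, None
    # drive artificials out where possible
    for i in range(m):
        if basis[i] >= ncols:
            for j in range(ncols):
                if T[i][j] != 0:
                    pivot(i, j)
                    break

    cost2 = list(c) + [Fraction(0)] * m
    status = run(cost2, ncols)
    if status == "unbounded":
        return "unbounded", None, None
    x = [Fraction(0)] * ncols
    for i, j in enumerate(basis):
        if j < ncols:
            x[j] = T[i][total]
    obj = sum(c[j] * x[j] for j in range(ncols))
    return "optimal", obj, x


def exact_minimum(
    model: MetabolicModel,
    constraints: Sequence[FluxConstraint] = (),
    caps: Sequence[CoupledCap] = (),
) -> ExactResult:
    """Exact rational L1 minimum via Fraction-arithmetic simplex.

    Independent of the float path: same split-variable formulation, but all
    pivoting is done in exact rational arithmetic, so the returned objective
    is the true minimum of the LP (no solver tolerances involved).
    """
    prob = _SplitProblem(model, constraints, caps)
    A, b, c, ncols = _exact_standard_form(prob)
    status, obj, x = _exact_simplex(A, b, c, ncols)
    if status != "optimal":
        return ExactResult(status=status, objective=None)
    flux = {}
    for rid in prob.rxn_ids:
        v = x[prob.pos_index[rid]]
        if rid in prob.neg_index:
            v -= x[prob.neg_index[rid]]
        flux[rid] = v
    return ExactResult(status="optimal", objective=obj, flux=flux)


def enumerate_oracle(
    model: MetabolicModel,
    constraints: Sequence[FluxConstraint] = (),
    caps: Sequence[CoupledCap] = (),
    max_dim: int = 25,
    max_bases: int = 2_000_000,
) -> ExactResult:
    """Exhaustive enumeration of basic feasible solutions (tiny systems only).

    Every basis (column subset) of the standard-form polytope is solved
    exactly; the minimum objective over feasible bases is the LP optimum and
    all optimal vertices are returned.  Refuses systems whose split-variable
    dimension exceeds ``max_dim``.
    """
    prob = _SplitProblem(model, constraints, caps)
    if prob.n_vars > max_dim:
        raise ValueError(
            f"enumeration oracle refuses {prob.n_vars} split variables (> {max_dim}); "
            "use exact_minimum instead"
        )
    A, b, c, ncols = _exact_standard_form(prob)
    m = len(A)
    # drop all-zero rows (external-only balances never enter)
    keep = [i for i in range(m) if A[i] or b[i] != 0]
    A = [A[i] for i in keep]
    b = [b[i] for i in keep]
    m = len(A)
    if m > ncols:
        # more equalities than variables: rely on subsets of rows being redundant;
        # simplex handles this case instead.
        exact = exact_minimum(model, constraints, caps)
        return exact

    from itertools import combinations

    n_bases = 1
    k = min(m, ncols - m)
    for i in range(k):
        n_bases = n_bases * (ncols - i) // (i + 1)
    if n_bases > max_bases:
        raise ValueError(f"too many bases to enumerate ({n_bases} > {max_bases})")

    best: Fraction | None = None
    vertices: list[list[Fraction]] = []
    feasible = False
    for cols_subset in combinations(range(ncols), m):
        M = [[A[i].get(j, Fraction(0)) for j in cols_subset] for i in range(m)]
        sol = _solve_square(M, b)
        if sol is None or any(v < 0 for v in sol):
            continue
        feasible = True
        x = [Fraction(0)] * ncols
        for j, v in zip(cols_subset, sol):
            x[j] = v
        obj = sum(c[j] * x[j] for j in range(ncols))
        if best is None or obj < best:
            best = obj
            vertices = [x]
        elif obj == best and x not in vertices:
            vertices.append(x)

    if not feasible:
        return ExactResult(status="infeasible", objective=None)

    def _to_flux(x):
        out = {}
        for rid in prob.rxn_ids:
            v = x[prob.pos_index[rid]]
            if rid in prob.neg_index:
                v -= x[prob.neg_index[rid]]
            out[rid] = v
        return out

    return ExactResult(
        status="optimal",
        objective=best,
        flux=_to_flux(vertices[0]),
        vertices=[_to_flux(x) for x in vertices],
    )


def _solve_square(M, rhs):
    """Exact Gaussian elimination; None if singular."""
    n = len(M)
    M = [row[:] + [rhs[i]] for i, row in enumerate(M)]
    for col in range(n):
        piv = next((r for r in range(col, n) if M[r][col] != 0), None)
        if piv is None:
            return None
        M[col], M[piv] = M[piv], M[col]
        inv = M[col][col]
        M[col] = [v / inv for v in M[col]]
        for r in range(n):
            if r != col and M[r][col] != 0:
                f = M[r][col]
                M[r] = [a - f * bb for a, bb in zip(M[r], M[col])]
    return [M[i][n] for i in range(n)]
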