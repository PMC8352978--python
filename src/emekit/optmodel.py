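"""Backend-neutral LP/MILP container and solver contract.

Every other module emits :class:`Problem` objects — plain collections of
named variables and linear constraints — without naming a solver.  Two
open-source mixed-integer backends are supported out of the box:

* ``"highs"`` — HiGHS, through :func:`scipy.optimize.milp` (default);
* ``"glpk"`` — GLPK, through :mod:`optlang` (present whenever cobrapy is).

The models built here are MILPs solvable with conventional double-precision
solvers, so no special numeric machinery is needed beyond a feasibility
tolerance (1e-6 absolute) and a lexicographic fixing tolerance (1e-6
relative by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import scipy.optimize
import scipy.sparse

CONTINUOUS = "continuous"
BINARY = "binary"

LE, EQ, GE = "<=", "=", ">="
_SENSES = (LE, EQ, GE)

MAXIMIZE = "max"
MINIMIZE = "min"

#: absolute feasibility tolerance used when re-evaluating solutions
FEASIBILITY_TOL = 1e-6


class BackendError(RuntimeError):
    """Unknown or misconfigured solver backend."""


class ProblemError(ValueError):
    """Malformed problem (duplicate names, undeclared variables, ...)."""


class LexicographicError(RuntimeError):
    """A stage of a lexicographic cascade did not solve to optimality."""

    def __init__(self, stage: int, status: str):
        self.stage = stage
        self.status = status
        super().__init__(f"lexicographic stage {stage} ended with status '{status}'")


@dataclass
class Variable:
    name: str
    kind: str = CONTINUOUS
    lower: float = 0.0
    upper: float = math.inf

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUOUS, BINARY):
            raise ProblemError(f"unknown variable kind {self.kind!r}")
        if self.lower > self.upper:
            raise ProblemError(
                f"variable {self.name}: lower bound {self.lower} > upper {self.upper}"
            )
        if self.kind == BINARY and (self.lower < 0 or self.upper > 1):
            raise ProblemError(f"binary variable {self.name} must have bounds in [0, 1]")


@dataclass
class Constraint:
    terms: Dict[str, float]
    sense: str
    rhs: float
    label: str

    def __post_init__(self) -> None:
        if self.sense not in _SENSES:
            raise ProblemError(f"constraint {self.label}: unknown sense {self.sense!r}")
        if not any(c != 0.0 for c in self.terms.values()):
            raise ProblemError(f"constraint {self.label} has no nonzero coefficient")

    def violation(self, primal: Mapping[str, float]) -> float:
        """Signed violation of the constraint at a point (0 when satisfied)."""
        lhs = sum(c * primal[v] for v, c in self.terms.items())
        if self.sense == LE:
            return max(0.0, lhs - self.rhs)
        if self.sense == GE:
            return max(0.0, self.rhs - lhs)
        return abs(lhs - self.rhs)


@dataclass
class Solution:
    status: str  # optimal | infeasible | unbounded | limit
    objective_value: Optional[float]
    primal: Dict[str, float] = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.primal[name]


class Problem:
    """A MILP: named variables, linear constraints, one linear objective.

    Variables and constraints keep insertion order so solver behaviour is
    reproducible across runs.
    """

    def __init__(self, name: str = "problem"):
        self.name = name
        self.variables: Dict[str, Variable] = {}
        self.constraints: Dict[str, Constraint] = {}
        self.objective: Dict[str, float] = {}
        self.direction: str = MAXIMIZE

    # -- construction -------------------------------------------------
    def add_variable(
        self,
        name: str,
        lower: float = 0.0,
        upper: float = math.inf,
        kind: str = CONTINUOUS,
    ) -> str:
        if name in self.variables:
            raise ProblemError(f"duplicate variable name {name!r}")
        self.variables[name] = Variable(name, kind, lower, upper)
        return name

    def add_constraint(
        self, terms: Mapping[str, float], sense: str, rhs: float, label: str
    ) -> str:
        if label in self.constraints:
            raise ProblemError(f"duplicate constraint label {label!r}")
        terms = {v: float(c) for v, c in terms.items() if c != 0.0}
        for v in terms:
            if v not in self.variables:
                raise ProblemError(f"constraint {label} references unknown variable {v!r}")
        self.constraints[label] = Constraint(terms, sense, float(rhs), label)
        return label

    def set_objective(self, coeffs: Mapping[str, float], direction: str = MAXIMIZE) -> None:
        for v in coeffs:
            if v not in self.variables:
                raise ProblemError(f"objective references unknown variable {v!r}")
        if direction not in (MAXIMIZE, MINIMIZE):
            raise ProblemError(f"unknown objective direction {direction!r}")
        self.objective = {v: float(c) for v, c in coeffs.items() if c != 0.0}
        self.direction = direction

    def set_bounds(self, name: str, lower: float, upper: float) -> None:
        var = self.variables[name]
        if lower > upper:
            raise ProblemError(f"variable {name}: lower {lower} > upper {upper}")
        var.lower, var.upper = lower, upper

    def fix_variable(self, name: str, value: float) -> None:
        self.set_bounds(name, value, value)

    def copy(self) -> "Problem":
        clone = Problem(self.name)
        for v in self.variables.values():
            clone.variables[v.name] = Variable(v.name, v.kind, v.lower, v.upper)
        for c in self.constraints.values():
            clone.constraints[c.label] = Constraint(dict(c.terms), c.sense, c.rhs, c.label)
        clone.objective = dict(self.objective)
        clone.direction = self.direction
        return clone

    # -- inspection ---------------------------------------------------
    def max_violation(self, primal: Mapping[str, float]) -> float:
        """Largest absolute constraint/bound violation at a point."""
        worst = 0.0
        for c in self.constraints.values():
            worst = max(worst, c.violation(primal))
        for v in self.variables.values():
            x = primal[v.name]
            worst = max(worst, v.lower - x, x - v.upper)
        return worst

    def evaluate(self, terms: Mapping[str, float], primal: Mapping[str, float]) -> float:
        return sum(c * primal[v] for v, c in terms.items())


def count_binaries(problem: Problem) -> int:
    """Exact number of binary-kind decision variables in the problem."""
    return sum(1 for v in problem.variables.values() if v.kind == BINARY)


# ----------------------------------------------------------------------
# Solving
# ----------------------------------------------------------------------

BACKENDS = ("highs", "glpk")


def solve(
    problem: Problem,
    backend: str = "highs",
    time_limit: Optional[float] = None,
) -> Solution:
    """Solve a problem with the named backend.

    A hit time limit is reported as ``status="limit"``, not an exception;
    an unknown backend raises :class:`BackendError`.
    """
    if backend == "highs":
        return _solve_highs(problem, time_limit)
    if backend == "glpk":
        return _solve_glpk(problem, time_limit)
    raise BackendError(f"unknown backend {backend!r}; available: {BACKENDS}")


def _solve_highs(problem: Problem, time_limit: Optional[float]) -> Solution:
    names = list(problem.variables)
    index = {n: i for i, n in enumerate(names)}
    n = len(names)

    sign = -1.0 if problem.direction == MAXIMIZE else 1.0
    c = np.zeros(n)
    for v, coef in problem.objective.items():
        c[index[v]] = sign * coef

    lb = np.array([problem.variables[v].lower for v in names])
    ub = np.array([problem.variables[v].upper for v in names])
    integrality = np.array(
        [1 if problem.variables[v].kind == BINARY else 0 for v in names]
    )

    rows: List[int] = []
    cols: List[int] = []
    data: List[float] = []
    c_lo: List[float] = []
    c_hi: List[float] = []
    for i, con in enumerate(problem.constraints.values()):
        for v, coef in con.terms.items():
            rows.append(i)
            cols.append(index[v])
            data.append(coef)
        if con.sense == LE:
            c_lo.append(-math.inf)
            c_hi.append(con.rhs)
        elif con.sense == GE:
            c_lo.append(con.rhs)
            c_hi.append(math.inf)
        else:
            c_lo.append(con.rhs)
            c_hi.append(con.rhs)

    constraints = []
    if problem.constraints:
        a = scipy.sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(problem.constraints), n)
        )
        constraints = scipy.optimize.LinearConstraint(a, np.array(c_lo), np.array(c_hi))

    # presolve is disabled: with catalytic coefficients spanning ~1e9 h^-1
    # (unconstrained transporters) against ~1e-9 mmol/gDW concentrations,
    # HiGHS presolve can prune the true optimum on these MILPs; and the
    # feasibility tolerances are tightened because a default-tolerance
    # violation on a capacity row, multiplied by a large kcat, becomes a
    # visible phantom flux.  The instances are small enough that solving
    # unreduced at tight tolerances costs little.
    options: Dict[str, object] = {
        "output_flag": False,
        "presolve": False,
        "primal_feasibility_tolerance": 1e-9,
        "dual_feasibility_tolerance": 1e-9,
        "mip_feasibility_tolerance": 1e-9,
    }
    if time_limit is not None:
        options["time_limit"] = float(time_limit)

    import warnings as _warnings

    with _warnings.catch_warnings():
        # scipy warns that HiGHS-specific options are passed verbatim
        _warnings.simplefilter("ignore", RuntimeWarning)
        res = scipy.optimize.milp(
            c,
            constraints=constraints,
            integrality=integrality,
            bounds=scipy.optimize.Bounds(lb, ub),
            options=options,
        )

    if res.status == 0:
        primal = {v: float(res.x[i]) for i, v in enumerate(names)}
        return Solution("optimal", sign * float(res.fun), primal)
    if res.status == 1:
        return Solution("limit", None)
    if res.status == 2:
        return Solution("infeasible", None)
    if res.status == 3:
        return Solution("unbounded", None)
    return Solution("limit", None)


def _solve_glpk(problem: Problem, time_limit: Optional[float]) -> Solution:
    try:
        from optlang import glpk_interface as glpk
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise BackendError("glpk backend requires optlang with swiglpk") from exc

    model = glpk.Model(name=problem.name)
    ovars = {}
    for v in problem.variables.values():
        ovars[v.name] = glpk.Variable(
            v.name,
            lb=None if v.lower == -math.inf else v.lower,
            ub=None if v.upper == math.inf else v.upper,
            type="binary" if v.kind == BINARY else "continuous",
        )
    model.add(list(ovars.values()))
    model.update()
    cons = []
    for con in problem.constraints.values():
        expr = sum(coef * ovars[v] for v, coef in con.terms.items())
        if con.sense == LE:
            cons.append(glpk.Constraint(expr, ub=con.rhs, name=con.label))
        elif con.sense == GE:
            cons.append(glpk.Constraint(expr, lb=con.rhs, name=con.label))
        else:
            cons.append(glpk.Constraint(expr, lb=con.rhs, ub=con.rhs, name=con.label))
    model.add(cons)
    obj_expr = sum(coef * ovars[v] for v, coef in problem.objective.items())
    model.objective = glpk.Objective(obj_expr, direction=problem.direction)
    if time_limit is not None:
        model.configuration.timeout = max(1, int(time_limit))
    status = model.optimize()
    if status == "optimal":
        primal = {name: float(var.primal) for name, var in ovars.items()}
        return Solution("optimal", float(model.objective.value), primal)
    if status in ("infeasible", "integer_infeasible"):
        return Solution("infeasible", None)
    if status == "unbounded":
        return Solution("unbounded", None)
    return Solution("limit", None)


def lexicographic_solve(
    problem: Problem,
    objectives: Sequence[Tuple[Mapping[str, float], str]],
    rel_tol: float = 1e-6,
    backend: str = "highs",
    time_limit: Optional[float] = None,
) -> Tuple[Solution, List[float]]:
    """Optimize a cascade of objectives, fixing each optimum before the next.

    ``objectives`` is an ordered list of ``(coefficients, direction)``
    pairs.  After stage *i* reaches its optimum ``opt_i``, a constraint keeps
    it within ``rel_tol * |opt_i|`` (absolute ``rel_tol`` when ``opt_i`` is
    zero) while later stages run.  Returns the final solution and the list
    of per-stage optima.
    """
    if not objectives:
        raise ProblemError("lexicographic_solve needs at least one objective")
    if rel_tol < 0:
        raise ProblemError("rel_tol must be nonnegative")

    work = problem.copy()
    optima: List[float] = []
    solution: Optional[Solution] = None
    for stage, (coeffs, direction) in enumerate(objectives):
        work.set_objective(coeffs, direction)
        solution = solve(work, backend=backend, time_limit=time_limit)
        if solution.status != "optimal":
            raise LexicographicError(stage, solution.status)
        opt = solution.objective_value
        optima.append(opt)
        if stage < len(objectives) - 1:
            slack = rel_tol * abs(opt) if opt != 0 else rel_tol
            sense = GE if direction == MAXIMIZE else LE
            rhs = opt - slack if direction == MAXIMIZE else opt + slack
            work.add_constraint(coeffs, sense, rhs, f"lex_fix_stage_{stage}")
    assert solution is not None
    return solution, optima


# ----------------------------------------------------------------------
# LP-format export (debugging aid)
# ----------------------------------------------------------------------

def to_lp_string(problem: Problem) -> str:
    """Render the problem in CPLEX LP text format."""

    def term_str(terms: Mapping[str, float]) -> str:
        parts = []
        for v, c in terms.items():
            sign = "+" if c >= 0 else "-"
            parts.append(f"{sign} {abs(c):.17g} {v}")
        return " ".join(parts) if parts else "0"

    lines = ["Maximize" if problem.direction == MAXIMIZE else "Minimize"]
    lines.append(f" obj: {term_str(problem.objective)}")
    lines.append("Subject To")
    for con in problem.constraints.values():
        op = {LE: "<=", GE: ">=", EQ: "="}[con.sense]
        lines.append(f" {con.label}: {term_str(con.terms)} {op} {con.rhs:.17g}")
    lines.append("Bounds")
    for v in problem.variables.values():
        lo = "-inf" if v.lower == -math.inf else f"{v.lower:.17g}"
        hi = "+inf" if v.upper == math.inf else f"{v.upper:.17g}"
        lines.append(f" {lo} <= {v.name} <= {hi}")
    binaries = [v.name for v in problem.variables.values() if v.kind == BINARY]
    if binaries:
        lines.append("Binaries")
        lines.append(" " + " ".join(binaries))
    lines.append("End")
    return "\n".join(lines) + "\n"


def write_lp(problem: Problem, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_lp_string(problem))
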