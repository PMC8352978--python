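"""Model analyses: uptake scans, gene essentiality, chemostat curves.

Three reusable procedures sit on top of a built problem:

* growth-vs-uptake scans, which expose the proteome-limited growth plateau
  that separates expression-aware models from plain FBA;
* single-gene knockouts by blocking the gene's transcription flux, scored
  against experimental labels with the Matthews correlation coefficient;
* chemostat simulation of overflow metabolism: per growth rate, a
  lexicographic cascade (minimal substrate uptake, then minimal total flux,
  then minimal total enzyme) followed by the Chebyshev center of the enzyme
  space as a representative solution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .build import MEBuild
from .discretization import fix_growth_bin
from .optmodel import (
    GE,
    LE,
    MAXIMIZE,
    MINIMIZE,
    Problem,
    Solution,
    solve,
)


class AnalysisError(RuntimeError):
    pass


# ----------------------------------------------------------------------
# Growth vs uptake
# ----------------------------------------------------------------------

@dataclass
class UptakeScanPoint:
    uptake: float  # bound magnitude, mmol gDW^-1 h^-1
    mu: float  # optimal growth, h^-1 (0 when infeasible)
    status: str


def scan_growth_vs_uptake(
    problem: Problem,
    uptake_var: str,
    uptake_values: Sequence[float],
    mode: str = "bwd_ub",
    mu_var: str = "mu",
    backend: str = "highs",
    time_limit: Optional[float] = None,
) -> List[UptakeScanPoint]:
    """Maximize growth at each substrate uptake bound.

    ``mode="bwd_ub"`` treats ``uptake_var`` as a nonnegative backward
    (uptake) flux and sets its upper bound; ``mode="lower_neg"`` treats it
    as a signed exchange flux and sets its lower bound to -value.
    Infeasible points are recorded (mu = 0), not fatal.
    """
    points: List[UptakeScanPoint] = []
    for value in uptake_values:
        work = problem.copy()
        if mode == "bwd_ub":
            work.set_bounds(uptake_var, 0.0, value)
        elif mode == "lower_neg":
            work.set_bounds(uptake_var, -value, work.variables[uptake_var].upper)
        else:
            raise AnalysisError(f"unknown scan mode {mode!r}")
        work.set_objective({mu_var: 1.0}, MAXIMIZE)
        sol = solve(work, backend=backend, time_limit=time_limit)
        mu = sol.objective_value if sol.status == "optimal" else 0.0
        points.append(UptakeScanPoint(value, mu, sol.status))
    return points


def plateau_growth(points: Sequence[UptakeScanPoint]) -> float:
    """The scan's plateau growth rate: the maximum over the grid."""
    return max((p.mu for p in points), default=0.0)


# ----------------------------------------------------------------------
# Gene essentiality
# ----------------------------------------------------------------------

def knockout_gene(problem: Problem, gene: str) -> Problem:
    """Return a copy with every transcription flux of the gene blocked."""
    var = f"v_tr_{gene}"
    if var not in problem.variables:
        raise AnalysisError(f"gene {gene!r} has no transcription flux in this problem")
    work = problem.copy()
    work.fix_variable(var, 0.0)
    return work


def knockout_gene_fba(problem: Problem, model, gene: str) -> Problem:
    """FBA-side knockout: zero every reaction with no gene-rule escape.

    A reaction survives if at least one of its isozyme gene sets avoids the
    knocked-out gene; reactions without a GPR are untouched.  Works on the
    plain-FBA problem (single flux variable per reaction) and on split
    forward/backward problems.
    """
    from .core import parse_gpr

    if gene not in model.genes:
        raise AnalysisError(f"unknown gene {gene!r}")
    work = problem.copy()
    for rxn in model.reactions.values():
        isozymes = parse_gpr(rxn.gpr)
        if not isozymes:
            continue
        if all(gene in iso for iso in isozymes):
            for var in (rxn.id, f"v_fwd_{rxn.id}", f"v_bwd_{rxn.id}"):
                if var in work.variables:
                    work.fix_variable(var, 0.0)
    return work


@dataclass
class ConfusionMatrix:
    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be nonnegative")


def mcc(matrix: ConfusionMatrix) -> float:
    """Matthews correlation coefficient in [-1, 1].

    (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); a zero margin
    makes the coefficient undefined and returns 0 by convention (warned).
    """
    tp, fn, fp, tn = matrix.tp, matrix.fn, matrix.fp, matrix.tn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        warnings.warn("MCC undefined for a zero margin; returning 0")
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


@dataclass
class EssentialityResult:
    wild_type_mu: float
    threshold: float
    knockout_mu: Dict[str, float]
    predictions: Dict[str, bool]  # gene -> predicted essential
    matrix: Optional[ConfusionMatrix] = None

    @property
    def mcc(self) -> Optional[float]:
        return None if self.matrix is None else mcc(self.matrix)


def essentiality_screen(
    problem: Problem,
    genes: Iterable[str],
    labels: Optional[Mapping[str, bool]] = None,
    threshold: float = 0.1,
    mu_var: str = "mu",
    backend: str = "highs",
    time_limit: Optional[float] = None,
) -> EssentialityResult:
    """Single-gene knockout screen against the wild-type optimum.

    A gene is predicted essential when the knockout optimum drops below
    ``threshold * mu_wt`` (infeasible knockouts count as zero growth).
    When experimental ``labels`` are given, predictions are tallied into a
    confusion matrix with experimental truth on the rows.
    """
    wt = solve(problem, backend=backend, time_limit=time_limit)
    if wt.status != "optimal" or wt.objective_value <= 0:
        raise AnalysisError(
            f"wild-type optimum unavailable (status {wt.status}); screen undefined"
        )
    mu_wt = wt.objective_value

    ko_mu: Dict[str, float] = {}
    predictions: Dict[str, bool] = {}
    for gene in genes:
        sol = solve(knockout_gene(problem, gene), backend=backend,
                    time_limit=time_limit)
        mu = sol.objective_value if sol.status == "optimal" else 0.0
        ko_mu[gene] = mu
        predictions[gene] = mu < threshold * mu_wt

    matrix = None
    if labels is not None:
        matrix = ConfusionMatrix()
        for gene, predicted in predictions.items():
            if gene not in labels:
                continue
            actual = labels[gene]
            if actual and predicted:
                matrix.tp += 1
            elif actual and not predicted:
                matrix.fn += 1
            elif not actual and predicted:
                matrix.fp += 1
            else:
                matrix.tn += 1
    return EssentialityResult(mu_wt, threshold, ko_mu, predictions, matrix)


# ----------------------------------------------------------------------
# Chebyshev center
# ----------------------------------------------------------------------

def chebyshev_center(
    inequalities: Sequence[Tuple[Mapping[str, float], float]],
    backend: str = "highs",
) -> Tuple[Dict[str, float], float]:
    """Center and radius of the largest ball inside {x : a_i.x <= b_i}.

    Solves max r subject to a_i.x + ||a_i||_2 r <= b_i.  The polytope must
    be nonempty and bounded; an empty polytope raises.
    """
    if not inequalities:
        raise AnalysisError("empty inequality list")
    problem = Problem("chebyshev")
    names = sorted({v for terms, _ in inequalities for v in terms})
    for n in names:
        problem.add_variable(n, -math.inf, math.inf)
    r = problem.add_variable("cheb_radius", 0.0, math.inf)
    for i, (terms, rhs) in enumerate(inequalities):
        norm = math.sqrt(sum(c * c for c in terms.values()))
        row = dict(terms)
        row[r] = norm
        problem.add_constraint(row, LE, rhs, f"ineq_{i}")
    problem.set_objective({r: 1.0}, MAXIMIZE)
    sol = solve(problem, backend=backend)
    if sol.status != "optimal":
        raise AnalysisError(f"polytope is {sol.status}")
    center = {n: sol.primal[n] for n in names}
    return center, sol.primal[r]


def _inscribe_ball(problem: Problem, subset: Sequence[str]) -> str:
    """Add a radius variable inscribing a ball in the subset dimensions.

    Every inequality involving a subset variable gets +||a_subset|| r on the
    constrained side; finite bounds of subset variables become rows too.
    Equality constraints define the affine hull and are left untouched.
    Returns the radius variable name.
    """
    subset = [v for v in subset if v in problem.variables]
    sset = set(subset)
    r = problem.add_variable("cheb_radius", 0.0, math.inf)
    for con in list(problem.constraints.values()):
        norm = math.sqrt(
            sum(c * c for v, c in con.terms.items() if v in sset)
        )
        if norm == 0.0 or con.sense == "=":
            continue
        if con.sense == LE:
            con.terms[r] = con.terms.get(r, 0.0) + norm
        else:
            con.terms[r] = con.terms.get(r, 0.0) - norm
    for v in subset:
        var = problem.variables[v]
        if var.lower > -math.inf:
            problem.add_constraint({v: 1.0, r: -1.0}, GE, var.lower,
                                   f"cheb_lb_{v}")
        if var.upper < math.inf:
            problem.add_constraint({v: 1.0, r: 1.0}, LE, var.upper,
                                   f"cheb_ub_{v}")
    return r


# ----------------------------------------------------------------------
# Chemostat / overflow simulation
# ----------------------------------------------------------------------

@dataclass
class ChemostatPoint:
    mu_requested: float
    mu: float  # bin-snapped growth actually simulated
    status: str
    uptake: float = math.nan
    o2_uptake: float = math.nan
    co2_secretion: float = math.nan
    ethanol_secretion: float = math.nan
    stage_optima: List[float] = field(default_factory=list)
    chebyshev_radius: float = math.nan
    enzymes: Dict[str, float] = field(default_factory=dict)


DEFAULT_EXCHANGES = {
    "uptake": "v_bwd_EX_glc",
    "o2_uptake": "v_bwd_EX_o2",
    "co2_secretion": "v_fwd_EX_co2",
    "ethanol_secretion": "v_fwd_EX_etoh",
}


def chemostat_curve(
    build: MEBuild,
    mu_values: Sequence[float],
    exchanges: Optional[Mapping[str, str]] = None,
    rel_tol: float = 1e-6,
    backend: str = "highs",
    time_limit: Optional[float] = None,
    with_chebyshev: bool = True,
) -> List[ChemostatPoint]:
    """Simulate glucose-limited chemostat points over a growth-rate grid.

    Per requested growth rate (snapped to the nearest encodable bin value):
    stage 1 minimizes substrate uptake; stage 2, with the uptake fixed at
    its minimum, minimizes total flux (forward+backward sum, parsimonious);
    stage 3 minimizes total (non-dummy) enzyme concentration; stage 4 picks
    the Chebyshev center of the remaining enzyme space as the reported
    solution.  Infeasible growth rates are flagged and the scan continues.
    """
    exchanges = dict(exchanges or DEFAULT_EXCHANGES)
    uptake_var = exchanges["uptake"]
    flux_vars = build.metabolic_flux_variables()
    enzyme_vars = build.enzyme_variables(include_dummy=False)
    res = build.grid.resolution
    points: List[ChemostatPoint] = []

    for mu_req in mu_values:
        u = int(round(mu_req / res))
        u = max(0, min(build.grid.n_bins - 1, u))
        mu_snap = build.grid.bin_values[u]
        work = build.problem.copy()
        fix_growth_bin(work, build.encoding, u)
        point = ChemostatPoint(mu_req, mu_snap, "optimal")

        stages = [
            ({uptake_var: 1.0}, MINIMIZE),
            ({v: 1.0 for v in flux_vars}, MINIMIZE),
            ({v: 1.0 for v in enzyme_vars}, MINIMIZE),
        ]
        sol: Optional[Solution] = None
        failed = False
        for si, (coeffs, direction) in enumerate(stages):
            work.set_objective(coeffs, direction)
            sol = solve(work, backend=backend, time_limit=time_limit)
            if sol.status != "optimal":
                point.status = f"{sol.status}@stage{si + 1}"
                failed = True
                break
            opt = sol.objective_value
            point.stage_optima.append(opt)
            slack = rel_tol * abs(opt) if opt else rel_tol
            work.add_constraint(coeffs, LE, opt + slack, f"chemostat_fix_{si}")
        if failed:
            points.append(point)
            continue

        if with_chebyshev and enzyme_vars:
            r = _inscribe_ball(work, enzyme_vars)
            work.set_objective({r: 1.0}, MAXIMIZE)
            cheb = solve(work, backend=backend, time_limit=time_limit)
            if cheb.status == "optimal":
                sol = cheb
                point.chebyshev_radius = cheb.primal[r]

        assert sol is not None
        point.uptake = sol.primal.get(uptake_var, math.nan)
        point.o2_uptake = sol.primal.get(exchanges["o2_uptake"], math.nan)
        point.co2_secretion = sol.primal.get(exchanges["co2_secretion"], math.nan)
        point.ethanol_secretion = sol.primal.get(
            exchanges["ethanol_secretion"], math.nan
        )
        point.enzymes = {v: sol.primal[v] for v in enzyme_vars if v in sol.primal}
        points.append(point)
    return points


def critical_growth_rate(
    points: Sequence[ChemostatPoint], tol: float = 1e-6
) -> Optional[float]:
    """Lowest simulated growth rate with ethanol secretion above tolerance."""
    secreting = [
        p.mu for p in points
        if p.status == "optimal" and p.ethanol_secretion > tol
    ]
    return min(secreting) if secreting else None
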