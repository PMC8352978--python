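"""Growth discretization and exact MILP linearization of mu * X products.

Growth mu in [0, mu_max] is encoded with p = log2(N) binary digits,

    mu = mu_max * sum_k delta_k * 2^-k,   k = 1..p,

which makes mu take the N values u * mu_max / N for the bin index
u = sum_k 2^(p-k) delta_k.  A redundant one-hot indicator b_u per bin is
coupled to the digits through the integer equality sum_u u*b_u = u; digits
drive the bilinear products, indicators drive growth-dependent parameters
(bin-selected biomass composition).  Every product mu * X with X bounded
above is replaced by per-digit auxiliaries z_k = delta_k * X using the four
standard big-M inequalities, which is exact at feasible (integer) points —
the only approximation in the whole formulation is the growth resolution
mu_max / N itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence

import numpy as np

from .optmodel import BINARY, EQ, GE, LE, Problem, ProblemError


class DiscretizationError(ValueError):
    pass


@dataclass(frozen=True)
class GrowthGrid:
    mu_max: float  # h^-1, upper bound on growth
    n_bins: int  # N, power of two
    p: int  # log2(N) binary digits
    resolution: float  # mu_max / N, h^-1
    bin_centers: tuple  # (u + 1/2) * resolution, for parameter selection
    bin_values: tuple  # u * resolution, the encodable growth values


def make_grid(mu_max: float, n_bins: int) -> GrowthGrid:
    """Build a growth grid over [0, mu_max] with N = n_bins bins.

    N must be a power of two >= 2: the binary-digit encoding of the bin
    index requires it.
    """
    if mu_max <= 0:
        raise DiscretizationError("mu_max must be positive")
    if n_bins < 2 or (n_bins & (n_bins - 1)) != 0:
        raise DiscretizationError(f"N must be a power of two >= 2, got {n_bins}")
    p = int(round(math.log2(n_bins)))
    res = mu_max / n_bins
    centers = tuple((u + 0.5) * res for u in range(n_bins))
    values = tuple(u * res for u in range(n_bins))
    return GrowthGrid(mu_max, n_bins, p, res, centers, values)


@dataclass
class GrowthEncoding:
    grid: GrowthGrid
    mu_var: str
    digit_vars: List[str]  # delta_k, k = 1..p
    indicator_vars: List[str]  # b_u, u = 0..N-1
    n_products: int = 0  # running count of linearized products

    def digit_weights(self) -> Dict[str, float]:
        """Coefficients of mu = mu_max * sum 2^-k delta_k."""
        return {
            name: self.grid.mu_max * 2.0 ** -(k + 1)
            for k, name in enumerate(self.digit_vars)
        }


def encode_growth(problem: Problem, grid: GrowthGrid, mu_var: str = "mu") -> GrowthEncoding:
    """Attach the binary growth encoding to a problem.

    Adds p digit binaries, N one-hot bin indicators (N + p binaries total;
    128 bins give 135) and three coupling constraint families:

    * mu = mu_max * sum_k 2^-k delta_k
    * sum_u b_u = 1
    * sum_u u * b_u = sum_k 2^(p-k) delta_k

    May only be called once per problem.
    """
    if mu_var not in problem.variables:
        raise DiscretizationError(f"problem has no growth variable {mu_var!r}")
    if any(n.startswith("growth_digit_") for n in problem.variables):
        raise DiscretizationError("growth already encoded on this problem")

    digits = [
        problem.add_variable(f"growth_digit_{k}", 0, 1, BINARY)
        for k in range(1, grid.p + 1)
    ]
    indicators = [
        problem.add_variable(f"growth_bin_{u}", 0, 1, BINARY)
        for u in range(grid.n_bins)
    ]
    enc = GrowthEncoding(grid, mu_var, digits, indicators)

    terms = {mu_var: 1.0}
    terms.update({d: -w for d, w in enc.digit_weights().items()})
    problem.add_constraint(terms, EQ, 0.0, "growth_digit_sum")
    problem.set_bounds(mu_var, 0.0, grid.mu_max * (grid.n_bins - 1) / grid.n_bins)

    problem.add_constraint({b: 1.0 for b in indicators}, EQ, 1.0, "growth_bin_onehot")

    idx_terms: Dict[str, float] = {b: float(u) for u, b in enumerate(indicators) if u}
    for k, d in enumerate(digits, start=1):
        idx_terms[d] = idx_terms.get(d, 0.0) - 2.0 ** (grid.p - k)
    problem.add_constraint(idx_terms, EQ, 0.0, "growth_bin_index")
    return enc


@dataclass
class LinearizedTerm:
    source: str
    upper_bound: float
    aux_vars: List[str]  # z_k = delta_k * X
    expression: Dict[str, float]  # linear terms equal to mu * X


def linearize_product(
    problem: Problem, encoding: GrowthEncoding, x_var: str, x_ub: float, tag: str = ""
) -> LinearizedTerm:
    """Linearize mu * X exactly for a continuous X with finite bound x_ub.

    For each digit delta_k an auxiliary z_k is constrained to equal
    delta_k * X via

        z_k <= x_ub * delta_k,  z_k <= X,
        z_k >= X - x_ub * (1 - delta_k),  z_k >= 0,

    and the product is the linear expression mu_max * sum_k 2^-k z_k.
    """
    if not (x_ub >= 0) or math.isinf(x_ub):
        raise DiscretizationError(
            f"linearize_product needs a finite nonnegative bound for {x_var}, got {x_ub}"
        )
    if x_var not in problem.variables:
        raise ProblemError(f"unknown variable {x_var}")
    tag = tag or f"{x_var}_{encoding.n_products}"
    encoding.n_products += 1

    aux = []
    expression: Dict[str, float] = {}
    for k, digit in enumerate(encoding.digit_vars, start=1):
        z = problem.add_variable(f"z_{tag}_{k}", 0.0, x_ub)
        aux.append(z)
        problem.add_constraint({z: 1.0, digit: -x_ub}, LE, 0.0, f"lin_{tag}_{k}_ub_digit")
        problem.add_constraint({z: 1.0, x_var: -1.0}, LE, 0.0, f"lin_{tag}_{k}_ub_x")
        problem.add_constraint(
            {z: 1.0, x_var: -1.0, digit: -x_ub}, GE, -x_ub, f"lin_{tag}_{k}_lb"
        )
        expression[z] = encoding.grid.mu_max * 2.0 ** -k
    return LinearizedTerm(x_var, x_ub, aux, expression)


def select_by_bin(
    encoding: GrowthEncoding, values: Sequence[float]
) -> Dict[str, float]:
    """Growth-dependent parameter as the linear expression sum_u X_u * b_u.

    ``values`` holds one real per growth bin; with the one-hot constraint in
    force the expression evaluates to the active bin's value.
    """
    if len(values) != encoding.grid.n_bins:
        raise DiscretizationError(
            f"need {encoding.grid.n_bins} per-bin values, got {len(values)}"
        )
    return {
        b: float(v) for b, v in zip(encoding.indicator_vars, values) if v != 0.0
    }


def enumerate_digit_assignments(p: int) -> List[tuple]:
    """All 2^p digit vectors (delta_1..delta_p), for brute-force oracles."""
    out = []
    for u in range(2 ** p):
        out.append(tuple((u >> (p - k)) & 1 for k in range(1, p + 1)))
    return out


def fix_growth_bin(problem: Problem, encoding: GrowthEncoding, u: int) -> None:
    """Pin the encoding to bin u by fixing digits and indicators (in place)."""
    p = encoding.grid.p
    if not 0 <= u < encoding.grid.n_bins:
        raise DiscretizationError(f"bin index {u} out of range")
    for k, d in enumerate(encoding.digit_vars, start=1):
        problem.fix_variable(d, float((u >> (p - k)) & 1))
    for v, b in enumerate(encoding.indicator_vars):
        problem.fix_variable(b, 1.0 if v == u else 0.0)
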