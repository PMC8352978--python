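"""Growth-grid, binary encoding, and product-linearization tests."""

import math

import pytest

from emekit.discretization import (
    DiscretizationError,
    encode_growth,
    enumerate_digit_assignments,
    fix_growth_bin,
    linearize_product,
    make_grid,
    select_by_bin,
)
from emekit.optmodel import EQ, Problem, count_binaries, solve


def _problem_with_mu(mu_max=0.75):
    p = Problem()
    p.add_variable("mu", 0.0, mu_max)
    return p


# ----------------------------------------------------------------------
# Grid construction
# ----------------------------------------------------------------------

def test_study_scale_grid():
    grid = make_grid(0.75, 128)
    assert grid.p == 7
    assert grid.resolution == pytest.approx(0.75 / 128)
    # 0.005859... is reported as 0.0058 at two significant figures
    # (truncated at the printed precision)
    assert int(grid.resolution * 1e4) == 58


@pytest.mark.parametrize(
    "mu_max,n,p,res",
    [(1.0, 2, 1, 0.5), (0.75, 64, 6, 0.75 / 64), (0.75, 8, 3, 0.09375)],
)
def test_grid_parameters(mu_max, n, p, res):
    grid = make_grid(mu_max, n)
    assert grid.p == p
    assert grid.resolution == pytest.approx(res)
    assert grid.bin_centers[0] == pytest.approx(0.5 * res)
    assert grid.bin_values[-1] == pytest.approx((n - 1) * res)


@pytest.mark.parametrize("bad_n", [0, 1, 3, 12, 100])
def test_non_power_of_two_rejected(bad_n):
    with pytest.raises(DiscretizationError):
        make_grid(0.75, bad_n)


# ----------------------------------------------------------------------
# Binary encoding
# ----------------------------------------------------------------------

@pytest.mark.parametrize("n,expected", [(2, 3), (8, 11), (128, 135)])
def test_binary_count_is_n_plus_p(n, expected):
    p = _problem_with_mu()
    encode_growth(p, make_grid(0.75, n))
    assert count_binaries(p) == expected


def test_double_encoding_rejected():
    p = _problem_with_mu()
    encode_growth(p, make_grid(0.75, 4))
    with pytest.raises(DiscretizationError):
        encode_growth(p, make_grid(0.75, 4))


@pytest.mark.parametrize("p_digits", [2, 3, 4])
def test_every_digit_assignment_yields_its_growth_value(p_digits):
    """Exhaustive check: fixing digits forces mu = mu_max * sum(delta 2^-k)."""
    n = 2 ** p_digits
    grid = make_grid(0.8, n)
    for digits in enumerate_digit_assignments(p_digits):
        prob = _problem_with_mu(0.8)
        enc = encode_growth(prob, grid)
        for name, d in zip(enc.digit_vars, digits):
            prob.fix_variable(name, float(d))
        expected = 0.8 * sum(d * 2.0 ** -(k + 1) for k, d in enumerate(digits))
        prob.set_objective({"mu": 1.0}, "max")
        hi = solve(prob)
        prob.set_objective({"mu": 1.0}, "min")
        lo = solve(prob)
        assert hi.status == lo.status == "optimal"
        assert hi.objective_value == pytest.approx(expected, abs=1e-9)
        assert lo.objective_value == pytest.approx(expected, abs=1e-9)
        # indicators select the matching bin
        u = sum(d * 2 ** (p_digits - k) for k, d in enumerate(digits, start=1))
        assert hi.primal[enc.indicator_vars[u]] == pytest.approx(1.0, abs=1e-6)


# ----------------------------------------------------------------------
# Product linearization
# ----------------------------------------------------------------------

def test_linearized_product_forced_by_digits():
    grid = make_grid(1.0, 4)
    prob = _problem_with_mu(1.0)
    enc = encode_growth(prob, grid)
    prob.add_variable("X", 0.0, 10.0)
    term = linearize_product(prob, enc, "X", 10.0, tag="X")
    prob.fix_variable("X", 3.0)
    # digits (1, 0): mu = 0.5, product must evaluate to 0.5 * 3
    prob.fix_variable(enc.digit_vars[0], 1.0)
    prob.fix_variable(enc.digit_vars[1], 0.0)
    prob.set_objective({"mu": 1.0}, "max")
    sol = solve(prob)
    value = sum(c * sol.primal[v] for v, c in term.expression.items())
    assert value == pytest.approx(0.5 * 3.0, abs=1e-8)
    assert sol.primal[term.aux_vars[0]] == pytest.approx(3.0, abs=1e-8)
    assert sol.primal[term.aux_vars[1]] == pytest.approx(0.0, abs=1e-8)


def test_linearized_product_zero_x():
    grid = make_grid(1.0, 4)
    for u in range(4):
        prob = _problem_with_mu(1.0)
        enc = encode_growth(prob, grid)
        prob.add_variable("X", 0.0, 5.0)
        term = linearize_product(prob, enc, "X", 5.0, tag="X")
        prob.fix_variable("X", 0.0)
        fix_growth_bin(prob, enc, u)
        prob.set_objective({"mu": 1.0}, "max")
        sol = solve(prob)
        value = sum(c * sol.primal[v] for v, c in term.expression.items())
        assert value == pytest.approx(0.0, abs=1e-9)


def test_linearization_exact_on_grid_and_bounded_off_grid():
    """Sweep all bins at p = 3: the linearized product equals the encoded
    mu times X exactly, and the encoded mu is within one resolution step of
    any continuous growth rate (the scheme's only approximation)."""
    grid = make_grid(0.75, 8)
    for u in range(8):
        for x in (0.0, 1.7, 4.0):
            prob = _problem_with_mu(0.75)
            enc = encode_growth(prob, grid)
            prob.add_variable("X", 0.0, 4.0)
            term = linearize_product(prob, enc, "X", 4.0, tag="X")
            prob.fix_variable("X", x)
            fix_growth_bin(prob, enc, u)
            prob.set_objective({"mu": 1.0}, "max")
            sol = solve(prob)
            mu_enc = sol.primal["mu"]
            value = sum(c * sol.primal[v] for v, c in term.expression.items())
            assert value == pytest.approx(mu_enc * x, abs=1e-8)
    # off-grid growth rates round down by less than one bin width
    for mu_cont in (0.01, 0.2, 0.44, 0.6):
        u = int(mu_cont / grid.resolution)
        assert abs(grid.bin_values[u] - mu_cont) <= 0.75 * 2.0 ** -3 + 1e-12


def test_unbounded_x_rejected():
    prob = _problem_with_mu()
    enc = encode_growth(prob, make_grid(0.75, 4))
    prob.add_variable("X", 0.0, math.inf)
    with pytest.raises(DiscretizationError):
        linearize_product(prob, enc, "X", math.inf)


# ----------------------------------------------------------------------
# Bin-selected parameters
# ----------------------------------------------------------------------

def test_select_by_bin_constant_and_onehot():
    prob = _problem_with_mu()
    enc = encode_growth(prob, make_grid(0.75, 8))
    const = select_by_bin(enc, [2.5] * 8)
    for u in range(8):
        point = {b: 1.0 if v == u else 0.0 for v, b in enumerate(enc.indicator_vars)}
        assert sum(c * point[v] for v, c in const.items()) == pytest.approx(2.5)
    values = [0.1 * u for u in range(8)]
    expr = select_by_bin(enc, values)
    point = {b: 1.0 if v == 3 else 0.0 for v, b in enumerate(enc.indicator_vars)}
    assert sum(c * point.get(v, 0.0) for v, c in expr.items()) == pytest.approx(0.3)


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=100)
@given(st.integers(min_value=0, max_value=63), st.floats(0.05, 2.0))
def test_bin_index_roundtrips_through_digits(u, mu_max):
    """For any bin u, the digit expansion reproduces both the growth value
    u * mu_max / N and the index u (the two encoding couplings agree)."""
    grid = make_grid(mu_max, 64)
    digits = [(u >> (grid.p - k)) & 1 for k in range(1, grid.p + 1)]
    mu = mu_max * sum(d * 2.0 ** -(k + 1) for k, d in enumerate(digits))
    assert mu == pytest.approx(grid.bin_values[u], rel=1e-12, abs=1e-15)
    assert sum(d * 2 ** (grid.p - k) for k, d in enumerate(digits, 1)) == u


def test_select_by_bin_length_mismatch():
    prob = _problem_with_mu()
    enc = encode_growth(prob, make_grid(0.75, 8))
    with pytest.raises(DiscretizationError):
        select_by_bin(enc, [1.0] * 7)
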