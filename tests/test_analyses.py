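"""Analysis-procedure tests: MCC, Chebyshev center, knockouts, cascades."""

import math
import random

import pytest

from emekit import (
    BuildConfig,
    ConfusionMatrix,
    build_fba,
    build_me_problem,
    chebyshev_center,
    chemostat_curve,
    essentiality_screen,
    knockout_gene,
    knockout_gene_fba,
    lexicographic_solve,
    mcc,
    scan_growth_vs_uptake,
    solve,
)
from emekit.analyses import AnalysisError
from emekit.discretization import fix_growth_bin
from emekit.optmodel import LE, MINIMIZE


# ----------------------------------------------------------------------
# Matthews correlation coefficient
# ----------------------------------------------------------------------

def test_mcc_perfect_predictions():
    assert mcc(ConfusionMatrix(tp=10, fn=0, fp=0, tn=20)) == pytest.approx(1.0)


def test_mcc_zero_margin_warns_and_returns_zero():
    with pytest.warns(UserWarning):
        assert mcc(ConfusionMatrix(tp=0, fn=0, fp=0, tn=5)) == 0.0


def test_mcc_agrees_with_sklearn_on_random_matrices():
    """Cross-check the closed form against scikit-learn's implementation on
    expanded label vectors, for 1000 random confusion matrices."""
    from sklearn.metrics import matthews_corrcoef

    rng = random.Random(42)
    for _ in range(1000):
        tp, fn, fp, tn = (rng.randint(0, 30) for _ in range(4))
        if min(tp + fp, tp + fn, tn + fp, tn + fn) == 0:
            continue
        y_true = [1] * (tp + fn) + [0] * (fp + tn)
        y_pred = [1] * tp + [0] * fn + [1] * fp + [0] * tn
        expected = matthews_corrcoef(y_true, y_pred)
        assert mcc(ConfusionMatrix(tp, fn, fp, tn)) == pytest.approx(
            expected, abs=1e-12
        )


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        ConfusionMatrix(tp=-1, fn=0, fp=0, tn=0)


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=200)
@given(st.tuples(*[st.integers(min_value=0, max_value=500)] * 4))
def test_mcc_stays_in_unit_interval(counts):
    tp, fn, fp, tn = counts
    if min(tp + fp, tp + fn, tn + fp, tn + fn) == 0:
        return
    value = mcc(ConfusionMatrix(tp, fn, fp, tn))
    assert -1.0 - 1e-12 <= value <= 1.0 + 1e-12


# ----------------------------------------------------------------------
# Chebyshev center
# ----------------------------------------------------------------------

def test_chebyshev_center_unit_square():
    ineqs = [
        ({"x": 1.0}, 1.0), ({"x": -1.0}, 0.0),
        ({"y": 1.0}, 1.0), ({"y": -1.0}, 0.0),
    ]
    center, radius = chebyshev_center(ineqs)
    assert center["x"] == pytest.approx(0.5, abs=1e-6)
    assert center["y"] == pytest.approx(0.5, abs=1e-6)
    assert radius == pytest.approx(0.5, abs=1e-6)


def test_chebyshev_center_degenerate_point():
    ineqs = [({"x": 1.0}, 2.0), ({"x": -1.0}, -2.0)]
    center, radius = chebyshev_center(ineqs)
    assert center["x"] == pytest.approx(2.0, abs=1e-6)
    assert radius == pytest.approx(0.0, abs=1e-6)


def test_chebyshev_center_empty_polytope_raises():
    with pytest.raises(AnalysisError):
        chebyshev_center([({"x": 1.0}, 0.0), ({"x": -1.0}, -1.0)])


def test_chebyshev_center_random_polytopes_satisfy_slack():
    rng = random.Random(3)
    for _ in range(10):
        ineqs = [({"x": 1.0}, 5.0), ({"x": -1.0}, 5.0),
                 ({"y": 1.0}, 5.0), ({"y": -1.0}, 5.0)]
        for _ in range(6):
            a = {"x": rng.uniform(-1, 1), "y": rng.uniform(-1, 1)}
            b = rng.uniform(0.5, 3.0)
            ineqs.append((a, b))
        center, radius = chebyshev_center(ineqs)
        assert radius >= 0.0
        for terms, rhs in ineqs:
            lhs = sum(c * center[v] for v, c in terms.items())
            norm = math.sqrt(sum(c * c for c in terms.values()))
            assert rhs - lhs >= radius * norm - 1e-6


# ----------------------------------------------------------------------
# Scans and knockouts
# ----------------------------------------------------------------------

def test_scan_growth_monotone_in_uptake(me_build):
    points = scan_growth_vs_uptake(
        me_build.problem, "v_bwd_EX_glc", [1.0, 2.0, 4.0, 8.0]
    )
    mus = [p.mu for p in points]
    assert all(b >= a - 1e-9 for a, b in zip(mus, mus[1:]))


def test_unknown_gene_knockout_raises(me_build):
    with pytest.raises(AnalysisError):
        knockout_gene(me_build.problem, "g_nonexistent")


def test_essential_and_isozyme_knockouts(me_build, me_solution):
    mu_wt = me_solution.objective_value
    # sole gene on the biomass path (amino-acid synthesis): essential
    ko = solve(knockout_gene(me_build.problem, "g_aa"))
    assert (ko.objective_value or 0.0) < 0.1 * mu_wt
    # one glycolysis isozyme: the other carries the flux
    ko = solve(knockout_gene(me_build.problem, "g_glyA"))
    assert ko.objective_value >= 0.1 * mu_wt
    # ribosomal peptide of variant A only: variant B still translates
    ko = solve(knockout_gene(me_build.problem, "g_rpA"))
    assert ko.objective_value >= 0.1 * mu_wt


def test_screen_requires_positive_wild_type(me_build):
    dead = me_build.problem.copy()
    dead.set_bounds("v_bwd_EX_glc", 0.0, 0.0)
    dead.set_bounds("v_fwd_NGAM", 0.0, 1000.0)
    with pytest.raises(AnalysisError):
        essentiality_screen(dead, ["g_aa"])


def test_threshold_one_marks_any_growth_reduction_essential(me_build):
    res_low = essentiality_screen(me_build.problem, ["g_fer"], threshold=0.1)
    res_high = essentiality_screen(me_build.problem, ["g_fer"], threshold=1.0)
    # knocking out fermentation reduces growth below wild type but not to zero
    assert not res_low.predictions["g_fer"]
    assert res_high.predictions["g_fer"]


def test_fba_and_me_essentiality_coincide_for_metabolic_genes(
    toy_doc, me_build, me_solution
):
    """Purely metabolic knockouts classify identically under FBA and the
    expression-aware build."""
    metabolic_genes = [
        "g_glt", "g_glyA", "g_glyB", "g_fer", "g_respN", "g_respM",
        "g_aa", "g_ntp", "g_carb", "g_lip",
    ]
    fba = build_fba(toy_doc.model)
    mu_fba = solve(fba).objective_value
    mu_me = me_solution.objective_value
    for gene in metabolic_genes:
        fba_mu = solve(knockout_gene_fba(fba, toy_doc.model, gene)).objective_value or 0.0
        me_mu = solve(knockout_gene(me_build.problem, gene)).objective_value or 0.0
        assert (fba_mu < 0.1 * mu_fba) == (me_mu < 0.1 * mu_me), gene


# ----------------------------------------------------------------------
# Chemostat cascade
# ----------------------------------------------------------------------

def test_lexicographic_matches_manual_chaining(me_build):
    """The three-stage chemostat cascade reproduces manually chained solves
    with explicit fixing constraints."""
    work = me_build.problem.copy()
    fix_growth_bin(work, me_build.encoding, 2)
    flux_vars = me_build.metabolic_flux_variables()
    enz_vars = me_build.enzyme_variables()
    objectives = [
        ({"v_bwd_EX_glc": 1.0}, MINIMIZE),
        ({v: 1.0 for v in flux_vars}, MINIMIZE),
        ({v: 1.0 for v in enz_vars}, MINIMIZE),
    ]
    lex_sol, lex_opt = lexicographic_solve(work, objectives, rel_tol=1e-6)

    manual = work.copy()
    manual_opt = []
    for i, (coeffs, direction) in enumerate(objectives):
        manual.set_objective(coeffs, direction)
        sol = solve(manual)
        assert sol.status == "optimal"
        manual_opt.append(sol.objective_value)
        slack = 1e-6 * abs(sol.objective_value) or 1e-6
        manual.add_constraint(coeffs, LE, sol.objective_value + slack, f"fix{i}")
    for a, b in zip(lex_opt, manual_opt):
        assert a == pytest.approx(b, rel=1e-5, abs=1e-8)
    assert lex_sol.primal["v_bwd_EX_glc"] == pytest.approx(
        sol.primal["v_bwd_EX_glc"], rel=1e-5, abs=1e-7
    )


def test_chemostat_minimum_uptake_at_zero_growth_covers_maintenance(me_build):
    """At mu = 0 the minimal uptake is exactly the maintenance-driven one."""
    points = chemostat_curve(me_build, [0.0], with_chebyshev=False)
    assert points[0].status == "optimal"
    # NGAM = 1 mmol ATP/h via respiration (~31 ATP per glucose): uptake is
    # small but strictly positive
    assert 0.0 < points[0].uptake < 0.2


def test_chemostat_points_record_exchanges(me_build):
    points = chemostat_curve(me_build, [0.2], with_chebyshev=False)
    p = points[0]
    assert p.status == "optimal"
    assert p.mu == pytest.approx(0.1875)
    assert p.o2_uptake > 0.0
    assert p.co2_secretion > 0.0
    assert len(p.stage_optima) == 3


def test_chemostat_infeasible_growth_flagged_not_fatal(me_build):
    points = chemostat_curve(me_build, [0.7, 0.2], with_chebyshev=False)
    assert points[0].status != "optimal"
    assert points[1].status == "optimal"
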