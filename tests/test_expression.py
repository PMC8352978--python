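"""Expression-layer tests: stoichiometry, capacities, dummy protein."""

import pytest

from emekit import BuildConfig, build_me_problem, solve
from emekit.expression import (
    DEFAULT_KCAT_PER_H,
    TRANSPORTER_KCAT_PER_H,
    Enzyme,
    effective_kcats,
)


def test_default_kcat_policy():
    enz = Enzyme("e", {"p": 1.0})
    fwd, bwd = effective_kcats(enz, is_transporter=False)
    assert fwd == pytest.approx(70.9 * 3600.0)  # median turnover, per hour
    assert bwd == fwd
    fwd_t, _ = effective_kcats(enz, is_transporter=True)
    assert fwd_t == TRANSPORTER_KCAT_PER_H == 1e9
    enz2 = Enzyme("e2", {"p": 1.0}, kcat_fwd=100.0, kcat_bwd=40.0)
    assert effective_kcats(enz2, False) == (100.0, 40.0)


def test_translation_consumes_two_gtp_per_amino_acid(me_build):
    """Eq-8 stoichiometry: a peptide of length L costs 2L GTP (+2L H2O)."""
    prob = me_build.problem
    gtp_balance = prob.constraints["mass_balance_gtp_c"]
    for pep in me_build.network.peptides.values():
        coef = gtp_balance.terms[f"v_tl_{pep.id}"]
        assert coef == pytest.approx(-2.0 * pep.length_aa)
        h2o = prob.constraints["mass_balance_h2o_c"].terms[f"v_tl_{pep.id}"]
        assert h2o == pytest.approx(-2.0 * pep.length_aa)
        gdp = prob.constraints["mass_balance_gdp_c"].terms[f"v_tl_{pep.id}"]
        assert gdp == pytest.approx(2.0 * pep.length_aa)


def test_transcription_consumes_nucleotide_counts(me_build):
    prob = me_build.problem
    net = me_build.network
    t = net.transcripts["mrna_g_fer"]
    for base, met in net.ntp_map.items():
        coef = prob.constraints[f"mass_balance_{met}"].terms.get("v_tr_g_fer", 0.0)
        # transcription consumes exactly the transcript's base counts
        # (other fluxes touching the pool have their own columns)
        assert coef == pytest.approx(-t.nt_counts[base])


def test_complexation_consumes_copy_numbers(me_build):
    """The respiratory complex (2 nuclear + 1 mitochondrial peptide) drains
    its peptides at their copy numbers."""
    prob = me_build.problem
    bal_n = prob.constraints["balance_pep_pep_respN"]
    bal_m = prob.constraints["balance_pep_pep_respM"]
    assert bal_n.terms["v_cplx_resp"] == pytest.approx(-2.0)
    assert bal_m.terms["v_cplx_resp"] == pytest.approx(-1.0)


def test_catalytic_constraint_sums_isozymes(me_build):
    """v <= sum_j kcat_j E_j for the two glycolysis isozymes."""
    con = me_build.problem.constraints["catalytic_fwd_GLYC"]
    net = me_build.network
    assert con.terms["v_fwd_GLYC"] == 1.0
    assert con.terms["E_glyA"] == pytest.approx(-net.enzymes["glyA"].kcat_fwd)
    assert con.terms["E_glyB"] == pytest.approx(-net.enzymes["glyB"].kcat_fwd)
    assert con.sense == "<="
    assert con.rhs == 0.0


def test_transporter_effectively_uncapped(me_build):
    con = me_build.problem.constraints["catalytic_fwd_T_glc"]
    assert con.terms["E_glt"] == pytest.approx(-1e9)


def test_uncatalyzed_reactions_left_unconstrained(me_build):
    # NDK and DNASYN carry no GPR: no catalytic rows exist for them
    labels = me_build.problem.constraints
    assert "catalytic_fwd_NDK" not in labels
    assert "catalytic_fwd_DNASYN" not in labels


def test_dummy_excluded_from_catalytic_constraints(me_build):
    for label, con in me_build.problem.constraints.items():
        if label.startswith("catalytic_"):
            assert "E_dummy_protein" not in con.terms


def test_dummy_protein_holds_unmodeled_proteome_fraction(me_build, me_solution):
    """With phi = 0.55, the dummy protein carries (1 - phi) of P^m at any
    feasible optimum (forced by the total and modeled protein equalities)."""
    net = me_build.network
    dummy_mass = me_solution.primal["E_dummy_protein"] * net.enzymes[
        "dummy_protein"
    ].mw(net.peptides) + me_solution.primal["PEP_dummy"] * net.peptides["dummy"].mw
    p_m = me_build.allocation.reference_fractions["protein"]
    assert dummy_mass == pytest.approx(0.45 * p_m, rel=1e-5)


def test_phi_one_forces_dummy_to_zero(toy_doc):
    me = build_me_problem(
        toy_doc.model, toy_doc.network, BuildConfig(n_bins=8, phi=1.0)
    )
    sol = solve(me.problem)
    assert sol.status == "optimal"
    assert sol.primal["E_dummy_protein"] == pytest.approx(0.0, abs=1e-8)


def test_machinery_conservation_at_optimum(me_build, me_solution):
    """Assigned + free machinery equals the machinery concentration, per
    polymerase and per ribosome variant."""
    p = me_solution.primal
    for mach_id, mach in me_build.network.machinery.items():
        prefix = "POLA_" if mach.kind == "rna_polymerase" else "RIBA_"
        free = ("POL_free_" if mach.kind == "rna_polymerase" else "RIB_free_")
        assigned = sum(
            v for k, v in p.items() if k.startswith(f"{prefix}{mach_id}_")
        )
        assert assigned + p[free + mach_id] == pytest.approx(
            p[f"M_{mach_id}"], abs=1e-7
        )


def test_blocking_mito_polymerase_zeroes_only_mito_transcripts(me_build):
    work = me_build.problem.copy()
    work.fix_variable("M_rnap_mito", 0.0)
    sol = solve(work)
    assert sol.status == "optimal"
    assert sol.objective_value > 0.1  # fermentative growth persists
    for t in me_build.network.transcripts.values():
        gene = me_build.model.genes.get(t.gene)
        if gene is not None and gene.locus_class == "mitochondrial":
            assert sol.primal[f"F_{t.id}"] == pytest.approx(0.0, abs=1e-9)
    # nuclear transcription is alive (rRNA synthesis sustains ribosomes)
    assert sol.primal["v_tr_g_rrnaC"] > 1e-8


def test_degradation_recycles_composition_weighted_mass(toy_doc):
    """With enzyme turnover on, amino-acid recycle flux equals
    kdeg * (composition-weighted enzyme concentration), summed network-wide."""
    me = build_me_problem(
        toy_doc.model, toy_doc.network,
        BuildConfig(n_bins=8, kdeg_enzyme=0.05),
    )
    sol = solve(me.problem)
    assert sol.status == "optimal"
    net = me.network
    total_recycled = 0.0
    expected = 0.0
    for enz in net.enzymes.values():
        v = sol.primal[f"v_deg_cplx_{enz.id}"]
        copies_aa = sum(
            n * sum(net.peptides[p].aa_counts.values())
            for p, n in enz.composition.items()
        )
        total_recycled += v * copies_aa
        expected += 0.05 * sol.primal[f"E_{enz.id}"] * copies_aa
    assert total_recycled == pytest.approx(expected, rel=1e-6)


def test_growth_monotone_in_kcat(toy_doc):
    """Raising a binding turnover number never decreases optimal growth."""
    import copy

    base = build_me_problem(toy_doc.model, toy_doc.network, BuildConfig(n_bins=8))
    mu_base = solve(base.problem).objective_value
    net = copy.deepcopy(toy_doc.network)
    net.enzymes["resp"].kcat_fwd *= 4.0
    faster = build_me_problem(toy_doc.model, net, BuildConfig(n_bins=8))
    mu_fast = solve(faster.problem).objective_value
    assert mu_fast >= mu_base - 1e-9
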