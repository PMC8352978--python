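"""Metabolic-layer tests: GPR parsing, biomass accounting, GAM, FBA."""

import math

import pytest

from emekit import (
    BiomassReaction,
    MetabolicModel,
    Metabolite,
    Reaction,
    ToySpec,
    adjust_gam,
    build_fba,
    check_biomass_mass,
    compute_mass_fractions,
    generate_toy_model,
    parse_gpr,
    solve,
    strip_biomass_pseudocomponents,
)
from emekit.core import ModelError


# ----------------------------------------------------------------------
# GPR parsing
# ----------------------------------------------------------------------

@pytest.mark.parametrize(
    "rule,expected",
    [
        ("", []),
        ("g1", [{"g1"}]),
        ("g1 or g2", [{"g1"}, {"g2"}]),
        ("g1 and g2", [{"g1", "g2"}]),
        ("(g1 and g2) or g3", [{"g1", "g2"}, {"g3"}]),
        ("g1 and (g2 or g3)", [{"g1", "g2"}, {"g1", "g3"}]),
        ("G1 AND G2", [{"G1", "G2"}]),  # keywords case-insensitive
    ],
)
def test_parse_gpr_dnf(rule, expected):
    assert parse_gpr(rule) == [frozenset(s) for s in expected]


@pytest.mark.parametrize("rule", ["g1 and", "(g1 or g2", "and g1", "g1 g2"])
def test_parse_gpr_malformed(rule):
    with pytest.raises(ModelError):
        parse_gpr(rule)


# ----------------------------------------------------------------------
# Biomass mass bookkeeping
# ----------------------------------------------------------------------

def _micro_model(reactants, byproducts=None, gam=0.0, mws=None):
    mws = mws or {}
    mets = {}
    for mid in set(reactants) | set(byproducts or {}) | {
        "atp_c", "adp_c", "pi_c", "h2o_c", "h_c"
    }:
        stem = mid.rsplit("_", 1)[0]
        default = {"atp": 0.507, "adp": 0.427, "pi": 0.097, "h2o": 0.018,
                   "h": 0.001}.get(stem, 0.1)
        mets[mid] = Metabolite(mid, "c", mw=mws.get(mid, default))
    rxn = Reaction("dummy_rxn", {list(mets)[0]: -1.0})
    return MetabolicModel(
        id="micro", compartments={"c": "cytosol"}, metabolites=mets,
        reactions={"dummy_rxn": rxn}, genes={},
        biomass=BiomassReaction(dict(reactants), dict(byproducts or {}), gam),
    )


def test_mass_fraction_single_amino_acid():
    m = _micro_model({"aa_c": 1.0}, mws={"aa_c": 0.1})
    fr = compute_mass_fractions(m, {"aa_c": "protein"})
    assert fr["protein"] == pytest.approx(0.1)


def test_mass_fraction_empty_class():
    m = _micro_model({"aa_c": 1.0})
    fr = compute_mass_fractions(m, {})
    assert fr == {}


def test_mass_fractions_match_biomass_total(toy_doc):
    fr = compute_mass_fractions(toy_doc.model)
    report = check_biomass_mass(toy_doc.model)
    # no byproducts in the toy biomass: class fractions alone carry the gram
    assert sum(fr.values()) == pytest.approx(report.total_mass, abs=1e-9)


def test_toy_biomass_weighs_one_gram(toy_doc):
    assert check_biomass_mass(toy_doc.model, tol=1e-6).passed


@pytest.mark.parametrize("seed", range(2, 12))
def test_randomized_toy_biomass_balanced(seed):
    doc = generate_toy_model(ToySpec(seed=seed))
    assert check_biomass_mass(doc.model, tol=1e-6).passed


def test_doubled_coefficient_fails_with_excess(toy_doc):
    model = toy_doc.model.copy()
    met = next(iter(model.biomass.reactants))
    model.biomass.reactants[met] *= 2.0
    report = check_biomass_mass(model, tol=1e-6)
    assert not report.passed
    excess = model.biomass.reactants[met] / 2.0 * model.metabolites[met].mw
    assert report.total_mass - 1.0 == pytest.approx(excess, rel=1e-9)


def test_gam_hydrolysis_cancels_in_mass_check():
    m = _micro_model({"aa_c": 10.0}, gam=30.0, mws={"aa_c": 0.1})
    assert check_biomass_mass(m, tol=1e-6).passed


# ----------------------------------------------------------------------
# GAM adjustment: 2 ATP per amino acid leave the maintenance term
# ----------------------------------------------------------------------

@pytest.mark.parametrize("a_tot,expected_removed", [(4.1, 8.2), (0.0, 0.0), (2.0, 4.0)])
def test_adjust_gam_removes_twice_the_amino_acid_total(a_tot, expected_removed):
    reactants = {"aa_c": a_tot} if a_tot else {"x_c": 1.0}
    m = _micro_model(reactants, gam=60.0)
    m.amino_acids = ["aa_c"] if a_tot else []
    adjusted, report = adjust_gam(m)
    assert report.amino_acid_total == pytest.approx(a_tot)
    assert report.atp_removed == pytest.approx(expected_removed)
    assert adjusted.biomass.gam_atp == pytest.approx(60.0 - expected_removed)


def test_adjust_gam_clamps_negative_with_warning():
    m = _micro_model({"aa_c": 4.0}, gam=5.0)  # would give 5 - 8 < 0
    m.amino_acids = ["aa_c"]
    with pytest.warns(UserWarning):
        adjusted, report = adjust_gam(m)
    assert adjusted.biomass.gam_atp == 0.0
    assert report.clamped


# ----------------------------------------------------------------------
# Stripping protein/RNA drains
# ----------------------------------------------------------------------

def test_strip_removes_mass_and_is_idempotent(toy_doc):
    stripped, removed = strip_biomass_pseudocomponents(toy_doc.model)
    assert removed["protein"] == pytest.approx(0.40, abs=1e-9)
    assert removed["RNA"] == pytest.approx(0.06, abs=1e-9)
    for met, cls in stripped.biomass_class_map.items():
        if cls in ("protein", "RNA"):
            assert met not in stripped.biomass.reactants
    with pytest.warns(UserWarning):
        again, removed2 = strip_biomass_pseudocomponents(stripped)
    assert removed2 == {"protein": 0.0, "RNA": 0.0}


# ----------------------------------------------------------------------
# FBA assembly
# ----------------------------------------------------------------------

def test_fba_linear_chain_hand_solution():
    # uptake -> A -> 2 B, biomass drains 4 B per unit growth; uptake <= 10
    mets = {
        "A_c": Metabolite("A_c", "c", mw=0.1),
        "B_c": Metabolite("B_c", "c", mw=0.25),
    }
    rxns = {
        "upt": Reaction("upt", {"A_c": 1.0}, 0.0, 10.0),
        "conv": Reaction("conv", {"A_c": -1.0, "B_c": 2.0}, 0.0, 1000.0),
    }
    model = MetabolicModel(
        id="chain", compartments={"c": "c"}, metabolites=mets, reactions=rxns,
        genes={}, biomass=BiomassReaction({"B_c": 4.0}),
    )
    sol = solve(build_fba(model))
    # 10 A -> 20 B; growth = 20 / 4 = 5
    assert sol.objective_value == pytest.approx(5.0, abs=1e-8)


def test_fba_zero_growth_with_closed_uptakes(toy_doc):
    prob = build_fba(toy_doc.model)
    for rxn in toy_doc.model.reactions.values():
        if rxn.id.startswith("EX_"):
            prob.set_bounds(rxn.id, 0.0, max(rxn.upper, 0.0))
    prob.set_bounds("NGAM", 0.0, 1000.0)  # maintenance cannot be met either
    sol = solve(prob)
    assert sol.status == "optimal"
    assert sol.objective_value == pytest.approx(0.0, abs=1e-8)


def test_fba_has_no_binaries(toy_doc):
    from emekit import count_binaries

    assert count_binaries(build_fba(toy_doc.model)) == 0


def test_adjust_gam_never_decreases_fba_growth(toy_doc):
    base = solve(build_fba(toy_doc.model)).objective_value
    adjusted, _ = adjust_gam(toy_doc.model)
    relaxed = solve(build_fba(adjusted)).objective_value
    assert relaxed >= base - 1e-9
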