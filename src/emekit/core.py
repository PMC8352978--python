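"""Metabolic layer: metabolites, reactions, genes, biomass bookkeeping.

Biomass accounting follows the 1-gram convention of genome-scale models:
the stoichiometric coefficients of the biomass reaction, weighted by
molecular weight (g mmol^-1), must account for exactly 1 g of dry weight.
Mass fractions per macromolecular class (protein, RNA, DNA, carbohydrate,
lipid, ion) are the MW-weighted sums of the class members' drains.

Units are fixed package-wide: fluxes mmol gDW^-1 h^-1, molecular weights
g mmol^-1, concentrations mmol gDW^-1, growth h^-1.  Turnover numbers given
in s^-1 are converted to h^-1 at parse time.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Mapping, Optional, Set, Tuple

from . import optmodel
from .optmodel import EQ, GE, LE, MAXIMIZE, Problem


class ModelError(ValueError):
    pass


@dataclass
class Metabolite:
    id: str
    compartment: str
    name: str = ""
    formula: Optional[str] = None
    mw: Optional[float] = None  # g mmol^-1
    dgf: Optional[float] = None  # standard Gibbs energy of formation, kJ mol^-1
    is_membrane_associated: bool = False

    def __post_init__(self) -> None:
        if self.mw is not None and self.mw <= 0:
            raise ModelError(f"metabolite {self.id}: MW must be positive")


@dataclass
class Reaction:
    id: str
    stoich: Dict[str, float]  # metabolite id -> coefficient, reactants negative
    lower: float = 0.0
    upper: float = 1000.0
    gpr: str = ""  # boolean gene rule; OR = isozymes, AND = complex members
    name: str = ""
    dgr: Optional[float] = None  # kJ mol^-1
    is_transport: bool = False

    def __post_init__(self) -> None:
        if not self.stoich:
            raise ModelError(f"reaction {self.id}: empty stoichiometry")
        self.stoich = {m: float(c) for m, c in self.stoich.items()}
        self.lower, self.upper = float(self.lower), float(self.upper)
        if self.lower > self.upper:
            raise ModelError(f"reaction {self.id}: bounds out of order")

    @property
    def genes(self) -> Set[str]:
        return {g for iso in parse_gpr(self.gpr) for g in iso}


@dataclass
class Gene:
    id: str
    sequence: Optional[str] = None  # nucleotide sequence (coding strand)
    length_nt: Optional[int] = None
    nucleotide_composition: Optional[Dict[str, float]] = None  # fractions
    locus_class: str = "nuclear"  # nuclear | mitochondrial

    def __post_init__(self) -> None:
        if self.sequence is not None:
            self.sequence = self.sequence.upper().replace("U", "T")
            self.length_nt = len(self.sequence)
        elif self.nucleotide_composition is not None:
            total = sum(self.nucleotide_composition.values())
            if abs(total - 1.0) > 1e-9:
                raise ModelError(
                    f"gene {self.id}: composition fractions sum to {total}, not 1"
                )
        if self.locus_class not in ("nuclear", "mitochondrial"):
            raise ModelError(f"gene {self.id}: unknown locus class {self.locus_class}")

    def nt_counts(self) -> Dict[str, float]:
        """Nucleotide counts (per transcript molecule) from sequence or fractions."""
        if self.sequence is not None:
            return {b: float(self.sequence.count(b)) for b in "ACGT"}
        if self.nucleotide_composition is not None and self.length_nt is not None:
            return {
                b: f * self.length_nt for b, f in self.nucleotide_composition.items()
            }
        raise ModelError(f"gene {self.id}: no sequence or composition available")


@dataclass
class BiomassReaction:
    """Biomass pseudo-reaction: drains (reactants) and released byproducts.

    Coefficients are stored positive on both sides, in mmol gDW^-1.  The GAM
    (growth-associated maintenance) ATP is carried separately from the
    precursor drains so it can be adjusted without touching composition;
    matched ADP/Pi/H2O/H+ terms are implied.
    """

    reactants: Dict[str, float] = field(default_factory=dict)
    byproducts: Dict[str, float] = field(default_factory=dict)
    gam_atp: float = 0.0
    gam_metabolites: Dict[str, str] = field(
        default_factory=lambda: {
            "atp": "atp_c", "h2o": "h2o_c", "adp": "adp_c", "pi": "pi_c", "h": "h_c",
        }
    )

    def __post_init__(self) -> None:
        self.reactants = {m: float(c) for m, c in self.reactants.items()}
        self.byproducts = {m: float(c) for m, c in self.byproducts.items()}
        self.gam_atp = float(self.gam_atp)

    def full_stoich(self) -> Dict[str, float]:
        """Signed stoichiometry including the GAM hydrolysis terms."""
        st: Dict[str, float] = {}
        for m, eta in self.reactants.items():
            st[m] = st.get(m, 0.0) - eta
        for m, eta in self.byproducts.items():
            st[m] = st.get(m, 0.0) + eta
        g = self.gam_metabolites
        if self.gam_atp:
            for key, sign in (("atp", -1), ("h2o", -1), ("adp", 1), ("pi", 1), ("h", 1)):
                mid = g[key]
                st[mid] = st.get(mid, 0.0) + sign * self.gam_atp
        return {m: c for m, c in st.items() if c != 0.0}

    def copy(self) -> "BiomassReaction":
        return BiomassReaction(
            dict(self.reactants), dict(self.byproducts), self.gam_atp,
            dict(self.gam_metabolites),
        )


@dataclass
class MetabolicModel:
    id: str
    compartments: Dict[str, str]
    metabolites: Dict[str, Metabolite]
    reactions: Dict[str, Reaction]
    genes: Dict[str, Gene]
    biomass: BiomassReaction
    biomass_class_map: Dict[str, str] = field(default_factory=dict)  # met -> class
    amino_acids: List[str] = field(default_factory=list)  # metabolite ids
    exchange_prefix: str = "EX_"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for rxn in self.reactions.values():
            for m in rxn.stoich:
                if m not in self.metabolites:
                    raise ModelError(f"reaction {rxn.id} references unknown metabolite {m}")
            for g in rxn.genes:
                if g not in self.genes:
                    raise ModelError(f"reaction {rxn.id} references unknown gene {g}")
        for m in list(self.biomass.reactants) + list(self.biomass.byproducts):
            if m not in self.metabolites:
                raise ModelError(f"biomass references unknown metabolite {m}")

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            compartments=dict(self.compartments),
            metabolites={k: replace(v) for k, v in self.metabolites.items()},
            reactions={
                k: replace(v, stoich=dict(v.stoich)) for k, v in self.reactions.items()
            },
            genes={k: replace(v) for k, v in self.genes.items()},
            biomass=self.biomass.copy(),
            biomass_class_map=dict(self.biomass_class_map),
            amino_acids=list(self.amino_acids),
            exchange_prefix=self.exchange_prefix,
        )


# ----------------------------------------------------------------------
# GPR parsing: boolean rule -> disjunctive normal form (list of isozymes)
# ----------------------------------------------------------------------

_TOKEN = re.compile(r"\(|\)|\band\b|\bor\b|[^\s()]+", re.IGNORECASE)


def parse_gpr(rule: str) -> List[FrozenSet[str]]:
    """Parse a gene-protein-reaction rule into disjunctive normal form.

    OR separates isozymes (alternative enzymes); AND groups members of one
    complex.  Returns a list of gene sets, one per isozyme; an empty rule
    gives an empty list (uncatalyzed reaction).
    """
    rule = rule.strip()
    if not rule:
        return []
    tokens = _TOKEN.findall(rule)
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def parse_or() -> List[FrozenSet[str]]:
        nonlocal pos
        terms = parse_and()
        while peek() is not None and peek().lower() == "or":
            pos += 1
            terms = terms + parse_and()
        return terms

    def parse_and() -> List[FrozenSet[str]]:
        nonlocal pos
        result = parse_atom()
        while peek() is not None and peek().lower() == "and":
            pos += 1
            right = parse_atom()
            result = [a | b for a in result for b in right]
        return result

    def parse_atom() -> List[FrozenSet[str]]:
        nonlocal pos
        tok = peek()
        if tok is None:
            raise ModelError(f"malformed GPR rule: {rule!r}")
        if tok == "(":
            pos += 1
            inner = parse_or()
            if peek() != ")":
                raise ModelError(f"unbalanced parentheses in GPR rule: {rule!r}")
            pos += 1
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ModelError(f"malformed GPR rule: {rule!r}")
        pos += 1
        return [frozenset([tok])]

    out = parse_or()
    if pos != len(tokens):
        raise ModelError(f"trailing tokens in GPR rule: {rule!r}")
    # dedupe while keeping order
    seen: Set[FrozenSet[str]] = set()
    uniq = []
    for iso in out:
        if iso not in seen:
            seen.add(iso)
            uniq.append(iso)
    return uniq


# ----------------------------------------------------------------------
# Biomass bookkeeping
# ----------------------------------------------------------------------

def compute_mass_fractions(
    model: MetabolicModel, class_map: Optional[Mapping[str, str]] = None
) -> Dict[str, float]:
    """Per-class biomass mass fractions f_k = sum over class drains of |eta| * MW.

    ``class_map`` maps biomass reactant metabolite ids to class names; the
    model's own ``biomass_class_map`` is used when omitted.  Fractions are
    in g gDW^-1.
    """
    cmap = dict(class_map) if class_map is not None else model.biomass_class_map
    fractions: Dict[str, float] = {k: 0.0 for k in set(cmap.values())}
    for met_id, eta in model.biomass.reactants.items():
        cls = cmap.get(met_id)
        if cls is None:
            continue
        met = model.metabolites[met_id]
        if met.mw is None:
            raise ModelError(f"biomass metabolite {met_id} has no molecular weight")
        fractions[cls] = fractions.get(cls, 0.0) + abs(eta) * met.mw
    return fractions


@dataclass
class BiomassMassReport:
    total_mass: float  # net drained mass, g per g biomass
    reactant_mass: float
    byproduct_mass: float
    tolerance: float
    passed: bool


def check_biomass_mass(model: MetabolicModel, tol: float = 1e-6) -> BiomassMassReport:
    """Verify that the biomass reaction accounts for 1 g of dry weight.

    Net drained mass (reactant mass minus released byproduct mass) must be
    1 g; the GAM hydrolysis terms cancel exactly when metabolite MWs are
    consistent.  Returns a report rather than raising.
    """
    reac = 0.0
    for m, eta in model.biomass.full_stoich().items():
        met = model.metabolites[m]
        if met.mw is None:
            raise ModelError(f"biomass metabolite {m} has no molecular weight")
    reac = sum(
        abs(eta) * model.metabolites[m].mw
        for m, eta in model.biomass.full_stoich().items()
        if eta < 0
    )
    byp = sum(
        eta * model.metabolites[m].mw
        for m, eta in model.biomass.full_stoich().items()
        if eta > 0
    )
    total = reac - byp
    return BiomassMassReport(total, reac, byp, tol, abs(total - 1.0) <= tol)


@dataclass
class GamAdjustment:
    amino_acid_total: float  # A_tot, mmol gDW^-1
    atp_removed: float  # 2 * A_tot, mmol gDW^-1
    old_gam: float
    new_gam: float
    clamped: bool


def adjust_gam(
    model: MetabolicModel, amino_acids: Optional[List[str]] = None
) -> Tuple[MetabolicModel, GamAdjustment]:
    """Remove the explicit peptide-polymerization ATP cost from the GAM.

    Translation consumes 2 GTP per amino acid, and each GTP is regenerated
    from one ATP (nucleoside-diphosphate kinase), so polymerizing the
    biomass amino-acid drains costs 2 * A_tot mmol ATP per gDW, where A_tot
    is the summed amino-acid stoichiometry.  Once translation is modeled
    explicitly that cost must leave the growth-associated maintenance to
    avoid double counting.  A negative result is clamped to zero with a
    warning (it signals inconsistent inputs).
    """
    aas = amino_acids if amino_acids is not None else model.amino_acids
    a_tot = sum(abs(model.biomass.reactants.get(a, 0.0)) for a in aas)
    removed = 2.0 * a_tot
    old = model.biomass.gam_atp
    new = old - removed
    clamped = False
    if new < 0:
        warnings.warn(
            f"GAM adjustment would be negative ({new:.3f}); clamping to 0 — "
            "check GAM and amino-acid drains for consistency"
        )
        new = 0.0
        clamped = True
    out = model.copy()
    out.biomass.gam_atp = new
    return out, GamAdjustment(a_tot, removed, old, new, clamped)


def strip_biomass_pseudocomponents(
    model: MetabolicModel, classes: Tuple[str, ...] = ("protein", "RNA")
) -> Tuple[MetabolicModel, Dict[str, float]]:
    """Remove protein/RNA drains from the biomass reaction.

    When the expression layer is built, mRNA and peptide synthesis account
    explicitly for amino-acid and NTP demand; leaving the corresponding
    drains in the biomass reaction would double-count them.  The removed
    mass per class (g gDW^-1) is returned so total-mass accounting can be
    transferred to the expression layer and its dummy species.  Idempotent.
    """
    out = model.copy()
    removed: Dict[str, float] = {c: 0.0 for c in classes}
    hit = False
    for met_id in list(out.biomass.reactants):
        cls = out.biomass_class_map.get(met_id)
        if cls in classes:
            met = out.metabolites[met_id]
            if met.mw is None:
                raise ModelError(f"biomass metabolite {met_id} has no molecular weight")
            removed[cls] += abs(out.biomass.reactants.pop(met_id)) * met.mw
            hit = True
    if not hit:
        warnings.warn(f"no biomass drains found for classes {classes}; no-op")
    return out, removed


# ----------------------------------------------------------------------
# Plain FBA assembly
# ----------------------------------------------------------------------

GROWTH_VAR = "mu"
BIOMASS_RXN = "v_biomass"


def build_fba(model: MetabolicModel) -> Problem:
    """Assemble the FBA linear program for a metabolic model.

    One flux variable per reaction within its bounds, one steady-state
    equality per metabolite, a biomass flux equal to the growth variable,
    and growth maximization as the objective.  Contains no binaries.
    """
    problem = Problem(f"fba_{model.id}")
    balances: Dict[str, Dict[str, float]] = {m: {} for m in model.metabolites}

    for rxn in model.reactions.values():
        problem.add_variable(rxn.id, rxn.lower, rxn.upper)
        for m, coef in rxn.stoich.items():
            balances[m][rxn.id] = balances[m].get(rxn.id, 0.0) + coef

    problem.add_variable(BIOMASS_RXN, 0.0, math.inf)
    problem.add_variable(GROWTH_VAR, 0.0, math.inf)
    problem.add_constraint(
        {GROWTH_VAR: 1.0, BIOMASS_RXN: -1.0}, EQ, 0.0, "growth_is_biomass_flux"
    )
    for m, coef in model.biomass.full_stoich().items():
        balances[m][BIOMASS_RXN] = balances[m].get(BIOMASS_RXN, 0.0) + coef

    for m, terms in balances.items():
        if terms:
            problem.add_constraint(terms, EQ, 0.0, f"mass_balance_{m}")

    problem.set_objective({GROWTH_VAR: 1.0}, MAXIMIZE)
    return problem
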