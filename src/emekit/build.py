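"""Assembly of the full metabolism-and-expression MILP.

``build_me_problem`` wires the layers together in a fixed order:

1. GAM adjustment (the explicit translation cost of 2 ATP per amino acid
   leaves the growth-associated maintenance) and removal of the protein /
   RNA drains from the biomass reaction (their synthesis is now explicit).
2. Growth variable + binary growth encoding.
3. Split forward/backward flux variables and metabolite balances for the
   metabolic layer.
4. Expression layer: dummy species, transcription, translation,
   complexation, tRNA cycling.
5. Allocation: protein/RNA total-mass equalities, phi split, and the
   residual biomass drains (constant or bin-rescaled).
6. Catalytic constraints, and optionally the TFA layer.

The resulting problem maximizes growth by default.  Model variants follow
the cb/vb x thermo naming: EFL.cb, EFL.vb, ETFL.cb, ETFL.vb.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional

from . import allocation as alloc_mod
from . import expression as expr_mod
from .allocation import AllocationParams, CompositionTable, interpolate_composition
from .core import (
    GamAdjustment,
    MetabolicModel,
    adjust_gam,
    compute_mass_fractions,
    strip_biomass_pseudocomponents,
)
from .discretization import (
    GrowthEncoding,
    GrowthGrid,
    encode_growth,
    linearize_product,
    make_grid,
)
from .expression import ExpressionNetwork, build_dummy_species
from .optmodel import EQ, MAXIMIZE, Problem
from .thermo import TFAConfig, ThermoAnnotation, add_tfa_constraints


@dataclass
class BuildConfig:
    """Knobs of the ME build, in the package's canonical units.

    Defaults: growth upper bound 0.75 h^-1 with 8 bins (desk-scale; raise to
    128 for the study-scale discretization), modeled-proteome fraction
    phi = 0.55 g/g, mRNA half-life 20 min (kdeg = ln2 / (1/3) h^-1), no
    protein turnover, ribosomal elongation 10.5 aa s^-1 and polymerase
    elongation 60 nt s^-1 (highest reported values, so the expression
    machinery is not over-constrained), 2 GTP per translated amino acid.
    """

    mu_max: float = 0.75  # h^-1
    n_bins: int = 8
    mode: str = "cb"  # cb | vb
    phi: float = 0.55
    thermo: bool = False
    kdeg_mrna: float = math.log(2.0) / (20.0 / 60.0)  # h^-1
    kdeg_peptide: float = 0.0
    kdeg_enzyme: float = 0.0
    gtp_per_aa: float = 2.0
    atp_per_charging: float = 0.0  # aminoacylation ATP; lumped in maintenance
    ribosome_footprint_nt: float = 30.0
    dummy_length_aa: int = 250
    tfa: TFAConfig = field(default_factory=TFAConfig)

    def variant_name(self) -> str:
        return ("ETFL." if self.thermo else "EFL.") + self.mode


class BuildContext:
    """Mutable assembly state shared by the layer builders."""

    def __init__(
        self,
        problem: Problem,
        model: MetabolicModel,
        network: ExpressionNetwork,
        config: BuildConfig,
        grid: GrowthGrid,
        encoding: GrowthEncoding,
        allocation: AllocationParams,
        bin_fractions: Optional[Dict[str, List[float]]],
    ):
        self.problem = problem
        self.model = model
        self.network = network
        self.config = config
        self.grid = grid
        self.encoding = encoding
        self.allocation = allocation
        self.bin_fractions = bin_fractions
        self.mu_var = encoding.mu_var

        self.met_balance: Dict[str, Dict[str, float]] = {
            m: {} for m in model.metabolites
        }
        self.trna_usage: Dict[str, Dict[str, float]] = {
            aa: {} for aa in network.trnas
        }
        self.peptide_use: Dict[str, Dict[str, float]] = {
            p: {} for p in network.peptides
        }
        self.rna_use: Dict[str, Dict[str, float]] = {
            t: {} for t in network.transcripts
        }
        self.peptide_balance_terms: Dict[str, Dict[str, float]] = {}
        self.peptide_balance_label: Dict[str, str] = {}
        self.rna_balance_terms: Dict[str, Dict[str, float]] = {}
        self.rna_balance_label: Dict[str, str] = {}

        # concentration caps (g gDW^-1) from the allocation data: a species
        # can never carry more mass than its whole macromolecular class
        if allocation.mode == "vb":
            self.protein_cap = max(bin_fractions["protein"])
            self.rna_cap = max(bin_fractions["RNA"])
        else:
            self.protein_cap = allocation.reference_fractions["protein"]
            self.rna_cap = allocation.reference_fractions["RNA"]

    # -- variable helpers ---------------------------------------------
    def conc_var(self, name: str, upper: float) -> str:
        if name not in self.problem.variables:
            self.problem.add_variable(name, 0.0, upper)
        return name

    def machinery_var(self, mach_id: str) -> str:
        name = "M_" + mach_id
        if name not in self.problem.variables:
            mach = self.network.machinery[mach_id]
            pmass = mach.peptide_mass(self.network.peptides)
            rmass = mach.rna_mass(self.network.transcripts)
            caps = []
            if pmass > 0:
                caps.append(self.protein_cap / pmass)
            if rmass > 0:
                caps.append(self.rna_cap / rmass)
            self.problem.add_variable(name, 0.0, min(caps) if caps else math.inf)
        return name

    def dilution(self, var: str, tag: str) -> Dict[str, float]:
        """Linear expression equal to mu * var (exact at integer points)."""
        ub = self.problem.variables[var].upper
        term = linearize_product(self.problem, self.encoding, var, ub, tag=tag)
        return term.expression


@dataclass
class MEBuild:
    """A built ME problem plus everything needed to analyze it."""

    problem: Problem
    grid: GrowthGrid
    encoding: GrowthEncoding
    model_input: MetabolicModel  # as handed in (before surgery)
    model: MetabolicModel  # GAM-adjusted, stripped
    network: ExpressionNetwork
    config: BuildConfig
    allocation: AllocationParams
    gam: GamAdjustment
    stripped_mass: Dict[str, float]
    thermo_reactions: List[str]
    ctx: BuildContext

    @property
    def mu_var(self) -> str:
        return self.encoding.mu_var

    def enzyme_variables(self, include_dummy: bool = False) -> List[str]:
        out = []
        for enz in self.network.enzymes.values():
            if enz.is_dummy and not include_dummy:
                continue
            out.append("E_" + enz.id)
        for mach in self.network.machinery:
            out.append("M_" + mach)
        return [v for v in out if v in self.problem.variables]

    def metabolic_flux_variables(self) -> List[str]:
        out = []
        for rxn in self.model.reactions:
            for pref in ("v_fwd_", "v_bwd_"):
                if pref + rxn in self.problem.variables:
                    out.append(pref + rxn)
        return out


def build_me_problem(
    model: MetabolicModel,
    network: ExpressionNetwork,
    config: Optional[BuildConfig] = None,
    allocation: Optional[AllocationParams] = None,
    table: Optional[CompositionTable] = None,
) -> MEBuild:
    """Build the ME MILP for a model + expression network.

    ``allocation`` defaults to fractions computed from the input biomass
    reaction (via the MW-weighted drains) with the configured phi; vb mode
    additionally needs a composition ``table`` (or one embedded in
    ``allocation``).
    """
    import copy

    config = config or BuildConfig()
    model_input = model.copy()
    network = copy.deepcopy(network)  # dummy species / kdeg defaults are per-build
    network.validate(model)

    reference = compute_mass_fractions(model_input)
    if allocation is None:
        allocation = AllocationParams(
            mode=config.mode,
            phi=config.phi,
            reference_fractions=reference,
            table=table,
        )
    elif not allocation.reference_fractions:
        allocation.reference_fractions = reference

    work, gam_adj = adjust_gam(model_input)
    work, stripped = strip_biomass_pseudocomponents(work, ("protein", "RNA"))

    grid = make_grid(config.mu_max, config.n_bins)
    bin_fractions = None
    if allocation.mode == "vb":
        bin_fractions = interpolate_composition(allocation.table, grid)

    problem = Problem(f"{config.variant_name()}_{model.id}")
    problem.add_variable("mu", 0.0, config.mu_max)
    encoding = encode_growth(problem, grid, "mu")

    ctx = BuildContext(
        problem, work, network, config, grid, encoding, allocation, bin_fractions
    )

    # metabolic layer: split fluxes, accumulate balances
    for rxn in work.reactions.values():
        fwd = problem.add_variable(f"v_fwd_{rxn.id}", 0.0, max(rxn.upper, 0.0))
        bwd = problem.add_variable(f"v_bwd_{rxn.id}", 0.0, max(-rxn.lower, 0.0))
        if rxn.lower > 0.0:
            problem.set_bounds(fwd, rxn.lower, rxn.upper)
        for m, coef in rxn.stoich.items():
            bal = ctx.met_balance[m]
            bal[fwd] = bal.get(fwd, 0.0) + coef
            bal[bwd] = bal.get(bwd, 0.0) - coef

    # expression layer
    if "dummy" not in network.peptides:
        build_dummy_species(
            network, work, length_aa=config.dummy_length_aa,
            mrna_kdeg=config.kdeg_mrna,
        )
        ctx.peptide_use.setdefault("dummy", {})
        ctx.rna_use.setdefault("mrna_dummy", {})
    _apply_default_degradation(network, config)

    expr_mod.build_transcription(ctx)
    expr_mod.build_translation(ctx)
    expr_mod.build_complexation_degradation(ctx)
    expr_mod.build_trna_cycle(ctx)

    # flush deferred macromolecule balances (complexation consumption known)
    for pid, terms in ctx.peptide_balance_terms.items():
        for v, copies in ctx.peptide_use.get(pid, {}).items():
            terms[v] = terms.get(v, 0.0) - copies
        problem.add_constraint(terms, EQ, 0.0, ctx.peptide_balance_label[pid])
    for tid, terms in ctx.rna_balance_terms.items():
        for v, copies in ctx.rna_use.get(tid, {}).items():
            terms[v] = terms.get(v, 0.0) - copies
        problem.add_constraint(terms, EQ, 0.0, ctx.rna_balance_label[tid])

    # allocation layer
    alloc_mod.add_macromolecule_totals(ctx)
    alloc_mod.apply_biomass_drains(ctx)

    # catalytic coupling
    expr_mod.add_catalytic_constraints(ctx)

    # thermodynamic layer
    thermo_rxns: List[str] = []
    if config.thermo:
        thermo_rxns = add_tfa_constraints(
            problem, work, ThermoAnnotation(), config.tfa
        )

    # metabolite steady-state balances
    for met, terms in ctx.met_balance.items():
        if terms:
            problem.add_constraint(terms, EQ, 0.0, f"mass_balance_{met}")

    problem.set_objective({"mu": 1.0}, MAXIMIZE)
    return MEBuild(
        problem, grid, encoding, model_input, work, network, config,
        allocation, gam_adj, stripped, thermo_rxns, ctx,
    )


def _apply_default_degradation(network: ExpressionNetwork, config: BuildConfig) -> None:
    """Fill unset turnover of macromolecules from the config defaults."""
    for t in network.transcripts.values():
        if t.kind in ("mrna", "dummy") and t.kdeg == 0.0 and config.kdeg_mrna:
            t.kdeg = config.kdeg_mrna
    for p in network.peptides.values():
        if p.kdeg == 0.0 and config.kdeg_peptide:
            p.kdeg = config.kdeg_peptide
    for e in network.enzymes.values():
        if e.kdeg == 0.0 and config.kdeg_enzyme:
            e.kdeg = config.kdeg_enzyme
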