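"""Thermodynamic (TFA) layer: Gibbs energies and directionality coupling.

Reaction standard Gibbs energies come from metabolite formation energies,
dG'0_r = sum_i eta_i * dG'0_f(i) (kJ mol^-1), but only for reactions whose
participants are all annotated and none membrane-associated: formation
energies estimated for the aqueous phase do not transfer to membrane
environments, so such reactions are skipped and left unconstrained.

Per covered reaction the actual Gibbs energy is

    dG_r = dG'0_r + RT * sum_i eta_i * ln(c_i),

with log-concentration variables bounded by physiological concentration
limits (water and protons excluded from the sum).  Two binaries, FU and BU,
couple flux direction to the dG sign through big-M inequalities: forward
flux forces dG_r < 0 and backward flux forces dG_r > 0, which eliminates
thermodynamically infeasible cycles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple, Union

from .core import MetabolicModel, Reaction
from .optmodel import BINARY, EQ, GE, LE, Problem


@dataclass
class TFAConfig:
    rt: float = 2.479  # kJ mol^-1, RT at 298.15 K
    c_min: float = 1e-8  # mol L^-1
    c_max: float = 0.05  # mol L^-1
    big_m_g: float = 5000.0  # kJ mol^-1, must exceed any attainable |dG_r|
    big_m_v: float = 1000.0  # mmol gDW^-1 h^-1, exceeds any attainable |v|
    eps_g: float = 0.05  # kJ mol^-1; strict-inequality margin (dG < -eps for
    # forward use).  Eliminates zero-dG loop fluxes and must exceed
    # big_m_g * (solver integrality tolerance) or near-integral binaries
    # leak through the big-M; 0.05 kJ/mol is physically negligible (~RT/50)
    excluded_metabolites: Tuple[str, ...] = ("h2o", "h")  # name stems; no ln c term

    def __post_init__(self) -> None:
        if self.c_min <= 0 or self.c_min >= self.c_max:
            raise ValueError("need 0 < c_min < c_max")


@dataclass
class ThermoAnnotation:
    """Per-metabolite formation energies and derived reaction energies."""

    dgf: Dict[str, float] = field(default_factory=dict)  # metabolite -> kJ mol^-1
    dgr_override: Dict[str, float] = field(default_factory=dict)  # reaction-level

    def coverage(self, model: MetabolicModel) -> Dict[str, int]:
        """Accounting of covered / skipped reactions, mirroring curation
        categories (annotated, missing formation energy, membrane)."""
        counts = {"annotated": 0, "missing_dgf": 0, "membrane": 0}
        for rxn in model.reactions.values():
            result = reaction_dg_from_formation(rxn, model, self)
            if isinstance(result, float):
                counts["annotated"] += 1
            else:
                counts[result] += 1
        return counts


SkipReason = str  # "missing_dgf" | "membrane"


def reaction_dg_from_formation(
    reaction: Reaction,
    model: MetabolicModel,
    annotations: ThermoAnnotation,
) -> Union[float, SkipReason]:
    """Standard reaction Gibbs energy from formation energies, or a skip reason.

    Returns dG'0_r = sum eta_i dG'0_f(i) in kJ mol^-1 when every participant
    is annotated and aqueous; otherwise the string ``"missing_dgf"`` or
    ``"membrane"`` (membrane exclusion is checked first).
    """
    if reaction.id in annotations.dgr_override:
        return annotations.dgr_override[reaction.id]
    if reaction.is_transport:
        return "membrane"
    for met_id in reaction.stoich:
        if model.metabolites[met_id].is_membrane_associated:
            return "membrane"
    total = 0.0
    for met_id, eta in reaction.stoich.items():
        met = model.metabolites[met_id]
        dgf = annotations.dgf.get(met_id, met.dgf)
        if dgf is None:
            return "missing_dgf"
        total += eta * dgf
    return total


def _is_excluded(met_id: str, config: TFAConfig) -> bool:
    stem = met_id.rsplit("_", 1)[0]
    return stem in config.excluded_metabolites


def add_tfa_constraints(
    problem: Problem,
    model: MetabolicModel,
    annotations: ThermoAnnotation,
    config: Optional[TFAConfig] = None,
    flux_prefix: Tuple[str, str] = ("v_fwd_", "v_bwd_"),
) -> List[str]:
    """Attach TFA constraints to a problem with split forward/backward fluxes.

    Per covered reaction adds one dG_r variable, the log-concentration
    coupling, and the directionality binaries:

        FU + BU <= 1
        dG_r <= big_m_g * (1 - FU)     (forward use forces dG_r <= 0)
        dG_r >= -big_m_g * (1 - BU)
        v_fwd <= big_m_v * FU
        v_bwd <= big_m_v * BU

    Exactly two binaries are added per covered reaction.  Returns the list
    of covered reaction ids.
    """
    config = config or TFAConfig()
    covered: List[str] = []
    ln_lo, ln_hi = math.log(config.c_min), math.log(config.c_max)

    for rxn in model.reactions.values():
        dgr0 = reaction_dg_from_formation(rxn, model, annotations)
        if not isinstance(dgr0, float):
            continue
        fwd, bwd = flux_prefix[0] + rxn.id, flux_prefix[1] + rxn.id
        if fwd not in problem.variables or bwd not in problem.variables:
            raise ValueError(
                f"reaction {rxn.id}: split flux variables {fwd}/{bwd} missing"
            )
        covered.append(rxn.id)

        dg = problem.add_variable(f"dG_{rxn.id}", -math.inf, math.inf)
        terms: Dict[str, float] = {dg: 1.0}
        for met_id, eta in rxn.stoich.items():
            if _is_excluded(met_id, config):
                continue
            lnc = f"lnc_{met_id}"
            if lnc not in problem.variables:
                problem.add_variable(lnc, ln_lo, ln_hi)
            terms[lnc] = terms.get(lnc, 0.0) - config.rt * eta
        problem.add_constraint(terms, EQ, dgr0, f"dg_def_{rxn.id}")

        fu = problem.add_variable(f"FU_{rxn.id}", 0, 1, BINARY)
        bu = problem.add_variable(f"BU_{rxn.id}", 0, 1, BINARY)
        problem.add_constraint({fu: 1.0, bu: 1.0}, LE, 1.0, f"dir_excl_{rxn.id}")
        problem.add_constraint(
            {dg: 1.0, fu: config.big_m_g}, LE,
            config.big_m_g - config.eps_g, f"dg_fwd_{rxn.id}",
        )
        problem.add_constraint(
            {dg: 1.0, bu: -config.big_m_g}, GE,
            config.eps_g - config.big_m_g, f"dg_bwd_{rxn.id}",
        )
        problem.add_constraint(
            {fwd: 1.0, fu: -config.big_m_v}, LE, 0.0, f"use_fwd_{rxn.id}"
        )
        problem.add_constraint(
            {bwd: 1.0, bu: -config.big_m_v}, LE, 0.0, f"use_bwd_{rxn.id}"
        )
    return covered


def build_fba_split(model: MetabolicModel) -> Problem:
    """FBA with every reaction split into nonnegative forward/backward fluxes.

    The net flux v_fwd - v_bwd enters the mass balances; bounds map to the
    two directions.  This is the LP base onto which TFA (and the expression
    layers) attach.
    """
    problem = Problem(f"fba_split_{model.id}")
    balances: Dict[str, Dict[str, float]] = {m: {} for m in model.metabolites}
    from .core import BIOMASS_RXN, GROWTH_VAR
    from .optmodel import MAXIMIZE

    for rxn in model.reactions.values():
        fwd = problem.add_variable(f"v_fwd_{rxn.id}", 0.0, max(rxn.upper, 0.0))
        bwd = problem.add_variable(f"v_bwd_{rxn.id}", 0.0, max(-rxn.lower, 0.0))
        for m, coef in rxn.stoich.items():
            balances[m][fwd] = balances[m].get(fwd, 0.0) + coef
            balances[m][bwd] = balances[m].get(bwd, 0.0) - coef

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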