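"""Macromolecule totals and growth-dependent biomass composition.

The protein and RNA pools are tied to their mass fractions (g gDW^-1):

    sum_j MW_j E_j = P^m            (all protein, dummy included)
    sum_l MW_l F_l = R^m            (mRNA + rRNA + tRNA + dummy mRNA)
    sum_{j != dummy} MW_j E_j = phi * P^m

so a fraction (1 - phi) of the proteome is forced into the dummy protein,
representing cellular tasks outside the model.  P^m and R^m are constants
in constant-biomass (cb) mode or bin-selected expressions in
variable-biomass (vb) mode, where a composition table indexed by growth
rate is resampled onto the growth grid by piecewise-linear interpolation.

The remaining biomass classes (DNA, carbohydrate, lipid, ion) stay in the
biomass reaction as drains of pooled metabolites.  In vb mode each drain
coefficient is rescaled per bin,

    eta_i(u) = eta_i,ref * X_u,i / X_ref,i,

which stays linear because both the bin fraction X_u,i and the bin growth
value are constants once the bin indicator is active.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .discretization import GrowthGrid, select_by_bin
from .optmodel import EQ, GE, LE

POOL_CLASSES = ("DNA", "carbohydrate", "lipid", "ion")
OTHER_CLASS = "other"


class AllocationError(ValueError):
    pass


@dataclass
class CompositionTable:
    """Growth-rate-indexed macromolecular mass fractions (g gDW^-1)."""

    growth_points: List[float]
    fractions: Dict[str, List[float]]  # class -> values at growth_points

    def __post_init__(self) -> None:
        pts = self.growth_points
        if not pts:
            raise AllocationError("empty composition table")
        if any(b <= a for a, b in zip(pts, pts[1:])):
            raise AllocationError("growth points must be strictly increasing")
        for cls, vals in self.fractions.items():
            if len(vals) != len(pts):
                raise AllocationError(f"class {cls}: wrong number of values")
            if any(v < 0 for v in vals):
                raise AllocationError(f"class {cls}: negative fraction")
        for i in range(len(pts)):
            s = sum(vals[i] for vals in self.fractions.values())
            if s > 1.0 + 1e-9:
                raise AllocationError(
                    f"fractions sum to {s:.4f} > 1 at growth point {pts[i]}"
                )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CompositionTable":
        df = df.sort_values("growth_rate_h")
        points = [float(x) for x in df["growth_rate_h"]]
        fractions = {
            c: [float(x) for x in df[c]] for c in df.columns if c != "growth_rate_h"
        }
        return cls(points, fractions)

    def to_dataframe(self) -> pd.DataFrame:
        data = {"growth_rate_h": self.growth_points}
        data.update(self.fractions)
        return pd.DataFrame(data)


def interpolate_composition(
    table: CompositionTable, grid: GrowthGrid
) -> Dict[str, List[float]]:
    """Resample the table onto the growth grid's bin centers.

    Piecewise-linear interpolation per class; bin centers outside the table
    range clamp to the end values (with a warning).
    """
    centers = np.asarray(grid.bin_centers)
    lo, hi = table.growth_points[0], table.growth_points[-1]
    if centers[0] < lo - 1e-12 or centers[-1] > hi + 1e-12:
        warnings.warn(
            f"composition table covers [{lo}, {hi}] but bin centers span "
            f"[{centers[0]:.4g}, {centers[-1]:.4g}]; clamping to end values"
        )
    out: Dict[str, List[float]] = {}
    for cls, vals in table.fractions.items():
        out[cls] = [
            float(v) for v in np.interp(centers, table.growth_points, vals)
        ]
    return out


@dataclass
class AllocationParams:
    mode: str = "cb"  # cb | vb
    phi: float = 0.55  # g g_protein^-1, modeled fraction of the proteome
    reference_fractions: Dict[str, float] = field(default_factory=dict)
    table: Optional[CompositionTable] = None

    def __post_init__(self) -> None:
        if self.mode not in ("cb", "vb"):
            raise AllocationError(f"unknown allocation mode {self.mode!r}")
        if not 0.0 <= self.phi <= 1.0:
            raise AllocationError("phi must be in [0, 1]")
        if self.mode == "vb" and self.table is None:
            raise AllocationError("vb mode requires a composition table")


def _protein_terms(ctx, include_dummy: bool) -> Dict[str, float]:
    net = ctx.network
    terms: Dict[str, float] = {}
    for enz in net.enzymes.values():
        if enz.is_dummy and not include_dummy:
            continue
        terms["E_" + enz.id] = enz.mw(net.peptides)
    for mach in net.machinery.values():
        terms[ctx.machinery_var(mach.id)] = mach.peptide_mass(net.peptides)
    for pep in net.peptides.values():
        if pep.is_dummy and not include_dummy:
            continue
        terms["PEP_" + pep.id] = terms.get("PEP_" + pep.id, 0.0) + pep.mw
    return {k: v for k, v in terms.items() if v != 0.0}


def _rna_terms(ctx) -> Dict[str, float]:
    net = ctx.network
    terms: Dict[str, float] = {}
    for t in net.transcripts.values():
        terms["F_" + t.id] = t.mw
    for mach in net.machinery.values():
        m = mach.rna_mass(net.transcripts)
        if m:
            terms[ctx.machinery_var(mach.id)] = m
    for aa, pair in net.trnas.items():
        terms[f"T_c_{aa}"] = pair.mw
        terms[f"T_u_{aa}"] = pair.mw
    return terms


def add_macromolecule_totals(ctx) -> List[str]:
    """Emit the protein/RNA total-mass equalities and the phi split."""
    params, prob = ctx.allocation, ctx.problem
    labels: List[str] = []

    def total_constraint(terms: Dict[str, float], cls: str, scale: float, label: str):
        terms = dict(terms)
        if params.mode == "cb":
            rhs = scale * params.reference_fractions[cls]
        else:
            rhs = 0.0
            per_bin = [scale * x for x in ctx.bin_fractions[cls]]
            for b, v in select_by_bin(ctx.encoding, per_bin).items():
                terms[b] = terms.get(b, 0.0) - v
        labels.append(prob.add_constraint(terms, EQ, rhs, label))

    total_constraint(_protein_terms(ctx, include_dummy=True), "protein", 1.0,
                     "total_protein_mass")
    total_constraint(_rna_terms(ctx), "RNA", 1.0, "total_rna_mass")
    if params.phi < 1.0:
        total_constraint(_protein_terms(ctx, include_dummy=False), "protein",
                         params.phi, "modeled_protein_mass")
    else:
        # phi = 1: the dummy protein is forced to zero mass
        terms = {
            v: c
            for v, c in _protein_terms(ctx, include_dummy=True).items()
            if v not in _protein_terms(ctx, include_dummy=False)
        }
        if terms:
            labels.append(prob.add_constraint(terms, LE, 0.0, "dummy_protein_zero"))
        total_constraint(_protein_terms(ctx, include_dummy=False), "protein",
                         1.0, "modeled_protein_mass")
    return labels


def apply_biomass_drains(ctx) -> None:
    """Wire the residual biomass reaction into the metabolite balances.

    The (stripped, GAM-adjusted) biomass reaction's drains and byproducts
    become terms proportional to growth.  In cb mode the coefficient is the
    reference eta; in vb mode pool-class drains are rescaled per bin by
    X_u,i / X_ref,i (Eq-style variable stoichiometry) and multiplied by the
    bin's exact growth value, entering the balance through the bin
    indicators.  The ``other`` class absorbs any residual table mass so
    that the 1-gram accounting closes at every bin.
    """
    params, model = ctx.allocation, ctx.model
    mode = params.mode

    def add_growth_drain(met_id: str, eta_signed: float, cls: Optional[str]) -> None:
        bal = ctx.met_balance[met_id]
        if mode == "cb" or cls is None or (
            cls not in (ctx.bin_fractions or {}) and cls != OTHER_CLASS
        ):
            bal[ctx.mu_var] = bal.get(ctx.mu_var, 0.0) + eta_signed
            return
        if cls == OTHER_CLASS:
            mw = model.metabolites[met_id].mw
            tracked = [c for c in ctx.bin_fractions if c != OTHER_CLASS]
            per_bin = [
                max(0.0, 1.0 - sum(ctx.bin_fractions[c][u] for c in tracked)) / mw
                * math.copysign(1.0, eta_signed)
                for u in range(ctx.grid.n_bins)
            ]
        else:
            x_ref = params.reference_fractions.get(cls, 0.0)
            if x_ref == 0.0:
                raise AllocationError(
                    f"class {cls}: zero reference fraction, cannot rescale"
                )
            per_bin = [
                eta_signed * ctx.bin_fractions[cls][u] / x_ref
                for u in range(ctx.grid.n_bins)
            ]
        for u, (b, eta_u) in enumerate(
            zip(ctx.encoding.indicator_vars, per_bin)
        ):
            coef = eta_u * ctx.grid.bin_values[u]
            if coef:
                bal[b] = bal.get(b, 0.0) + coef

    for met_id, eta in ctx.model.biomass.reactants.items():
        add_growth_drain(met_id, -eta, model.biomass_class_map.get(met_id))
    for met_id, eta in ctx.model.biomass.byproducts.items():
        add_growth_drain(met_id, +eta, model.biomass_class_map.get(met_id))
    # GAM hydrolysis scales with growth in both modes
    g = model.biomass.gam_metabolites
    gam = model.biomass.gam_atp
    if gam:
        for key, sign in (("atp", -1), ("h2o", -1), ("adp", 1), ("pi", 1), ("h", 1)):
            bal = ctx.met_balance[g[key]]
            bal[ctx.mu_var] = bal.get(ctx.mu_var, 0.0) + sign * gam
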