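"""Expression layer: transcription, translation, tRNA cycling, complexation.

Macromolecule species (transcripts F_l, free peptides, enzymes E_j,
machinery) are concentration variables in mmol gDW^-1.  Each has a
steady-state balance of the form

    synthesis - degradation - mu * concentration = 0,

where the growth-dilution product mu * X is linearized through the growth
encoding.  Synthesis draws real metabolites: transcription consumes NTPs
per the gene's nucleotide composition; translation follows the ribosomal
elongation stoichiometry — per amino acid, one charged tRNA is consumed and
returned uncharged, and 2 GTP (+ H2O) are hydrolyzed to GDP + Pi + H+, so a
peptide of length L costs 2L GTP.  Machinery capacity couples those fluxes
to the amount of RNA polymerase / ribosome assigned to each gene, and
catalytic constraints cap metabolic fluxes at sum(kcat_j * E_j) over
isozymes.

Polymer molecular weights are monomer-mass sums (condensation water is not
subtracted), which keeps the mass bookkeeping between the metabolic and the
expression layers exactly closed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Set, Tuple

from .core import MetabolicModel, ModelError, parse_gpr
from .optmodel import EQ, GE, LE, Problem

#: default turnover number for enzymes lacking one: the reported median for
#: S. cerevisiae, 70.9 s^-1, converted to h^-1.
DEFAULT_KCAT_PER_H = 70.9 * 3600.0

#: transporters get an effectively unconstraining turnover of 1e9 h^-1 so
#: only the gene-protein-reaction relationship is preserved.
TRANSPORTER_KCAT_PER_H = 1e9

RIBOSOME = "ribosome"
RNA_POLYMERASE = "rna_polymerase"


class ExpressionError(ValueError):
    pass


@dataclass
class Transcript:
    id: str
    gene: str
    length_nt: int
    nt_counts: Dict[str, float]  # base -> count per molecule
    mw: float  # g mmol^-1
    kdeg: float = 0.0  # h^-1
    kind: str = "mrna"  # mrna | rrna | dummy

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ExpressionError(f"transcript {self.id}: nonpositive MW")


@dataclass
class Peptide:
    id: str
    gene: str
    length_aa: int
    aa_counts: Dict[str, float]  # amino-acid metabolite id -> count
    mw: float
    kdeg: float = 0.0
    is_dummy: bool = False

    def __post_init__(self) -> None:
        total = sum(self.aa_counts.values())
        if abs(total - self.length_aa) > 1e-6:
            raise ExpressionError(
                f"peptide {self.id}: amino-acid counts sum to {total}, "
                f"length is {self.length_aa}"
            )


@dataclass
class Enzyme:
    id: str
    composition: Dict[str, float]  # peptide id -> copy number
    kcat_fwd: Optional[float] = None  # h^-1; None -> default policy
    kcat_bwd: Optional[float] = None  # None -> same as forward
    reactions: List[str] = field(default_factory=list)
    kdeg: float = 0.0
    is_dummy: bool = False

    def mw(self, peptides: Mapping[str, Peptide]) -> float:
        return sum(n * peptides[p].mw for p, n in self.composition.items())


@dataclass
class Machinery:
    """An expression machine: a ribosome variant or an RNA polymerase.

    ``composition`` may reference both peptides and RNA species (rRNA for
    ribosomes).  ``k_el`` is the elongation rate in nt h^-1 (polymerases)
    or aa h^-1 (ribosomes); ``genes`` is the set of gene ids served — the
    transcribed genes for a polymerase, the translated (peptide) genes for
    a ribosome.
    """

    id: str
    kind: str
    composition: Dict[str, float]  # species id (peptide or transcript) -> copies
    k_el: float
    genes: Set[str] = field(default_factory=set)
    kdeg: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in (RIBOSOME, RNA_POLYMERASE):
            raise ExpressionError(f"machinery {self.id}: unknown kind {self.kind}")
        if self.k_el <= 0:
            raise ExpressionError(f"machinery {self.id}: elongation rate must be > 0")

    def peptide_mass(self, peptides: Mapping[str, Peptide]) -> float:
        return sum(
            n * peptides[p].mw for p, n in self.composition.items() if p in peptides
        )

    def rna_mass(self, transcripts: Mapping[str, Transcript]) -> float:
        return sum(
            n * transcripts[t].mw for t, n in self.composition.items() if t in transcripts
        )


@dataclass
class TRNAPair:
    """Charged/uncharged tRNA pair for one amino acid.

    The uncharged form is synthesized from NTPs (a lumped transcription-like
    reaction); charging consumes the amino acid plus one ATP.  Both forms
    dilute with growth, which is why tRNAs are tracked explicitly.
    """

    amino_acid: str  # amino-acid metabolite id
    length_nt: int
    nt_counts: Dict[str, float]
    mw: float


@dataclass
class ExpressionNetwork:
    transcripts: Dict[str, Transcript] = field(default_factory=dict)
    peptides: Dict[str, Peptide] = field(default_factory=dict)
    enzymes: Dict[str, Enzyme] = field(default_factory=dict)
    machinery: Dict[str, Machinery] = field(default_factory=dict)
    trnas: Dict[str, TRNAPair] = field(default_factory=dict)  # keyed by amino acid
    ntp_map: Dict[str, str] = field(
        default_factory=lambda: {
            "A": "atp_c", "C": "ctp_c", "G": "gtp_c", "T": "utp_c",
        }
    )
    energy: Dict[str, str] = field(
        default_factory=lambda: {
            "atp": "atp_c", "adp": "adp_c", "gtp": "gtp_c", "gdp": "gdp_c",
            "pi": "pi_c", "h2o": "h2o_c", "h": "h_c",
        }
    )

    def transcript_of_gene(self, gene: str) -> Optional[Transcript]:
        for t in self.transcripts.values():
            if t.gene == gene:
                return t
        return None

    def peptides_of_gene(self, gene: str) -> List[Peptide]:
        return [p for p in self.peptides.values() if p.gene == gene]

    def polymerase_of_gene(self, gene: str) -> Optional[Machinery]:
        for m in self.machinery.values():
            if m.kind == RNA_POLYMERASE and gene in m.genes:
                return m
        return None

    def ribosomes_of_gene(self, gene: str) -> List[Machinery]:
        return [
            m
            for m in self.machinery.values()
            if m.kind == RIBOSOME and gene in m.genes
        ]

    def validate(self, model: MetabolicModel) -> None:
        for pep in self.peptides.values():
            for aa in pep.aa_counts:
                if aa not in model.metabolites:
                    raise ExpressionError(
                        f"peptide {pep.id} references unknown amino acid {aa}"
                    )
        for enz in self.enzymes.values():
            for p in enz.composition:
                if p not in self.peptides:
                    raise ExpressionError(
                        f"enzyme {enz.id} references unknown peptide {p}"
                    )
        for t in self.transcripts.values():
            if t.gene not in model.genes and t.kind != "dummy":
                raise ExpressionError(f"transcript {t.id} has unknown gene {t.gene}")
        # every non-dummy gene must have exactly one polymerase
        for t in self.transcripts.values():
            if t.kind == "dummy":
                continue
            pols = [
                m for m in self.machinery.values()
                if m.kind == RNA_POLYMERASE and t.gene in m.genes
            ]
            if len(pols) != 1:
                raise ExpressionError(
                    f"gene {t.gene} must be assigned to exactly one RNA polymerase, "
                    f"found {len(pols)}"
                )
        for pep in self.peptides.values():
            if pep.is_dummy:
                continue
            if not self.ribosomes_of_gene(pep.gene):
                raise ExpressionError(
                    f"gene {pep.gene} (peptide {pep.id}) has no ribosome assignment"
                )


def effective_kcats(enzyme: Enzyme, is_transporter: bool) -> Tuple[float, float]:
    """Apply the default-kcat policy.

    Missing turnover numbers fall back to the S. cerevisiae median
    (70.9 s^-1); transporter enzymes get 1e9 h^-1 so they are effectively
    uncapped.  The backward kcat defaults to the forward one.
    """
    fwd = enzyme.kcat_fwd
    if fwd is None:
        fwd = TRANSPORTER_KCAT_PER_H if is_transporter else DEFAULT_KCAT_PER_H
    bwd = enzyme.kcat_bwd if enzyme.kcat_bwd is not None else fwd
    return fwd, bwd


def build_dummy_species(
    network: ExpressionNetwork,
    model: MetabolicModel,
    length_aa: int = 250,
    length_nt: Optional[int] = None,
    mrna_kdeg: Optional[float] = None,
) -> Tuple[Transcript, Peptide, Enzyme]:
    """Add the dummy protein (and dummy mRNA) to the network.

    The dummy protein represents the proteome fraction with no modeled
    catalytic task (structural proteins, chaperones, ...); it is excluded
    from every catalytic constraint but still carries full synthesis costs.
    Its composition is the count-weighted average of the non-dummy peptides
    (respectively transcripts), scaled to ``length_aa``.
    """
    if "dummy" in network.peptides:
        return (
            network.transcripts["mrna_dummy"],
            network.peptides["dummy"],
            network.enzymes["dummy_protein"],
        )
    real_peps = [p for p in network.peptides.values() if not p.is_dummy]
    if not real_peps:
        raise ExpressionError("cannot average composition: no peptides in network")
    total_aa = sum(sum(p.aa_counts.values()) for p in real_peps)
    aa_frac = {
        aa: sum(p.aa_counts.get(aa, 0.0) for p in real_peps) / total_aa
        for aa in {a for p in real_peps for a in p.aa_counts}
    }
    aa_counts = {aa: f * length_aa for aa, f in aa_frac.items()}
    aa_mw = {m: model.metabolites[m].mw for m in aa_counts}
    pep = Peptide(
        "dummy", "g_dummy", length_aa, aa_counts,
        mw=sum(aa_counts[a] * aa_mw[a] for a in aa_counts),
        is_dummy=True,
    )

    if length_nt is None:
        length_nt = 3 * length_aa
    real_trs = [t for t in network.transcripts.values() if t.kind == "mrna"]
    total_nt = sum(sum(t.nt_counts.values()) for t in real_trs)
    nt_frac = {
        b: sum(t.nt_counts.get(b, 0.0) for t in real_trs) / total_nt for b in "ACGT"
    }
    nt_counts = {b: f * length_nt for b, f in nt_frac.items()}
    ntp_mw = {b: model.metabolites[network.ntp_map[b]].mw for b in "ACGT"}
    if mrna_kdeg is None:
        mrna_kdeg = real_trs[0].kdeg if real_trs else 0.0
    tr = Transcript(
        "mrna_dummy", "g_dummy", length_nt, nt_counts,
        mw=sum(nt_counts[b] * ntp_mw[b] for b in "ACGT"),
        kdeg=mrna_kdeg, kind="dummy",
    )
    enz = Enzyme("dummy_protein", {"dummy": 1.0}, kcat_fwd=0.0, is_dummy=True)
    network.peptides[pep.id] = pep
    network.transcripts[tr.id] = tr
    network.enzymes[enz.id] = enz
    return tr, pep, enz


# ----------------------------------------------------------------------
# Constraint builders.  They operate on a BuildContext (see emekit.build)
# which carries the problem, the growth encoding, and the accumulating
# metabolite balances.
# ----------------------------------------------------------------------

def build_transcription(ctx) -> List[str]:
    """Transcription fluxes, mRNA balances, and RNA polymerase capacity.

    Per gene l with polymerase P: a flux v_tr,l consuming NTPs per the
    transcript's nucleotide composition, the balance

        v_tr,l - kdeg_l * F_l - mu * F_l = 0,

    and the capacity coupling v_tr,l <= (k_el / L_nt) * POL_assigned,l with
    conservation sum_l POL_assigned,l + POL_free = POL_total.
    """
    net, prob = ctx.network, ctx.problem
    labels: List[str] = []
    pol_assignments: Dict[str, List[str]] = {m: [] for m in net.machinery}

    for t in net.transcripts.values():
        fvar = ctx.conc_var("F_" + t.id, ctx.rna_cap / t.mw)
        v_tr = prob.add_variable("v_tr_" + t.gene, 0.0, math.inf)
        for base, count in t.nt_counts.items():
            if count:
                ctx.met_balance[net.ntp_map[base]][v_tr] = (
                    ctx.met_balance[net.ntp_map[base]].get(v_tr, 0.0) - count
                )
        dil = ctx.dilution(fvar, "F_" + t.id)
        terms = {v_tr: 1.0, fvar: -t.kdeg}
        for z, c in dil.items():
            terms[z] = terms.get(z, 0.0) - c
        # complexation may consume this transcript (rRNA); emitted at flush
        ctx.rna_balance_terms[t.id] = terms
        ctx.rna_balance_label[t.id] = f"balance_{t.id}"
        if t.kdeg:
            _degrade_rna(ctx, t, fvar)

        if t.kind == "dummy":
            pol = None
        else:
            pol = net.polymerase_of_gene(t.gene)
            if pol is None:
                raise ExpressionError(f"gene {t.gene} has no RNA polymerase")
        if pol is not None:
            a = prob.add_variable(f"POLA_{pol.id}_{t.gene}", 0.0, math.inf)
            pol_assignments[pol.id].append(a)
            labels.append(
                prob.add_constraint(
                    {v_tr: 1.0, a: -pol.k_el / t.length_nt},
                    LE, 0.0, f"cap_tr_{t.gene}",
                )
            )
        else:
            # the dummy transcript is synthesized outside polymerase capacity
            pass

    for pol in net.machinery.values():
        if pol.kind != RNA_POLYMERASE:
            continue
        free = prob.add_variable(f"POL_free_{pol.id}", 0.0, math.inf)
        terms = {a: 1.0 for a in pol_assignments[pol.id]}
        terms[free] = 1.0
        terms[ctx.machinery_var(pol.id)] = -1.0
        labels.append(prob.add_constraint(terms, EQ, 0.0, f"pol_total_{pol.id}"))
    return labels


def build_translation(ctx) -> List[str]:
    """Translation fluxes, peptide balances, ribosome capacity and loading.

    Per peptide l of length L: the flux v_tl,l consumes one charged tRNA per
    amino acid (returned uncharged) and 2L GTP + 2L H2O, releasing
    2L (GDP + Pi + H+).  Capacity: v_tl,l <= (k_el / L) * sum over serving
    ribosome variants of RIB_assigned; assigned ribosomes on a transcript
    are additionally capped by the mRNA level (polysome loading), so a
    transcription knockout silences translation too.
    """
    net, prob, cfg = ctx.network, ctx.problem, ctx.config
    labels: List[str] = []
    rib_assignments: Dict[str, List[str]] = {m: [] for m in net.machinery}

    for pep in net.peptides.values():
        pvar = ctx.conc_var("PEP_" + pep.id, ctx.protein_cap / pep.mw)
        v_tl = prob.add_variable("v_tl_" + pep.id, 0.0, math.inf)

        e = net.energy
        for aa, count in pep.aa_counts.items():
            if count == 0:
                continue
            tr_pair = net.trnas.get(aa)
            if tr_pair is not None:
                ctx.trna_usage[aa][v_tl] = ctx.trna_usage[aa].get(v_tl, 0.0) + count
            else:
                # no tRNA modeled: draw the amino acid directly
                ctx.met_balance[aa][v_tl] = ctx.met_balance[aa].get(v_tl, 0.0) - count
        cost = cfg.gtp_per_aa * pep.length_aa
        for met, sign in ((e["gtp"], -1), (e["h2o"], -1), (e["gdp"], 1), (e["pi"], 1), (e["h"], 1)):
            ctx.met_balance[met][v_tl] = ctx.met_balance[met].get(v_tl, 0.0) + sign * cost

        dil = ctx.dilution(pvar, "PEP_" + pep.id)
        terms = {v_tl: 1.0, pvar: -pep.kdeg}
        for z, c in dil.items():
            terms[z] = terms.get(z, 0.0) - c
        # complexation consumption is appended later via ctx.peptide_use
        ctx.peptide_balance_terms[pep.id] = terms
        ctx.peptide_balance_label[pep.id] = f"balance_pep_{pep.id}"
        if pep.kdeg:
            _degrade_peptide(ctx, pep, pvar)

        if pep.is_dummy:
            # the dummy protein rides the cytosolic (nuclear-gene) variants
            nuclear = {
                g for g, gene in ctx.model.genes.items()
                if gene.locus_class == "nuclear"
            }
            ribs = [
                m for m in net.machinery.values()
                if m.kind == RIBOSOME and (m.genes & nuclear)
            ]
        else:
            ribs = net.ribosomes_of_gene(pep.gene)
        if not pep.is_dummy and not ribs:
            raise ExpressionError(f"peptide {pep.id} has no ribosome assignment")
        cap_terms = {v_tl: 1.0}
        for rib in ribs:
            a = prob.add_variable(f"RIBA_{rib.id}_{pep.id}", 0.0, math.inf)
            rib_assignments[rib.id].append(a)
            cap_terms[a] = -rib.k_el / pep.length_aa
            # polysome loading: ribosomes on a transcript <= slots * mRNA
            tr = net.transcript_of_gene(pep.gene)
            if tr is not None and cfg.ribosome_footprint_nt > 0:
                slots = max(1.0, tr.length_nt / cfg.ribosome_footprint_nt)
                labels.append(
                    prob.add_constraint(
                        {a: 1.0, "F_" + tr.id: -slots},
                        LE, 0.0, f"loading_{rib.id}_{pep.id}",
                    )
                )
        if ribs:
            labels.append(
                prob.add_constraint(cap_terms, LE, 0.0, f"cap_tl_{pep.id}")
            )

    for rib in net.machinery.values():
        if rib.kind != RIBOSOME:
            continue
        free = prob.add_variable(f"RIB_free_{rib.id}", 0.0, math.inf)
        terms = {a: 1.0 for a in rib_assignments[rib.id]}
        terms[free] = 1.0
        terms[ctx.machinery_var(rib.id)] = -1.0
        labels.append(prob.add_constraint(terms, EQ, 0.0, f"rib_total_{rib.id}"))
    return labels


def build_trna_cycle(ctx) -> List[str]:
    """tRNA synthesis, charging and dilution balances.

    Charging: aa + tRNA_uncharged -> tRNA_charged (plus ATP hydrolysis when
    the config sets a nonzero aminoacylation cost; by default that energy is
    lumped into maintenance, the explicit translation cost being the 2 GTP
    per amino acid).  Charged balance: v_charge - usage - mu*Tc = 0;
    uncharged: v_syn + usage - v_charge - mu*Tu = 0, with v_syn a lumped
    NTP-consuming synthesis flux.
    """
    net, prob = ctx.network, ctx.problem
    labels: List[str] = []
    e = net.energy
    atp_cost = getattr(ctx.config, "atp_per_charging", 0.0)
    for aa, pair in net.trnas.items():
        tc = ctx.conc_var(f"T_c_{aa}", ctx.rna_cap / pair.mw)
        tu = ctx.conc_var(f"T_u_{aa}", ctx.rna_cap / pair.mw)
        v_charge = prob.add_variable(f"v_charge_{aa}", 0.0, math.inf)
        v_syn = prob.add_variable(f"v_syn_trna_{aa}", 0.0, math.inf)
        for base, count in pair.nt_counts.items():
            if count:
                ctx.met_balance[net.ntp_map[base]][v_syn] = (
                    ctx.met_balance[net.ntp_map[base]].get(v_syn, 0.0) - count
                )
        charge_stoich = [(aa, -1.0)]
        if atp_cost:
            charge_stoich += [
                (e["atp"], -atp_cost), (e["adp"], atp_cost), (e["pi"], atp_cost),
            ]
        for met, coef in charge_stoich:
            ctx.met_balance[met][v_charge] = (
                ctx.met_balance[met].get(v_charge, 0.0) + coef
            )
        usage = ctx.trna_usage[aa]  # translation fluxes consuming charged tRNA
        dil_c = ctx.dilution(tc, f"T_c_{aa}")
        terms_c = {v_charge: 1.0}
        for v, n in usage.items():
            terms_c[v] = terms_c.get(v, 0.0) - n
        for z, c in dil_c.items():
            terms_c[z] = terms_c.get(z, 0.0) - c
        labels.append(prob.add_constraint(terms_c, EQ, 0.0, f"balance_trna_c_{aa}"))
        dil_u = ctx.dilution(tu, f"T_u_{aa}")
        terms_u = {v_syn: 1.0, v_charge: -1.0}
        for v, n in usage.items():
            terms_u[v] = terms_u.get(v, 0.0) + n
        for z, c in dil_u.items():
            terms_u[z] = terms_u.get(z, 0.0) - c
        labels.append(prob.add_constraint(terms_u, EQ, 0.0, f"balance_trna_u_{aa}"))
    return labels


def build_complexation_degradation(ctx) -> List[str]:
    """Enzyme/machinery complexation fluxes and their balances.

    Per enzyme j: v_cplx,j consumes the constituent peptide copies (and rRNA
    copies for ribosomes) and the balance v_cplx,j - kdeg,j E_j - mu E_j = 0
    holds.  Degradation recycles the composition back to precursors.
    """
    net, prob = ctx.network, ctx.problem
    labels: List[str] = []

    species: List[Tuple[str, Dict[str, float], float, str]] = []
    for enz in net.enzymes.values():
        cvar = ctx.conc_var("E_" + enz.id, ctx.protein_cap / enz.mw(net.peptides))
        species.append((enz.id, enz.composition, enz.kdeg, cvar))
    for mach in net.machinery.values():
        species.append((mach.id, mach.composition, mach.kdeg, ctx.machinery_var(mach.id)))

    for sid, comp, kdeg, cvar in species:
        v_cplx = prob.add_variable(f"v_cplx_{sid}", 0.0, math.inf)
        for part, copies in comp.items():
            if part in net.peptides:
                ctx.peptide_use[part][v_cplx] = (
                    ctx.peptide_use[part].get(v_cplx, 0.0) + copies
                )
            elif part in net.transcripts:
                # rRNA incorporation: consumes the free transcript
                ctx.rna_use[part][v_cplx] = (
                    ctx.rna_use[part].get(v_cplx, 0.0) + copies
                )
            else:
                raise ExpressionError(
                    f"composition of {sid} references unknown species {part}"
                )
        dil = ctx.dilution(cvar, cvar)
        terms = {v_cplx: 1.0, cvar: -kdeg}
        for z, c in dil.items():
            terms[z] = terms.get(z, 0.0) - c
        labels.append(prob.add_constraint(terms, EQ, 0.0, f"balance_{cvar}"))
        if kdeg:
            _degrade_complex(ctx, sid, comp, cvar, kdeg)
    return labels


def add_catalytic_constraints(ctx) -> List[str]:
    """Cap each catalyzed flux direction at the summed isozyme capacity.

    v_i <= sum_j kcat_j * E_j over the isozymes j of reaction i (forward and
    backward separately; V_max = kcat * E_total).  Reactions without a GPR
    are left unconstrained; dummy species never appear here.
    """
    net, prob, model = ctx.network, ctx.problem, ctx.model
    labels: List[str] = []
    by_rxn: Dict[str, List[Enzyme]] = {}
    for enz in net.enzymes.values():
        if enz.is_dummy:
            continue
        for r in enz.reactions:
            by_rxn.setdefault(r, []).append(enz)

    for rxn_id, enzymes in by_rxn.items():
        rxn = model.reactions.get(rxn_id)
        if rxn is None:
            continue
        for direction, getter in (("fwd", 0), ("bwd", 1)):
            vname = f"v_{direction}_{rxn_id}"
            if vname not in prob.variables:
                continue
            var = prob.variables[vname]
            if var.upper == 0.0:
                continue
            terms = {vname: 1.0}
            for enz in enzymes:
                kf, kb = effective_kcats(enz, rxn.is_transport)
                k = kf if direction == "fwd" else kb
                if k <= 0:
                    raise ExpressionError(
                        f"enzyme {enz.id} has nonpositive kcat for {rxn_id}"
                    )
                terms["E_" + enz.id] = terms.get("E_" + enz.id, 0.0) - k
            labels.append(
                prob.add_constraint(terms, LE, 0.0, f"catalytic_{direction}_{rxn_id}")
            )
    return labels


# -- degradation helpers ------------------------------------------------

def _degrade_rna(ctx, transcript: Transcript, fvar: str) -> None:
    """First-order RNA decay recycling nucleotides.

    The decay flux v_deg = kdeg * F is explicit; it returns the nucleotide
    counts to the NTP pools at a re-phosphorylation cost of 2 ATP per
    nucleotide (lumped NMP -> NTP).
    """
    net, prob = ctx.network, ctx.problem
    v_deg = prob.add_variable(f"v_deg_{transcript.id}", 0.0, math.inf)
    prob.add_constraint(
        {v_deg: 1.0, fvar: -transcript.kdeg}, EQ, 0.0, f"deg_rate_{transcript.id}"
    )
    e = net.energy
    total_nt = sum(transcript.nt_counts.values())
    for base, count in transcript.nt_counts.items():
        if count:
            met = net.ntp_map[base]
            ctx.met_balance[met][v_deg] = ctx.met_balance[met].get(v_deg, 0.0) + count
    cost = 2.0 * total_nt
    for met, sign in ((e["atp"], -1), (e["adp"], 1), (e["pi"], 1)):
        ctx.met_balance[met][v_deg] = ctx.met_balance[met].get(v_deg, 0.0) + sign * cost


def _degrade_peptide(ctx, pep: Peptide, pvar: str) -> None:
    net, prob = ctx.network, ctx.problem
    v_deg = prob.add_variable(f"v_deg_pep_{pep.id}", 0.0, math.inf)
    prob.add_constraint({v_deg: 1.0, pvar: -pep.kdeg}, EQ, 0.0, f"deg_rate_pep_{pep.id}")
    for aa, count in pep.aa_counts.items():
        ctx.met_balance[aa][v_deg] = ctx.met_balance[aa].get(v_deg, 0.0) + count


def _degrade_complex(
    ctx, sid: str, comp: Dict[str, float], cvar: str, kdeg: float
) -> None:
    """Complex decay releases amino acids of all constituent peptides."""
    net, prob = ctx.network, ctx.problem
    v_deg = prob.add_variable(f"v_deg_cplx_{sid}", 0.0, math.inf)
    prob.add_constraint({v_deg: 1.0, cvar: -kdeg}, EQ, 0.0, f"deg_rate_cplx_{sid}")
    for part, copies in comp.items():
        pep = net.peptides.get(part)
        if pep is None:
            continue
        for aa, count in pep.aa_counts.items():
            ctx.met_balance[aa][v_deg] = (
                ctx.met_balance[aa].get(v_deg, 0.0) + copies * count
            )
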