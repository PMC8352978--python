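"""Deterministic generator of small eukaryote-like ME model documents.

The generated organism is a two-compartment (cytosol + mitochondrion)
caricature of a Crabtree-positive yeast:

* glucose uptake, a lumped glycolysis (2 ATP, 2 NADH per glucose) with two
  isozymes, and two ATP-regenerating branches — mitochondrial respiration
  (high ATP yield per glucose, catalyzed by a slow nuclear+mitochondrial
  enzyme complex) and cytosolic fermentation to ethanol (low yield, fast
  cheap enzyme).  Respiration therefore wins whenever proteome is abundant
  and fermentation takes over when it is not, which is exactly the
  proteome-limitation route to overflow metabolism;
* a four-letter amino-acid alphabet with tRNA pairs, NTP/dNTP synthesis,
  and pooled carbohydrate/lipid/ion/DNA biomass classes;
* a compartmentalized expression system: nuclear and mitochondrial RNA
  polymerases, two cytosolic ribosome variants (A/B peptide sets) plus a
  mitochondrial ribosome, with rRNA species entering ribosome complexation.

Network topology is fixed by the flags; the seeded RNG only draws gene
sequences and amino-acid compositions, so qualitative properties (growth
plateau, overflow switch, essential/isozyme genes) hold by construction.
The same seed yields byte-identical documents.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .allocation import CompositionTable
from .core import BiomassReaction, Gene, MetabolicModel, Metabolite, Reaction
from .expression import (
    RIBOSOME,
    RNA_POLYMERASE,
    Enzyme,
    ExpressionNetwork,
    Machinery,
    Peptide,
    Transcript,
    TRNAPair,
)
from .iodocs import ModelDocument


class ToySpecError(ValueError):
    pass


@dataclass
class ToySpec:
    """Parameters of the generated toy organism."""

    seed: int = 1
    include_mitochondrion: bool = True
    overflow_mode: bool = True
    n_bins: int = 8
    mu_max: float = 0.75  # h^-1
    glucose_uptake: float = 10.0  # mmol gDW^-1 h^-1
    ngam: float = 1.0  # non-growth maintenance ATP, mmol gDW^-1 h^-1
    gam_atp: float = 30.0  # mmol gDW^-1
    phi: float = 0.55
    kcat_jitter: float = 0.05  # relative, seeded
    ribosome_el_aa_s: float = 10.5
    polymerase_el_nt_s: float = 60.0

    def __post_init__(self) -> None:
        if self.mu_max <= 0 or self.glucose_uptake <= 0:
            raise ToySpecError("spec below minimal viability")
        if self.n_bins < 2:
            raise ToySpecError("need at least 2 growth bins")


# molecular weights, g mmol^-1
MW = {
    "glc": 0.180, "o2": 0.032, "co2": 0.044, "etoh": 0.046, "nh4": 0.018,
    "pyr": 0.088, "atp": 0.507, "adp": 0.427, "gtp": 0.523, "gdp": 0.443,
    "ctp": 0.483, "utp": 0.484, "pi": 0.097, "h2o": 0.018, "h": 0.001,
    "nad": 0.663, "nadh": 0.664, "dntp": 0.490, "dna": 0.490,
    "carb": 0.162, "lipid": 0.700, "ion": 0.050,
    "aa_ala": 0.089, "aa_arg": 0.174, "aa_asn": 0.132, "aa_asp": 0.133,
}

# standard Gibbs energies of formation, kJ mol^-1 (aqueous, transformed);
# pool pseudometabolites stay unannotated, mimicking abstract compounds
DGF = {
    "glc": -426.7, "pyr": -350.8, "etoh": -181.8, "co2": -386.0, "o2": 16.4,
    "nh4": -79.5, "atp": -2771.0, "adp": -1903.7, "gtp": -2768.1,
    "gdp": -1900.8, "pi": -1059.5, "h2o": -157.3, "h": 0.0,
    "nad": -1038.9, "nadh": -1010.5, "ctp": -2700.0, "utp": -2705.0,
}

AMINO_ACIDS = ("aa_ala", "aa_arg", "aa_asn", "aa_asp")
NTP_BASES = {"A": "atp_c", "C": "ctp_c", "G": "gtp_c", "T": "utp_c"}

# reference biomass mass fractions, g gDW^-1 (sum to 1)
REF_FRACTIONS = {
    "protein": 0.40, "RNA": 0.06, "DNA": 0.01,
    "carbohydrate": 0.38, "lipid": 0.12, "ion": 0.03,
}

# growth-dependent composition (rows sum to 1); protein and RNA rise with
# growth while storage carbohydrate falls, the standard chemostat trend
COMPOSITION_TABLE = {
    "growth_rate_h": [0.0, 0.15, 0.30, 0.45, 0.60, 0.75],
    "protein": [0.34, 0.37, 0.40, 0.43, 0.45, 0.46],
    "RNA": [0.040, 0.048, 0.060, 0.075, 0.090, 0.100],
    "DNA": [0.012, 0.011, 0.010, 0.009, 0.008, 0.008],
    "carbohydrate": [0.44, 0.41, 0.38, 0.345, 0.31, 0.29],
    "lipid": [0.125, 0.122, 0.120, 0.115, 0.112, 0.110],
    "ion": [0.043, 0.039, 0.030, 0.026, 0.030, 0.032],
}

# gene id -> (peptide length in aa, locus class); rRNA genes carry
# (transcript length in nt, locus) and no peptide
PEPTIDE_GENES = {
    "g_glt": 300, "g_glyA": 450, "g_glyB": 450, "g_fer": 350,
    "g_respN": 600, "g_aa": 400, "g_ntp": 400, "g_carb": 350, "g_lip": 500,
    "g_rpA": 400, "g_rpB": 400, "g_rpM": 350, "g_rnapN": 500, "g_rnapM": 450,
}
MITO_PEPTIDE_GENES = {"g_respM": 400}
RRNA_GENES = {"g_rrnaC": (3500, "nuclear"), "g_rrnaM": (2500, "mitochondrial")}

# turnover numbers, s^-1; respiration is slow per unit mass (a lumped
# electron-transport chain), fermentation cheap and fast — the inequality
# that produces the overflow switch under a fixed proteome budget
KCAT_S = {
    "glyA": 50.0, "glyB": 50.0, "fer": 300.0, "resp": 0.25,
    "aa": 20.0, "ntp": 20.0, "carb": 30.0, "lip": 30.0,
}
KCAT_RESP_NO_OVERFLOW_S = 50.0  # removes the proteome pressure on respiration


def _seq(rng: random.Random, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


def _aa_counts(rng: random.Random, length: int) -> Dict[str, float]:
    # mean-field composition: every peptide carries the average mixture, so
    # the biomass amino-acid drains and the explicit translation demand
    # describe the same proteome (counts may be fractional)
    return {f"{aa}_c": length / len(AMINO_ACIDS) for aa in AMINO_ACIDS}


def generate_toy_model(spec: Optional[ToySpec] = None) -> ModelDocument:
    """Emit the complete toy model document for a spec (same seed, same bytes)."""
    spec = spec or ToySpec()
    rng = random.Random(spec.seed)
    mito = spec.include_mitochondrion

    compartments = {"c": "cytosol", "e": "extracellular"}
    if mito:
        compartments["m"] = "mitochondrion"

    mets: Dict[str, Metabolite] = {}

    def met(stem: str, comp: str, membrane: bool = False) -> str:
        mid = f"{stem}_{comp}"
        if mid not in mets:
            mets[mid] = Metabolite(
                mid, comp, name=stem, mw=MW[stem],
                dgf=DGF.get(stem) if comp != "e" else DGF.get(stem),
                is_membrane_associated=membrane,
            )
        return mid

    for stem in ("glc", "o2", "co2", "etoh", "nh4", "ion"):
        met(stem, "e")
    for stem in (
        "glc", "o2", "co2", "etoh", "nh4", "pyr", "atp", "adp", "gtp", "gdp",
        "ctp", "utp", "pi", "h2o", "h", "nad", "nadh", "dntp", "dna", "carb",
        "lipid", "ion",
    ):
        met(stem, "c")
    for aa in AMINO_ACIDS:
        met(aa, "c")
    resp_comp = "m" if mito else "c"
    if mito:
        met("o2", "m")
        met("co2", "m")
        met("pyr", "m")

    # amino-acid formation energies chosen so synthesis runs 50 kJ downhill
    atp_drive = DGF["atp"] - DGF["adp"] - DGF["pi"]
    for aa in AMINO_ACIDS:
        mets[f"{aa}_c"].dgf = DGF["glc"] + DGF["nh4"] + atp_drive - 50.0
    for pool in ("dntp", "dna", "carb", "lipid", "ion"):
        for comp in compartments:
            if f"{pool}_{comp}" in mets:
                mets[f"{pool}_{comp}"].dgf = None  # abstract pools: no dGf

    rxns: Dict[str, Reaction] = {}

    def rxn(rid: str, stoich: Dict[str, float], lower=0.0, upper=1000.0,
            gpr="", transport=False) -> None:
        rxns[rid] = Reaction(rid, stoich, lower, upper, gpr, is_transport=transport)

    # exchanges (boundary; excluded from thermodynamic coupling)
    rxn("EX_glc", {"glc_e": -1}, lower=-spec.glucose_uptake, upper=0.0, transport=True)
    rxn("EX_o2", {"o2_e": -1}, lower=-1000.0, upper=0.0, transport=True)
    rxn("EX_co2", {"co2_e": -1}, lower=0.0, upper=1000.0, transport=True)
    rxn("EX_etoh", {"etoh_e": -1}, lower=0.0, upper=1000.0, transport=True)
    rxn("EX_nh4", {"nh4_e": -1}, lower=-1000.0, upper=0.0, transport=True)
    rxn("EX_ion", {"ion_e": -1}, lower=-1000.0, upper=0.0, transport=True)
    rxn("SINK_h2o", {"h2o_c": -1}, lower=-1000.0, upper=1000.0, transport=True)
    rxn("SINK_h", {"h_c": -1}, lower=-1000.0, upper=1000.0, transport=True)

    # transport
    rxn("T_glc", {"glc_e": -1, "glc_c": 1}, gpr="g_glt", transport=True)
    rxn("T_o2", {"o2_e": -1, "o2_c": 1}, transport=True)
    rxn("T_co2", {"co2_c": -1, "co2_e": 1}, transport=True)
    rxn("T_etoh", {"etoh_c": -1, "etoh_e": 1}, transport=True)
    rxn("T_nh4", {"nh4_e": -1, "nh4_c": 1}, transport=True)
    rxn("T_ion", {"ion_e": -1, "ion_c": 1}, transport=True)
    if mito:
        rxn("T_o2m", {"o2_c": -1, "o2_m": 1}, transport=True)
        rxn("T_co2m", {"co2_m": -1, "co2_c": 1}, transport=True)
        rxn("T_pyr", {"pyr_c": -1, "pyr_m": 1}, transport=True)

    # central carbon metabolism (lumped)
    rxn("GLYC", {
        "glc_c": -1, "adp_c": -2, "pi_c": -2, "nad_c": -2,
        "pyr_c": 2, "atp_c": 2, "nadh_c": 2, "h2o_c": 2,
    }, gpr="g_glyA or g_glyB")
    rxn("FERM", {
        "pyr_c": -1, "nadh_c": -1, "h_c": -1,
        "etoh_c": 1, "co2_c": 1, "nad_c": 1,
    }, gpr="g_fer")
    resp_gpr = "g_respN and g_respM" if mito else "g_respN"
    rxn("RESP", {
        f"pyr_{resp_comp}": -1, f"o2_{resp_comp}": -2.5,
        "adp_c": -12.5, "pi_c": -12.5, "h_c": -12.5,
        f"co2_{resp_comp}": 3, "atp_c": 12.5, "h2o_c": 13.5,
    }, gpr=resp_gpr)
    # respiratory oxidation of cytosolic NADH (shares the chain enzyme)
    rxn("NOX", {
        "nadh_c": -1, "o2_c": -0.5, "adp_c": -2, "pi_c": -2, "h_c": -3,
        "nad_c": 1, "atp_c": 2, "h2o_c": 3,
    }, gpr=resp_gpr)

    # anabolism
    for aa in AMINO_ACIDS:
        rxn(f"AASYN_{aa[3:]}", {
            "glc_c": -1, "nh4_c": -1, "atp_c": -1,
            f"{aa}_c": 1, "adp_c": 1, "pi_c": 1,
        }, gpr="g_aa")
    for ntp in ("gtp", "ctp", "utp"):
        rxn(f"NTPSYN_{ntp}", {
            "glc_c": -1, "nh4_c": -1, "atp_c": -2,
            f"{ntp}_c": 1, "adp_c": 2, "pi_c": 2,
        }, gpr="g_ntp")
    # adenosine backbone synthesis (as ADP; energy metabolism phosphorylates)
    rxn("AXPSYN", {
        "glc_c": -1, "nh4_c": -1, "atp_c": -1, "adp_c": 2, "pi_c": 2,
    }, gpr="g_ntp")
    rxn("DNTPSYN", {
        "glc_c": -1, "nh4_c": -1, "atp_c": -2,
        "dntp_c": 1, "adp_c": 2, "pi_c": 2,
    })
    rxn("DNASYN", {"dntp_c": -1, "dna_c": 1})
    rxn("NDK", {"atp_c": -1, "gdp_c": -1, "adp_c": 1, "gtp_c": 1},
        lower=-1000.0)
    rxn("POOL_carb", {
        "glc_c": -1, "atp_c": -1, "carb_c": 1, "adp_c": 1, "pi_c": 1,
    }, gpr="g_carb")
    rxn("POOL_lipid", {
        "glc_c": -4, "atp_c": -10,
        "lipid_c": 1, "adp_c": 10, "pi_c": 10,
    }, gpr="g_lip")
    rxn("NGAM", {
        "atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1,
    }, lower=spec.ngam)

    # genes with seeded sequences
    genes: Dict[str, Gene] = {}
    pep_lengths = dict(PEPTIDE_GENES)
    if mito:
        pep_lengths.update(MITO_PEPTIDE_GENES)
    else:
        pep_lengths.pop("g_rpM", None)
        pep_lengths.pop("g_rnapM", None)
    for gid in sorted(pep_lengths):
        locus = "mitochondrial" if gid in MITO_PEPTIDE_GENES else "nuclear"
        genes[gid] = Gene(gid, sequence=_seq(rng, 3 * pep_lengths[gid]),
                          locus_class=locus)
    rrna_genes = dict(RRNA_GENES) if mito else {"g_rrnaC": RRNA_GENES["g_rrnaC"]}
    for gid in sorted(rrna_genes):
        length, locus = rrna_genes[gid]
        genes[gid] = Gene(gid, sequence=_seq(rng, length), locus_class=locus)

    # biomass: drains per class scaled to the reference fractions
    reactants: Dict[str, float] = {}
    class_map: Dict[str, str] = {}
    # equal counts per amino acid, total mass = protein fraction
    mw_avg = sum(MW[aa] for aa in AMINO_ACIDS) / len(AMINO_ACIDS)
    per_aa_count = REF_FRACTIONS["protein"] / mw_avg / len(AMINO_ACIDS)
    for aa in AMINO_ACIDS:
        reactants[f"{aa}_c"] = per_aa_count
        class_map[f"{aa}_c"] = "protein"
    per_ntp = REF_FRACTIONS["RNA"] / 4.0
    for stem in ("atp", "gtp", "ctp", "utp"):
        reactants[f"{stem}_c"] = per_ntp / MW[stem]
        class_map[f"{stem}_c"] = "RNA"
    for stem, cls in (("dna", "DNA"), ("carb", "carbohydrate"),
                      ("lipid", "lipid"), ("ion", "ion")):
        reactants[f"{stem}_c"] = REF_FRACTIONS[cls] / MW[stem]
        class_map[f"{stem}_c"] = cls
    biomass = BiomassReaction(reactants=reactants, gam_atp=spec.gam_atp)

    model = MetabolicModel(
        id=f"toy_s{spec.seed}",
        compartments=compartments,
        metabolites=mets,
        reactions=rxns,
        genes=genes,
        biomass=biomass,
        biomass_class_map=class_map,
        amino_acids=[f"{aa}_c" for aa in AMINO_ACIDS],
    )

    network = _build_network(spec, rng, model, pep_lengths, rrna_genes)

    table = CompositionTable(
        COMPOSITION_TABLE["growth_rate_h"],
        {k: v for k, v in COMPOSITION_TABLE.items() if k != "growth_rate_h"},
    )
    return ModelDocument(
        model=model, network=network, table=table,
        allocation_mode="cb", phi=spec.phi,
        mu_max=spec.mu_max, n_bins=spec.n_bins,
    )


def _build_network(
    spec: ToySpec,
    rng: random.Random,
    model: MetabolicModel,
    pep_lengths: Dict[str, int],
    rrna_genes: Dict[str, Tuple[int, str]],
) -> ExpressionNetwork:
    mito = spec.include_mitochondrion
    net = ExpressionNetwork()

    for gid, gene in model.genes.items():
        counts = gene.nt_counts()
        mw = sum(counts[b] * MW[NTP_BASES[b].split("_")[0]] for b in counts)
        kind = "rrna" if gid in rrna_genes else "mrna"
        prefix = "rrna" if kind == "rrna" else "mrna"
        net.transcripts[f"{prefix}_{gid}"] = Transcript(
            f"{prefix}_{gid}", gid, gene.length_nt, counts, mw, kind=kind
        )

    for gid, length in sorted(pep_lengths.items()):
        counts = _aa_counts(rng, length)
        mw = sum(counts[a] * MW[a[:-2]] for a in counts)
        net.peptides[f"pep_{gid[2:]}"] = Peptide(
            f"pep_{gid[2:]}", gid, length, counts, mw
        )

    def jitter(x: float) -> float:
        return x * (1.0 + spec.kcat_jitter * (2.0 * rng.random() - 1.0))

    kcats = dict(KCAT_S)
    if not spec.overflow_mode:
        kcats["resp"] = KCAT_RESP_NO_OVERFLOW_S
    resp_comp = {"pep_respN": 2.0}
    if mito:
        resp_comp["pep_respM"] = 1.0
    enzyme_defs = [
        ("glt", {"pep_glt": 1.0}, None, ["T_glc"]),
        ("glyA", {"pep_glyA": 1.0}, kcats["glyA"], ["GLYC"]),
        ("glyB", {"pep_glyB": 1.0}, kcats["glyB"], ["GLYC"]),
        ("fer", {"pep_fer": 1.0}, kcats["fer"], ["FERM"]),
        ("resp", resp_comp, kcats["resp"], ["RESP", "NOX"]),
        ("aa", {"pep_aa": 1.0}, kcats["aa"],
         [f"AASYN_{aa[3:]}" for aa in AMINO_ACIDS]),
        ("ntp", {"pep_ntp": 1.0}, kcats["ntp"],
         ["NTPSYN_gtp", "NTPSYN_ctp", "NTPSYN_utp", "AXPSYN"]),
        ("carb", {"pep_carb": 1.0}, kcats["carb"], ["POOL_carb"]),
        ("lip", {"pep_lip": 1.0}, kcats["lip"], ["POOL_lipid"]),
    ]
    for eid, comp, kcat_s, rids in enzyme_defs:
        kcat_h = None if kcat_s is None else jitter(kcat_s) * 3600.0
        net.enzymes[eid] = Enzyme(eid, comp, kcat_fwd=kcat_h, reactions=rids)

    nuclear_genes = {
        g for g, gene in model.genes.items() if gene.locus_class == "nuclear"
    }
    mito_genes = set(model.genes) - nuclear_genes
    k_el_rib = spec.ribosome_el_aa_s * 3600.0
    k_el_pol = spec.polymerase_el_nt_s * 3600.0
    nuclear_pep_genes = {g for g in pep_lengths if g in nuclear_genes}

    net.machinery["rnap_nuc"] = Machinery(
        "rnap_nuc", RNA_POLYMERASE, {"pep_rnapN": 2.0}, k_el_pol,
        genes=set(nuclear_genes),
    )
    net.machinery["rib_A"] = Machinery(
        "rib_A", RIBOSOME, {"pep_rpA": 16.0, "rrna_g_rrnaC": 1.0}, k_el_rib,
        genes=set(nuclear_pep_genes),
    )
    net.machinery["rib_B"] = Machinery(
        "rib_B", RIBOSOME, {"pep_rpB": 16.0, "rrna_g_rrnaC": 1.0}, k_el_rib,
        genes=set(nuclear_pep_genes),
    )
    if mito:
        net.machinery["rnap_mito"] = Machinery(
            "rnap_mito", RNA_POLYMERASE, {"pep_rnapM": 1.0}, 0.8 * k_el_pol,
            genes=set(mito_genes),
        )
        net.machinery["rib_M"] = Machinery(
            "rib_M", RIBOSOME, {"pep_rpM": 8.0, "rrna_g_rrnaM": 1.0},
            0.8 * k_el_rib, genes={"g_respM"},
        )

    for aa in AMINO_ACIDS:
        counts = {b: 19.0 for b in "ACGT"}
        mw = sum(counts[b] * MW[NTP_BASES[b].split("_")[0]] for b in counts)
        net.trnas[f"{aa}_c"] = TRNAPair(f"{aa}_c", 76, counts, mw)
    return net


def essentiality_truth(spec: Optional[ToySpec] = None) -> Dict[str, bool]:
    """Constructed ground-truth essentiality of the toy genes.

    Essential: single-copy genes on the sole route to biomass (glucose
    transport, amino-acid/NTP synthesis, pools, nuclear expression
    machinery, cytosolic rRNA).  Nonessential: either glycolysis isozyme,
    fermentation or respiration alone (the other branch regenerates ATP),
    either cytosolic ribosome variant, and the mitochondrial system when
    fermentation can carry growth.
    """
    spec = spec or ToySpec()
    truth = {
        "g_glt": True, "g_aa": True, "g_ntp": True, "g_carb": True,
        "g_lip": True, "g_rnapN": True, "g_rrnaC": True,
        "g_glyA": False, "g_glyB": False, "g_fer": False, "g_respN": False,
        "g_rpA": False, "g_rpB": False,
    }
    if spec.include_mitochondrion:
        truth.update({
            "g_respM": False, "g_rrnaM": False, "g_rpM": False,
            "g_rnapM": False,
        })
    return truth


def generate_printed_fixtures() -> Dict[str, Dict[str, float]]:
    """Machine-readable worked-example inputs used by the validation suite.

    ``metabolic_gene_screen``: the metabolic-gene essentiality confusion
    matrix (experimental rows x predicted columns).
    ``combined_gene_screen``: the screen extended with expression genes.
    ``gam``: the biomass amino-acid total feeding the maintenance
    adjustment.  ``grid``: the study-scale growth discretization.
    """
    return {
        "metabolic_gene_screen": {"TP": 53.0, "FN": 106.0, "FP": 12.0, "TN": 945.0},
        "combined_gene_screen": {"TP": 72.0, "FN": 118.0, "FP": 16.0, "TN": 1132.0},
        "gam": {"A_tot": 4.1},
        "grid": {"mu_max": 0.75, "N": 128.0},
    }
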