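"""Model-document IO: COBRA-dialect JSON with extension blocks, plus
FASTA/TSV/CSV side formats.

The document schema ("eme-kit/1") keeps the metabolic section in the shape
standard constraint-based tooling expects — ``metabolites``, ``reactions``
(including the biomass reaction), ``genes``, ``compartments`` — and adds
ignorable extension blocks: ``biomass`` (structured drains/byproducts/GAM
and class map), ``expression`` (transcripts, peptides, enzymes, machinery,
tRNA), ``allocation`` (mode, phi, composition table), ``discretization``
(mu_max, N).  Unknown extension blocks are preserved verbatim on
round-trip.  Writing is key-sorted, so write(read(x)) is byte-stable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .allocation import CompositionTable
from .core import BiomassReaction, Gene, MetabolicModel, Metabolite, Reaction
from .expression import (
    Enzyme,
    ExpressionNetwork,
    Machinery,
    Peptide,
    Transcript,
    TRNAPair,
)

SCHEMA = "eme-kit/1"
KNOWN_BLOCKS = {
    "schema", "id", "compartments", "metabolites", "reactions", "genes",
    "biomass", "expression", "allocation", "discretization",
}


class DocumentError(ValueError):
    pass


@dataclass
class ModelDocument:
    model: MetabolicModel
    network: Optional[ExpressionNetwork] = None
    table: Optional[CompositionTable] = None
    allocation_mode: str = "cb"
    phi: float = 0.55
    mu_max: float = 0.75
    n_bins: int = 8
    extra_blocks: Dict[str, Any] = field(default_factory=dict)


BIOMASS_RXN_ID = "r_biomass"


def document_to_dict(doc: ModelDocument) -> Dict[str, Any]:
    m = doc.model
    out: Dict[str, Any] = {
        "schema": SCHEMA,
        "id": m.id,
        "compartments": dict(m.compartments),
        "metabolites": [
            {
                "id": met.id, "name": met.name, "compartment": met.compartment,
                "formula": met.formula, "mw": met.mw, "dgf": met.dgf,
                "is_membrane_associated": met.is_membrane_associated,
            }
            for met in m.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id, "name": r.name, "metabolites": dict(r.stoich),
                "lower_bound": r.lower, "upper_bound": r.upper,
                "gene_reaction_rule": r.gpr, "dgr": r.dgr,
                "is_transport": r.is_transport,
            }
            for r in m.reactions.values()
        ]
        + [
            {
                "id": BIOMASS_RXN_ID, "name": "biomass pseudo-reaction",
                "metabolites": m.biomass.full_stoich(),
                "lower_bound": 0.0, "upper_bound": 1000.0,
                "gene_reaction_rule": "", "objective_coefficient": 1.0,
            }
        ],
        "genes": [
            {
                "id": g.id, "sequence": g.sequence, "length_nt": g.length_nt,
                "nucleotide_composition": g.nucleotide_composition,
                "locus_class": g.locus_class,
            }
            for g in m.genes.values()
        ],
        "biomass": {
            "reactants": dict(m.biomass.reactants),
            "byproducts": dict(m.biomass.byproducts),
            "gam_atp": m.biomass.gam_atp,
            "gam_metabolites": dict(m.biomass.gam_metabolites),
            "class_map": dict(m.biomass_class_map),
            "amino_acids": list(m.amino_acids),
        },
        "discretization": {"mu_max": doc.mu_max, "n_bins": doc.n_bins},
        "allocation": {
            "mode": doc.allocation_mode,
            "phi": doc.phi,
            "composition_table": (
                None
                if doc.table is None
                else {
                    "growth_rate_h": list(doc.table.growth_points),
                    **{k: list(v) for k, v in doc.table.fractions.items()},
                }
            ),
        },
    }
    if doc.network is not None:
        net = doc.network
        out["expression"] = {
            "transcripts": [
                {
                    "id": t.id, "gene": t.gene, "length_nt": t.length_nt,
                    "nt_counts": dict(t.nt_counts), "mw": t.mw,
                    "kdeg": t.kdeg, "kind": t.kind,
                }
                for t in net.transcripts.values()
            ],
            "peptides": [
                {
                    "id": p.id, "gene": p.gene, "length_aa": p.length_aa,
                    "aa_counts": dict(p.aa_counts), "mw": p.mw,
                    "kdeg": p.kdeg, "is_dummy": p.is_dummy,
                }
                for p in net.peptides.values()
            ],
            "enzymes": [
                {
                    "id": e.id, "composition": dict(e.composition),
                    "kcat_fwd": e.kcat_fwd, "kcat_bwd": e.kcat_bwd,
                    "reactions": list(e.reactions), "kdeg": e.kdeg,
                    "is_dummy": e.is_dummy,
                }
                for e in net.enzymes.values()
            ],
            "machinery": [
                {
                    "id": mach.id, "kind": mach.kind,
                    "composition": dict(mach.composition), "k_el": mach.k_el,
                    "genes": sorted(mach.genes), "kdeg": mach.kdeg,
                }
                for mach in net.machinery.values()
            ],
            "trnas": [
                {
                    "amino_acid": t.amino_acid, "length_nt": t.length_nt,
                    "nt_counts": dict(t.nt_counts), "mw": t.mw,
                }
                for t in net.trnas.values()
            ],
            "ntp_map": dict(net.ntp_map),
            "energy": dict(net.energy),
        }
    out.update(doc.extra_blocks)
    return out


def document_from_dict(data: Dict[str, Any]) -> ModelDocument:
    if data.get("schema") != SCHEMA:
        raise DocumentError(
            f"unsupported schema {data.get('schema')!r}; expected {SCHEMA!r}"
        )
    missing = {"id", "compartments", "metabolites", "reactions"} - set(data)
    if missing:
        raise DocumentError(f"missing document sections: {sorted(missing)}")

    mets = {
        d["id"]: Metabolite(
            d["id"], d["compartment"], name=d.get("name", ""),
            formula=d.get("formula"), mw=d.get("mw"), dgf=d.get("dgf"),
            is_membrane_associated=d.get("is_membrane_associated", False),
        )
        for d in data["metabolites"]
    }
    rxns = {}
    for d in data["reactions"]:
        if d["id"] == BIOMASS_RXN_ID:
            continue  # reconstructed from the structured biomass block
        rxns[d["id"]] = Reaction(
            d["id"], {k: float(v) for k, v in d["metabolites"].items()},
            d.get("lower_bound", 0.0), d.get("upper_bound", 1000.0),
            d.get("gene_reaction_rule", ""), name=d.get("name", ""),
            dgr=d.get("dgr"), is_transport=d.get("is_transport", False),
        )
    genes = {
        d["id"]: Gene(
            d["id"], sequence=d.get("sequence"), length_nt=d.get("length_nt"),
            nucleotide_composition=d.get("nucleotide_composition"),
            locus_class=d.get("locus_class", "nuclear"),
        )
        for d in data.get("genes", [])
    }
    bm = data.get("biomass", {})
    biomass = BiomassReaction(
        reactants={k: float(v) for k, v in bm.get("reactants", {}).items()},
        byproducts={k: float(v) for k, v in bm.get("byproducts", {}).items()},
        gam_atp=bm.get("gam_atp", 0.0),
        gam_metabolites=bm.get(
            "gam_metabolites", BiomassReaction().gam_metabolites
        ),
    )
    model = MetabolicModel(
        id=data["id"], compartments=data["compartments"], metabolites=mets,
        reactions=rxns, genes=genes, biomass=biomass,
        biomass_class_map=bm.get("class_map", {}),
        amino_acids=bm.get("amino_acids", []),
    )

    network = None
    if "expression" in data:
        ex = data["expression"]
        network = ExpressionNetwork(
            transcripts={
                d["id"]: Transcript(
                    d["id"], d["gene"], d["length_nt"], d["nt_counts"],
                    d["mw"], d.get("kdeg", 0.0), d.get("kind", "mrna"),
                )
                for d in ex.get("transcripts", [])
            },
            peptides={
                d["id"]: Peptide(
                    d["id"], d["gene"], d["length_aa"], d["aa_counts"],
                    d["mw"], d.get("kdeg", 0.0), d.get("is_dummy", False),
                )
                for d in ex.get("peptides", [])
            },
            enzymes={
                d["id"]: Enzyme(
                    d["id"], d["composition"], d.get("kcat_fwd"),
                    d.get("kcat_bwd"), d.get("reactions", []),
                    d.get("kdeg", 0.0), d.get("is_dummy", False),
                )
                for d in ex.get("enzymes", [])
            },
            machinery={
                d["id"]: Machinery(
                    d["id"], d["kind"], d["composition"], d["k_el"],
                    set(d.get("genes", [])), d.get("kdeg", 0.0),
                )
                for d in ex.get("machinery", [])
            },
            trnas={
                d["amino_acid"]: TRNAPair(
                    d["amino_acid"], d["length_nt"], d["nt_counts"], d["mw"]
                )
                for d in ex.get("trnas", [])
            },
        )
        if "ntp_map" in ex:
            network.ntp_map = dict(ex["ntp_map"])
        if "energy" in ex:
            network.energy = dict(ex["energy"])
    else:
        warnings.warn("document has no expression block; loading as FBA-only model")

    table = None
    alloc = data.get("allocation", {})
    tbl = alloc.get("composition_table")
    if tbl:
        table = CompositionTable(
            [float(x) for x in tbl["growth_rate_h"]],
            {
                k: [float(x) for x in v]
                for k, v in tbl.items()
                if k != "growth_rate_h"
            },
        )
    disc = data.get("discretization", {})
    extra = {k: v for k, v in data.items() if k not in KNOWN_BLOCKS}
    return ModelDocument(
        model=model, network=network, table=table,
        allocation_mode=alloc.get("mode", "cb"), phi=alloc.get("phi", 0.55),
        mu_max=disc.get("mu_max", 0.75), n_bins=disc.get("n_bins", 8),
        extra_blocks=extra,
    )


def write_model(doc: ModelDocument, path) -> None:
    with open(path, "w") as fh:
        json.dump(document_to_dict(doc), fh, sort_keys=True, indent=1)
        fh.write("\n")


def read_model(path) -> ModelDocument:
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise DocumentError(f"invalid JSON in {path}: {exc}") from exc
    return document_from_dict(data)


# ----------------------------------------------------------------------
# Side formats
# ----------------------------------------------------------------------

def write_fasta(genes: Dict[str, Gene], path) -> None:
    """Gene sequences as FASTA; headers carry gene ids verbatim."""
    records = [
        SeqRecord(Seq(g.sequence), id=g.id, description="")
        for g in genes.values()
        if g.sequence is not None
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Dict[str, str]:
    """Sequences by gene id; case-insensitive, U mapped to T."""
    return {
        rec.id: str(rec.seq).upper().replace("U", "T")
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_enzyme_tsv(network: ExpressionNetwork, path) -> None:
    rows = []
    for e in network.enzymes.values():
        rows.append({
            "enzyme_id": e.id,
            "composition": ";".join(
                f"{p}:{c:g}" for p, c in e.composition.items()
            ),
            "kcat_fwd_s": None if e.kcat_fwd is None else e.kcat_fwd / 3600.0,
            "kcat_bwd_s": None if e.kcat_bwd is None else e.kcat_bwd / 3600.0,
            "reactions": ";".join(e.reactions),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_enzyme_tsv(path) -> Dict[str, Enzyme]:
    df = pd.read_csv(path, sep="\t")
    out: Dict[str, Enzyme] = {}
    for _, row in df.iterrows():
        comp = {}
        for token in str(row["composition"]).split(";"):
            if token:
                pep, copies = token.split(":")
                comp[pep] = float(copies)
        kf = row.get("kcat_fwd_s")
        kb = row.get("kcat_bwd_s")
        out[row["enzyme_id"]] = Enzyme(
            row["enzyme_id"], comp,
            kcat_fwd=None if pd.isna(kf) else float(kf) * 3600.0,
            kcat_bwd=None if pd.isna(kb) else float(kb) * 3600.0,
            reactions=[r for r in str(row["reactions"]).split(";") if r],
        )
    return out


def write_dgf_tsv(model: MetabolicModel, path) -> None:
    rows = [
        {"metabolite_id": m.id, "dgf_kJ_mol": m.dgf}
        for m in model.metabolites.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_dgf_tsv(path) -> Dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    return {
        row["metabolite_id"]: float(row["dgf_kJ_mol"])
        for _, row in df.iterrows()
        if not pd.isna(row["dgf_kJ_mol"])
    }


def write_composition_csv(table: CompositionTable, path) -> None:
    table.to_dataframe().to_csv(path, index=False)


def read_composition_csv(path) -> CompositionTable:
    return CompositionTable.from_dataframe(pd.read_csv(path))


def write_labels_tsv(labels: Dict[str, bool], path) -> None:
    rows = [
        {"gene_id": g, "essentiality": "essential" if e else "nonessential"}
        for g, e in labels.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_labels_tsv(path) -> Dict[str, bool]:
    df = pd.read_csv(path, sep="\t")
    return {
        row["gene_id"]: str(row["essentiality"]).strip().lower() == "essential"
        for _, row in df.iterrows()
    }
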