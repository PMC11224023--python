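"""Synthetic knowledge-base snapshots and single-cell datasets with ground truth.

Two generator families make every pipeline stage testable without
downloading real snapshots or sequencing data:

* :func:`generate_fixture_kb` writes the seven snapshot dialects consumed
  by the ingestion and assembly modules (interaction TSV, protein role
  CSV, enzyme catalog, ion-channel list, SIF triples, statement JSONL,
  ortholog TSV) together with a manifest of every interaction expected to
  survive assembly, including deliberately planted filter violations
  (zero curation effort, wrong organism, kinase enzymes, one-sentence
  channel statements, unmapped orthologs).

* :func:`generate_expression` draws negative-binomial counts for
  ~15 immune cell types across 12 condition x timepoint groups
  (zymosan / incision / uv_burn at 4/24/48 h plus contralateral
  controls), with planted proportion kinetics (neutrophil and recruited-
  macrophage influx peaking at each injury's T_max), planted DE genes,
  planted sender->receiver communication signals and planted QC
  violations. :func:`generate_neuron_profiles` emits nine sensory-neuron
  subtypes with subtype-restricted receptor expression.

Everything is driven by a single integer-seeded generator; identical
seeds give byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .communication import CellTypeProfile
from .interactome import (
    EvidenceRecord,
    Interactome,
    InteractionRecord,
)

# ---------------------------------------------------------------------------
# Shared study-design constants
# ---------------------------------------------------------------------------

INJURY_CONDITIONS = ("zymosan", "incision", "uv_burn")
TIMEPOINTS = (4, 24, 48)
#: timepoint of peak hypersensitivity per injury model
T_MAX = {"zymosan": 4, "incision": 24, "uv_burn": 48}

NEURON_SUBTYPES = (
    "cLTMR1",
    "NF1",
    "NF2",
    "NF3",
    "NP",
    "p_cLTMR2",
    "PEP1",
    "PEP2",
    "SST",
)

IMMUNE_CELL_TYPES = {
    "Neutrophils": 0.04,
    "Ccr2+ recMacs": 0.05,
    "Ccr2- recMacs": 0.05,
    "Cx3cr1hi Macs": 0.10,
    "MHCII+ Macs": 0.10,
    "Cd163+ Macs": 0.08,
    "DCs": 0.09,
    "Langerhans": 0.06,
    "Tconv": 0.09,
    "Treg": 0.06,
    "gdT": 0.07,
    "ILC": 0.06,
    "B cells": 0.05,
    "NK": 0.06,
    "Mast": 0.04,
}


# ===========================================================================
# Fixture knowledge base
# ===========================================================================

ANCHOR_RECEPTORS = [
    "CD47",
    "IL6ST",
    "OSMR",
    "TNFRSF11A",
    "CD44",
    "KIT",
    "PTGER4",
    "MRGPRD",
    "IFNGR2",
    "S1PR1",
]
ANCHOR_LIGANDS = ["THBS1", "OSM", "TNFSF11", "HBEGF", "KITLG", "NGF"]
ANCHOR_ENZYMES = ["PTGS2", "ALDH3A2"]
ANCHOR_CHANNELS = ["TRPV1"]
PGE2 = "CHEBI:15551"  # prostaglandin E2
BALA = "CHEBI:16958"  # beta-alanine

#: anchor ligand-receptor pairs planted as surviving interactions
ANCHOR_LR_PAIRS = [
    ("THBS1", "CD47"),
    ("OSM", "IL6ST"),
    ("OSM", "OSMR"),
    ("TNFSF11", "TNFRSF11A"),
    ("HBEGF", "CD44"),
    ("KITLG", "KIT"),
]


@dataclass
class FixtureKBSpec:
    """Scale and seed of a fixture knowledge-base snapshot."""

    n_extra_receptors: int = 12
    n_extra_ligands: int = 8
    n_extra_enzymes: int = 6
    n_extra_channels: int = 4
    n_extra_lr: int = 10
    n_enzyme_statements: int = 8
    n_channel_statements: int = 4
    seed: int = 0


def _sentence_evidence(k: int) -> list:
    return [{"source_api": "reach", "text": f"Supporting sentence {i + 1}."} for i in range(k)]


def _db_evidence() -> list:
    return [{"source_api": "signor", "text": ""}]


def generate_fixture_kb(spec: FixtureKBSpec, out_dir) -> dict:
    """Write the seven snapshot files plus a ground-truth manifest.

    Returns the manifest (also written to ``manifest.json``): the four
    expected role sets, the expected surviving interactions per modality,
    and the expected mouse-mapped records with dropped human keys.
    """
    rng = np.random.default_rng(spec.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    extra_receptors = [f"RCPT{i + 1:02d}" for i in range(spec.n_extra_receptors)]
    extra_ligands = [f"LIGD{i + 1:02d}" for i in range(spec.n_extra_ligands)]
    extra_enzymes = [f"ENZY{i + 1:02d}" for i in range(spec.n_extra_enzymes)]
    extra_channels = [f"CHAN{i + 1:02d}" for i in range(spec.n_extra_channels)]
    extra_products = [f"CHEBI:9{i + 1:04d}" for i in range(spec.n_extra_enzymes)]
    kinases = ["KINA01", "KINA02"]
    phosphatases = ["PHOS01"]
    sinks = ["SINK01", "SINK02"]

    receptors = ANCHOR_RECEPTORS + extra_receptors + ["RCPTX"]  # RCPTX: no mouse ortholog
    ligand_pool = ANCHOR_LIGANDS + extra_ligands + ["LIGDX", "LIGDD"]
    enzymes = ANCHOR_ENZYMES + extra_enzymes
    channels = ANCHOR_CHANNELS + extra_channels

    all_symbols = sorted(
        set(receptors)
        | set(ligand_pool)
        | set(enzymes)
        | set(channels)
        | set(kinases)
        | set(phosphatases)
        | set(sinks)
        | {"UNDL01", "DLIG1", "DLIG2", "DLIG3", "DLIG4"}
    )
    acc = {sym: f"P{10000 + i}" for i, sym in enumerate(all_symbols)}

    # ----- ligand-receptor plan -------------------------------------------
    lr_pairs = list(ANCHOR_LR_PAIRS)
    for lig in extra_ligands:
        lr_pairs.append((lig, extra_receptors[int(rng.integers(len(extra_receptors)))]))
    for _ in range(spec.n_extra_lr):
        lr_pairs.append(
            (
                extra_ligands[int(rng.integers(len(extra_ligands)))],
                extra_receptors[int(rng.integers(len(extra_receptors)))],
            )
        )
    lr_pairs.append(("LIGDX", "RCPTX"))  # dropped later: receptor has no ortholog
    lr_pairs.append(("LIGDD", "RCPT01"))  # ligand with two mouse orthologs
    lr_pairs = sorted(set(lr_pairs))

    resources_ok = ["CellPhoneDB", "Guide2Pharma", "CellChatDB", "ICELLNET"]

    def omnirow(src, tgt, directed=1, curation=None, resources=None, subset="ligrecextra", tax="9606"):
        cur = int(rng.integers(1, 9)) if curation is None else curation
        res = resources or [resources_ok[int(rng.integers(len(resources_ok)))]]
        return [acc[src], acc[tgt], src, tgt, directed, cur, ";".join(res), subset, tax]

    omni_rows = []
    for src, tgt in lr_pairs:
        omni_rows.append(omnirow(src, tgt))
    # duplicate of an anchor pair: dedup must collapse it
    omni_rows.append(omnirow("THBS1", "CD47", curation=2, resources=["Guide2Pharma"]))
    # ligand-only rows: retained, source becomes a ligand, target is no receptor
    omni_rows.append(omnirow("NGF", "SINK01"))
    omni_rows.append(omnirow("OSM", "SINK02"))
    # undirected row: retained but contributes neither ligand nor record
    omni_rows.append(omnirow("UNDL01", "RCPT02", directed=0))
    # decoys, each violating exactly one filter
    omni_rows.append(omnirow("DLIG1", "RCPT01", curation=0))
    omni_rows.append(omnirow("DLIG2", "RCPT02", tax="10090"))
    omni_rows.append(omnirow("DLIG3", "RCPT03", subset="misc"))
    omni_rows.append(omnirow("DLIG4", "RCPT01", resources=["UnlistedDB"]))

    header = [
        "source",
        "target",
        "source_genesymbol",
        "target_genesymbol",
        "is_directed",
        "curation_effort",
        "sources",
        "subset",
        "ncbi_tax_id",
    ]
    with open(out / "omnipath.tsv", "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in omni_rows:
            fh.write("\t".join(str(v) for v in row) + "\n")

    expected_ligands = sorted(set(s for s, _ in lr_pairs) | {"NGF"})

    # ----- protein role table ---------------------------------------------
    with open(out / "cpdb_proteins.csv", "w") as fh:
        fh.write("uniprot,gene_name,receptor\n")
        for sym in all_symbols:
            flag = 1 if sym in receptors else 0
            fh.write(f"{acc[sym]},{sym},{flag}\n")

    # ----- enzyme catalog ---------------------------------------------------
    with open(out / "enzymes.tsv", "w") as fh:
        fh.write("uniprot\tgene_name\tec_classes\tis_kinase\tis_phosphatase\n")
        for i, sym in enumerate(enzymes):
            fh.write(f"{acc[sym]}\t{sym}\t1.14.99.{i + 1}\t0\t0\n")
        for sym in kinases:
            fh.write(f"{acc[sym]}\t{sym}\t2.7.11.1\t1\t0\n")
        for sym in phosphatases:
            fh.write(f"{acc[sym]}\t{sym}\t3.1.3.16\t0\t1\n")

    # ----- ion-channel list (with role overlaps that must be removed) -------
    with open(out / "ion_channels.txt", "w") as fh:
        for sym in channels + ["CD47", "THBS1"]:
            fh.write(sym + "\n")

    # ----- SIF enzyme -> product -------------------------------------------
    product_enzymes: dict = {PGE2: ["PTGS2"], BALA: ["ALDH3A2"]}
    sif_rows = [("PTGS2", "controls-production-of", PGE2), ("ALDH3A2", "controls-production-of", BALA)]
    for enz, prod in zip(extra_enzymes, extra_products):
        sif_rows.append((enz, "controls-production-of", prod))
        product_enzymes.setdefault(prod, []).append(enz)
    if len(extra_enzymes) >= 2:
        # one product made by two enzymes: statements expand to both
        sif_rows.append((extra_enzymes[1], "controls-production-of", extra_products[0]))
        product_enzymes[extra_products[0]].append(extra_enzymes[1])
    sif_rows.append(("PTGS2", "controls-transport-of", "CHEBI:99990"))  # unknown relation
    sif_rows.append(("KINA01", "controls-production-of", "CHEBI:99991"))  # not an enzyme
    sif_rows.append(("THBS1", "controls-production-of", "CHEBI:99992"))  # not an enzyme
    with open(out / "pc_sif.tsv", "w") as fh:
        for row in sif_rows:
            fh.write("\t".join(row) + "\n")

    # ----- statements --------------------------------------------------------
    statements = []
    enzyme_surviving = set()
    ion_surviving = set()

    def add_product_receptor(product, receptor, stmt_type, evidence):
        statements.append({"type": stmt_type, "subj": product, "obj": receptor, "evidence": evidence})
        for enz in product_enzymes[product]:
            enzyme_surviving.add((enz, receptor, product))

    add_product_receptor(PGE2, "PTGER4", "Activation", _db_evidence())
    add_product_receptor(BALA, "MRGPRD", "Activation", _sentence_evidence(2))
    for i in range(spec.n_enzyme_statements):
        prod = extra_products[int(rng.integers(len(extra_products)))]
        rec = extra_receptors[int(rng.integers(len(extra_receptors)))]
        stype = "Complex" if rng.random() < 0.4 else "Activation"
        evid = _db_evidence() if rng.random() < 0.5 else _sentence_evidence(int(rng.integers(1, 4)))
        if stype == "Complex" and rng.random() < 0.5:
            # reversed Complex: still oriented by role
            statements.append({"type": stype, "subj": rec, "obj": prod, "evidence": evid})
            for enz in product_enzymes[prod]:
                enzyme_surviving.add((enz, rec, prod))
        else:
            add_product_receptor(prod, rec, stype, evid)

    # channel statements: evidence filter applies
    statements.append({"type": "Complex", "subj": "NGF", "obj": "TRPV1", "evidence": _db_evidence()})
    ion_surviving.add(("NGF", "TRPV1", ""))
    statements.append(
        {"type": "Activation", "subj": PGE2, "obj": "TRPV1", "evidence": _sentence_evidence(2)}
    )
    for enz in product_enzymes[PGE2]:
        ion_surviving.add((enz, "TRPV1", PGE2))
    # boundary plants: 1 text-mined sentence always fails, 2 always pass
    lig_a = extra_ligands[0]
    lig_b = extra_ligands[1 % len(extra_ligands)]
    statements.append(
        {"type": "Activation", "subj": lig_a, "obj": channels[1], "evidence": _sentence_evidence(1)}
    )
    statements.append(
        {"type": "Activation", "subj": lig_b, "obj": channels[1], "evidence": _sentence_evidence(2)}
    )
    ion_surviving.add((lig_b, channels[1], ""))
    for i in range(spec.n_channel_statements):
        lig = extra_ligands[int(rng.integers(len(extra_ligands)))]
        chan = extra_channels[int(rng.integers(len(extra_channels)))]
        n_sent = int(rng.integers(1, 4))
        use_db = rng.random() < 0.4
        evid = _db_evidence() if use_db else _sentence_evidence(n_sent)
        statements.append({"type": "Activation", "subj": lig, "obj": chan, "evidence": evid})
        if use_db or n_sent >= 2:
            ion_surviving.add((lig, chan, ""))
    # decoys
    statements.append(
        {"type": "Activation", "subj": "PTGER4", "obj": PGE2, "evidence": _db_evidence()}
    )  # reversed Activation: no record
    statements.append(
        {"type": "Activation", "subj": "CHEBI:99999", "obj": "RCPT01", "evidence": _db_evidence()}
    )  # product without enzyme link
    statements.append(
        {"type": "Phosphorylation", "subj": "KINA01", "obj": "RCPT01", "evidence": _db_evidence()}
    )  # wrong statement type

    with open(out / "statements.jsonl", "w") as fh:
        for stmt in statements:
            fh.write(json.dumps(stmt, sort_keys=True) + "\n")

    # ----- orthologs ---------------------------------------------------------
    mappable = sorted(
        (set(receptors) | set(ligand_pool) | set(enzymes) | set(channels)) - {"RCPTX"}
    )
    with open(out / "orthologs.tsv", "w") as fh:
        fh.write("human_symbol\tmouse_symbol\n")
        for sym in mappable:
            if sym == "LIGDD":
                fh.write("LIGDD\tLigdda\nLIGDD\tLigddb\n")
            else:
                fh.write(f"{sym}\t{sym.capitalize()}\n")

    # ----- manifest ----------------------------------------------------------
    lr_surviving = sorted(set(lr_pairs))
    expected_channels = sorted(channels)

    def mouse_of(sym):
        if sym == "LIGDD":
            return ["Ligdda", "Ligddb"]
        if sym == "RCPTX":
            return []
        return [sym.capitalize()]

    mouse_records = set()
    dropped = []
    human_keyed = (
        [(s, r, "ligand_receptor") for s, r in lr_surviving]
        + [(e, r, "enzyme_receptor") for e, r, _ in sorted(enzyme_surviving)]
        + [(s, c, "ion_channel") for s, c, _ in sorted(ion_surviving)]
    )
    for s, r, modality in sorted(set(human_keyed)):
        ms_list, mr_list = mouse_of(s), mouse_of(r)
        if not ms_list or not mr_list:
            dropped.append([s, r, modality])
            continue
        for ms in ms_list:
            for mr in mr_list:
                mouse_records.add((ms, mr, modality))

    manifest = {
        "roles": {
            "receptors": sorted(receptors),
            "ligands": expected_ligands,
            "enzymes": sorted(enzymes),
            "ion_channels": expected_channels,
        },
        "surviving": {
            "ligand_receptor": [list(p) for p in lr_surviving],
            "enzyme_receptor": [list(t) for t in sorted(enzyme_surviving)],
            "ion_channel": [list(t) for t in sorted(ion_surviving)],
        },
        "mouse": {
            "records": [list(t) for t in sorted(mouse_records)],
            "dropped_human": sorted(dropped),
        },
        "seed": spec.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest


# ===========================================================================
# Synthetic expression data
# ===========================================================================

#: baseline negative-binomial mean (counts per cell) for named genes
NAMED_GENE_MEANS = {
    "Thbs1": 0.10,
    "Osm": 0.10,
    "Tnfsf11": 0.10,
    "Hbegf": 0.10,
    "Kitlg": 0.08,
    "Ngf": 0.05,
    "Ptgs2": 0.10,
    "Aldh3a2": 0.08,
    "Il1b": 0.50,
    "Arg1": 0.40,
    "Fn1": 0.50,
    "Hif1a": 0.80,
    "C1qa": 1.00,
    "Klf6": 0.80,
    "Atf3": 0.60,
    "Jun": 1.00,
    "Fos": 1.00,
}

MACROPHAGE_TYPES = ["Cx3cr1hi Macs", "MHCII+ Macs", "Ccr2+ recMacs", "Ccr2- recMacs"]


@dataclass(frozen=True)
class DEPlan:
    gene: str
    cell_type: str
    condition: str
    timepoint_h: int
    log2_effect: float  # positive = up in injury vs contralateral


@dataclass(frozen=True)
class CommPlan:
    ligand_gene: str
    receptor_gene: str
    sender_type: str
    receiver_subtype: str
    condition: str
    fold: float = 8.0


def default_de_plan() -> list:
    plan = []
    for cond in INJURY_CONDITIONS:
        tmax = T_MAX[cond]
        for ct in MACROPHAGE_TYPES:
            plan.append(DEPlan("Thbs1", ct, cond, tmax, 1.5))
            plan.append(DEPlan("Hif1a", ct, cond, tmax, 1.0))
        plan.append(DEPlan("Ptgs2", "Cx3cr1hi Macs", cond, tmax, 1.2))
        plan.append(DEPlan("C1qa", "Cx3cr1hi Macs", cond, tmax, -1.2))
        plan.append(DEPlan("Fos", "Cx3cr1hi Macs", cond, tmax, -1.0))
    plan.append(DEPlan("Il1b", "Cx3cr1hi Macs", "zymosan", 4, 1.5))
    plan.append(DEPlan("Arg1", "Cx3cr1hi Macs", "incision", 24, 1.3))
    return plan


def default_comm_plan() -> list:
    return [
        CommPlan("Kitlg", "Kit", "Ccr2+ recMacs", "PEP1", "zymosan"),
        CommPlan("Osm", "Osmr", "Cx3cr1hi Macs", "SST", "incision"),
        CommPlan("Tnfsf11", "Tnfrsf11a", "Tconv", "cLTMR1", "uv_burn"),
    ]


@dataclass
class SyntheticSCSpec:
    """Design of a synthetic immune + neuron dataset."""

    cell_types: dict = field(default_factory=lambda: dict(IMMUNE_CELL_TYPES))
    n_genes: int = 800
    n_cells_per_sample: int = 600
    n_replicates: int = 2
    dispersion: float = 2.0
    #: influx multipliers applied to proportions, peaking at T_max
    influx_peak: dict = field(
        default_factory=lambda: {"Neutrophils": 6.0, "Ccr2+ recMacs": 4.0, "Ccr2- recMacs": 4.0}
    )
    influx_offpeak: float = 1.5
    de_plan: list = field(default_factory=default_de_plan)
    comm_plan: list = field(default_factory=default_comm_plan)
    doublet_rate: float = 0.02
    high_mito_rate: float = 0.01
    size_outlier_rate: float = 0.005
    marker_boost: float = 6.0
    seed: int = 0


def _gene_names(spec: SyntheticSCSpec) -> list:
    named = list(NAMED_GENE_MEANS)
    fillers = [f"Gene{i + 1:04d}" for i in range(spec.n_genes - len(named))]
    return named + fillers


def _group_proportions(spec: SyntheticSCSpec, condition: str, timepoint_h: int) -> np.ndarray:
    types = list(spec.cell_types)
    props = np.array([spec.cell_types[t] for t in types], dtype=float)
    if condition in INJURY_CONDITIONS:
        for t, peak in spec.influx_peak.items():
            factor = peak if T_MAX[condition] == timepoint_h else spec.influx_offpeak
            props[types.index(t)] *= factor
    return props / props.sum()


def generate_expression(spec: SyntheticSCSpec) -> tuple:
    """Draw the full 12-group immune dataset; returns ``(adata, truth)``.

    ``adata.X`` holds raw counts; obs carries sample/condition/timepoint/
    cell-type annotations, the doublet flag, the mitochondrial fraction
    and a ``qc_truth`` column naming the planted QC violation (or
    ``none``). ``truth`` records the proportion design, the DE plan and
    the communication plan.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec)
    n_genes = len(genes)
    types = list(spec.cell_types)
    if any(v <= 0 for v in spec.cell_types.values()):
        raise ValueError("all declared cell types need positive baseline proportions")

    baseline = rng.lognormal(mean=-1.0, sigma=1.0, size=n_genes).clip(0.05, 8.0)
    for i, g in enumerate(genes):
        if g in NAMED_GENE_MEANS:
            baseline[i] = NAMED_GENE_MEANS[g]

    # cell-type marker structure on filler genes only
    marker = np.ones((len(types), n_genes))
    n_named = len(NAMED_GENE_MEANS)
    for ti in range(len(types)):
        lo = n_named + ti * 10
        hi = min(lo + 10, n_genes)
        marker[ti, lo:hi] = spec.marker_boost

    gene_idx = {g: i for i, g in enumerate(genes)}
    type_idx = {t: i for i, t in enumerate(types)}

    de_mult: dict = {}
    for p in spec.de_plan:
        if p.gene in gene_idx and p.cell_type in type_idx:
            key = (p.condition, p.timepoint_h, p.cell_type)
            de_mult.setdefault(key, {})[gene_idx[p.gene]] = 2.0 ** p.log2_effect
    for p in spec.comm_plan:
        if p.ligand_gene in gene_idx and p.sender_type in type_idx:
            key = (p.condition, T_MAX[p.condition], p.sender_type)
            cur = de_mult.setdefault(key, {})
            cur[gene_idx[p.ligand_gene]] = cur.get(gene_idx[p.ligand_gene], 1.0) * p.fold

    groups = [(c, t) for c in INJURY_CONDITIONS for t in TIMEPOINTS]
    groups += [("contralateral", t) for t in TIMEPOINTS]

    blocks = []
    obs_rows = []
    proportions_design = {}
    for condition, tp in groups:
        props = _group_proportions(spec, condition, tp)
        proportions_design[f"{condition}_{tp}"] = dict(zip(types, props.round(6)))
        for rep in range(1, spec.n_replicates + 1):
            sample_id = f"{condition}_{tp}h_r{rep}"
            counts_per_type = rng.multinomial(spec.n_cells_per_sample, props)
            labels = np.repeat(np.arange(len(types)), counts_per_type)
            n_cells = labels.size

            mean = baseline[None, :] * marker[labels]
            for (pc, pt, pct), shifts in de_mult.items():
                if pc == condition and pt == tp:
                    mask = labels == type_idx[pct]
                    if mask.any():
                        for gi, factor in shifts.items():
                            mean[mask, gi] *= factor

            scale = rng.lognormal(mean=0.0, sigma=0.1, size=n_cells)
            qc_truth = np.array(["none"] * n_cells, dtype=object)
            doublet = rng.random(n_cells) < spec.doublet_rate
            qc_truth[doublet] = "doublet"
            scale[doublet] *= 2.0

            singlet_pool = np.where(~doublet)[0]
            n_out = max(1, int(round(spec.size_outlier_rate * n_cells)))
            picked = rng.choice(singlet_pool, size=3 * n_out, replace=False)
            low, high, mito_cells = (
                picked[:n_out],
                picked[n_out : 2 * n_out],
                picked[2 * n_out :],
            )
            scale[low] *= 0.03
            scale[high] *= 30.0
            qc_truth[low] = "size_low"
            qc_truth[high] = "size_high"

            mito = rng.uniform(0.0, 0.04, size=n_cells)
            mito[mito_cells] = rng.uniform(0.06, 0.20, size=mito_cells.size)
            qc_truth[mito_cells] = "mito"

            mu = mean * scale[:, None]
            theta = spec.dispersion
            counts = rng.negative_binomial(theta, theta / (theta + mu))
            blocks.append(sp.csr_matrix(counts))
            for i in range(n_cells):
                obs_rows.append(
                    {
                        "barcode": f"{sample_id}_c{i:04d}",
                        "sample_id": sample_id,
                        "condition": condition,
                        "timepoint_h": tp,
                        "cell_type": types[labels[i]],
                        "doublet_flag": bool(doublet[i]),
                        "mito_fraction": float(mito[i]),
                        "qc_truth": qc_truth[i],
                    }
                )

    X = sp.vstack(blocks).tocsr()
    obs = pd.DataFrame(obs_rows).set_index("barcode")
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    from dataclasses import asdict

    truth = {
        "proportions_design": proportions_design,
        "de_plan": [asdict(p) for p in spec.de_plan],
        "comm_plan": [asdict(p) for p in spec.comm_plan],
        "t_max": dict(T_MAX),
    }
    return adata, truth


#: receptor -> (subtypes, CP10K level) restriction plan for neuron profiles
DEFAULT_NEURON_PLAN = {
    "Cd47": (["PEP1"], 8.0),
    "Osmr": (["SST"], 8.0),
    "Tnfrsf11a": (["cLTMR1"], 8.0),
    "Il6st": (["NP", "PEP1", "PEP2"], 3.0),
    "Ptger4": (["PEP2"], 3.0),
    "Mrgprd": (["NP"], 5.0),
    "Trpv1": (["PEP1"], 4.0),
    "Cd44": (list(NEURON_SUBTYPES), 1.5),
    "Kit": (["PEP1"], 8.0),
    "Ifngr2": (["cLTMR1"], 4.0),
    "S1pr1": (["SST"], 4.0),
}


def generate_neuron_profiles(
    plan: Optional[dict] = None,
    n_cells_per_subtype: int = 120,
    rare_subtype: str = "p_cLTMR2",
    rare_n_cells: int = 8,
    seed: int = 0,
) -> CellTypeProfile:
    """Summarized receptor expression for the nine sensory-neuron subtypes.

    Each receptor is expressed only in the subtypes its plan names
    (subtype-restricted repertoires); an empty plan gives a uniform
    profile. One subtype is kept rare to exercise the minimum-cell
    exclusion downstream.
    """
    if plan is None:
        plan = DEFAULT_NEURON_PLAN
    rng = np.random.default_rng(seed)
    genes = sorted(plan) if plan else ["Gene0001"]
    expr = pd.DataFrame(
        0.0,
        index=pd.Index(list(NEURON_SUBTYPES), name="cell_type"),
        columns=pd.Index(genes, name="gene"),
    )
    for gene in genes:
        subtypes, level = plan.get(gene, (list(NEURON_SUBTYPES), 1.0))
        for st in subtypes:
            expr.loc[st, gene] = level * float(rng.uniform(0.9, 1.1))
    n_cells = pd.Series(n_cells_per_subtype, index=expr.index, dtype=int, name="n_cells")
    if rare_subtype in n_cells.index:
        n_cells[rare_subtype] = rare_n_cells
    return CellTypeProfile(expr=expr, frac=(expr > 0).astype(float), n_cells=n_cells)


# ===========================================================================
# Focused benchmark generators
# ===========================================================================

def comm_benchmark_spec(seed: int = 0) -> SyntheticSCSpec:
    """Communication-recovery benchmark configuration.

    The planted communication plan (one 8x-enriched sender->receiver
    pair per condition, applied at that condition's T_max) is the only
    expression enrichment; the DE plan is empty so ligand abundance is
    flat everywhere else and recovered pairs are attributable solely to
    the planted communication signal.
    """
    return SyntheticSCSpec(de_plan=[], seed=seed)


def generate_de_benchmark(
    seed: int = 0,
    n_cells_per_group: int = 200,
    n_genes: int = 500,
    n_planted: int = 24,
    effect_range: tuple = (1.0, 1.6),
    dispersion: float = 2.0,
) -> tuple:
    """Two-group dataset with planted fold changes for DE power checks.

    Returns ``(adata, truth)``; truth maps each planted gene to its signed
    log2 effect. The planted fraction is kept small and the effect signs
    alternate up/down so per-cell normalization does not impart a
    compositional fold change onto the unplanted genes - those must stay
    genuinely null. With ``n_planted=0`` this is a null dataset for
    false-positive calibration.
    """
    rng = np.random.default_rng(seed)
    genes = [f"Gene{i + 1:04d}" for i in range(n_genes)]
    baseline = rng.lognormal(mean=0.0, sigma=0.7, size=n_genes).clip(0.3, 6.0)
    planted_idx = rng.choice(n_genes, size=n_planted, replace=False) if n_planted else np.array([], dtype=int)
    signs = np.where(np.arange(n_planted) % 2 == 0, 1.0, -1.0)
    effects = rng.uniform(*effect_range, size=n_planted) * signs

    mean_case = baseline.copy()
    mean_case[planted_idx] *= 2.0 ** effects
    n = n_cells_per_group
    theta = dispersion
    counts = np.vstack(
        [
            rng.negative_binomial(theta, theta / (theta + np.tile(mean_case, (n, 1)))),
            rng.negative_binomial(theta, theta / (theta + np.tile(baseline, (n, 1)))),
        ]
    )
    obs = pd.DataFrame(
        {
            "group": ["case"] * n + ["control"] * n,
            "sample_id": ["s1"] * (2 * n),
            "condition": ["zymosan"] * n + ["contralateral"] * n,
            "timepoint_h": [4] * (2 * n),
            "cell_type": ["Macs"] * (2 * n),
            "doublet_flag": [False] * (2 * n),
            "mito_fraction": [0.01] * (2 * n),
        },
        index=pd.Index([f"c{i:05d}" for i in range(2 * n)], name="barcode"),
    )
    adata = ad.AnnData(
        X=sp.csr_matrix(counts), obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene"))
    )
    truth = {genes[i]: float(e) for i, e in zip(planted_idx, effects)}
    return adata, truth


def toy_interactome(pairs: Iterable[tuple], modality: str = "ligand_receptor") -> Interactome:
    """Build a minimal interactome from (sender_gene, receiver_gene) pairs."""
    evid = (
        EvidenceRecord(
            kind="structured_database",
            statement_type="other",
            sentence_count=0,
            source_label="synthetic",
        ),
    )
    records = {}
    for s, r in pairs:
        rec = InteractionRecord(
            modality=modality, sender_gene=s, receiver_gene=r, evidence=evid
        )
        records[rec.key] = rec
    return Interactome(records=records, species="mouse")


def generate_null_communication(
    seed: int = 0,
    n_pairs: int = 100,
    n_types: int = 5,
    n_cells_per_type: int = 30,
    mean: float = 2.0,
    dispersion: float = 2.0,
) -> tuple:
    """Label-randomized dataset for permutation-null calibration.

    Sender genes are expressed identically in every cell (no cell-type
    structure), so every (record, sender, receiver) triple is a true
    null. Returns ``(adata, receiver_profile, interactome)`` with one
    record per sender/receiver gene pair.
    """
    rng = np.random.default_rng(seed)
    send_genes = [f"Lig{i + 1:04d}" for i in range(n_pairs)]
    recv_genes = [f"Rec{i + 1:04d}" for i in range(n_pairs)]
    n_cells = n_types * n_cells_per_type
    counts = rng.negative_binomial(
        dispersion, dispersion / (dispersion + mean), size=(n_cells, n_pairs)
    )
    labels = rng.permutation(np.repeat([f"T{i:02d}" for i in range(n_types)], n_cells_per_type))
    obs = pd.DataFrame(
        {"cell_type": labels},
        index=pd.Index([f"c{i:05d}" for i in range(n_cells)], name="barcode"),
    )
    adata = ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(send_genes, name="gene")),
    )
    receiver = CellTypeProfile(
        expr=pd.DataFrame(
            3.0,
            index=pd.Index(["N1"], name="cell_type"),
            columns=pd.Index(recv_genes, name="gene"),
        ),
        frac=pd.DataFrame(
            1.0,
            index=pd.Index(["N1"], name="cell_type"),
            columns=pd.Index(recv_genes, name="gene"),
        ),
        n_cells=pd.Series([100], index=pd.Index(["N1"], name="cell_type"), name="n_cells"),
    )
    itx = toy_interactome(zip(send_genes, recv_genes))
    return adata, receiver, itx
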