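"""Independent brute-force oracles used to check the pipeline.

Everything here is deliberately written as naive loops over the raw
snapshot files, sharing no code with the package, so agreement with the
package's output is a genuine two-route check.
"""

from __future__ import annotations

import csv
import json
from itertools import combinations
from pathlib import Path

from scipy.stats import rankdata

ALLOWED = {
    "CellPhoneDB",
    "Guide2Pharma",
    "HPMR",
    "ICELLNET",
    "Kirouac2010",
    "CellTalkDB",
    "CellChatDB",
    "connectomeDB2020",
    "Ramilowski2015",
    "talklr",
}
STRUCTURED = {"signor", "biogrid", "hprd", "reactome", "intact", "pathway_commons", "drugbank"}


def brute_force_assembly(kb_dir):
    """Enumerate role sets and surviving interactions straight off the files.

    Returns a dict with ``roles`` (four symbol sets) and per-modality
    record key sets: ligand_receptor as (sender, receiver), the other two
    as (sender, receiver, intermediate-or-empty).
    """
    kb_dir = Path(kb_dir)

    # --- interaction table -------------------------------------------------
    retained = []
    with open(kb_dir / "omnipath.tsv") as fh:
        for rec in csv.DictReader(fh, delimiter="\t"):
            if int(rec["curation_effort"]) <= 0:
                continue
            if rec["ncbi_tax_id"] != "9606":
                continue
            if "ligrecextra" not in rec["subset"].split(";"):
                continue
            if not set(rec["sources"].split(";")) & ALLOWED:
                continue
            retained.append(rec)
    directed_pairs = set()
    ligand_sources = set()
    for rec in retained:
        if rec["is_directed"] in {"1", "True", "true"}:
            directed_pairs.add((rec["source_genesymbol"], rec["target_genesymbol"]))
            ligand_sources.add(rec["source_genesymbol"])

    # --- role sets ---------------------------------------------------------
    receptors = set()
    with open(kb_dir / "cpdb_proteins.csv") as fh:
        for rec in csv.DictReader(fh):
            if rec["receptor"] == "1":
                receptors.add(rec["gene_name"])
    ligands = ligand_sources - receptors
    enzymes = set()
    with open(kb_dir / "enzymes.tsv") as fh:
        for rec in csv.DictReader(fh, delimiter="\t"):
            if rec["ec_classes"] and rec["is_kinase"] == "0" and rec["is_phosphatase"] == "0":
                enzymes.add(rec["gene_name"])
    channels = set()
    for line in (kb_dir / "ion_channels.txt").read_text().splitlines():
        if line.strip():
            channels.add(line.strip())
    channels -= receptors | ligands

    # --- modalities ----------------------------------------------------------
    lr = {(s, t) for s, t in directed_pairs if s in ligands and t in receptors}

    products = {}
    with open(kb_dir / "pc_sif.tsv") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                continue
            controller, relation, product = parts
            if relation == "controls-production-of" and controller in enzymes:
                products.setdefault(product, set()).add(controller)

    enz_rec = set()
    ion = set()
    with open(kb_dir / "statements.jsonl") as fh:
        for line in fh:
            stmt = json.loads(line)
            if stmt["type"] not in {"Complex", "Activation"}:
                continue
            subj, obj = stmt["subj"], stmt["obj"]
            n_sent = sum(
                1
                for ev in stmt["evidence"]
                if ev.get("source_api") not in STRUCTURED and ev.get("text")
            )
            has_db = any(ev.get("source_api") in STRUCTURED for ev in stmt["evidence"])
            evidence_ok = has_db or n_sent >= 2

            oriented = [(subj, obj)]
            if stmt["type"] == "Complex":
                oriented.append((obj, subj))

            for a, b in oriented:
                if a in products and b in receptors:
                    for enz in products[a]:
                        enz_rec.add((enz, b, a))
                if evidence_ok:
                    if a in ligands and b in channels:
                        ion.add((a, b, ""))
                    if a in products and b in channels:
                        for enz in products[a]:
                            ion.add((enz, b, a))

    return {
        "roles": {
            "receptors": receptors,
            "ligands": ligands,
            "enzymes": enzymes,
            "ion_channels": channels,
        },
        "ligand_receptor": lr,
        "enzyme_receptor": enz_rec,
        "ion_channel": ion,
    }


def brute_force_mouse_keys(kb_dir, human_keys):
    """Expand (sender, receiver, modality) keys over the ortholog table."""
    mapping = {}
    with open(Path(kb_dir) / "orthologs.tsv") as fh:
        for rec in csv.DictReader(fh, delimiter="\t"):
            mapping.setdefault(rec["human_symbol"], set()).add(rec["mouse_symbol"])
    mouse = set()
    dropped = set()
    for s, r, modality in human_keys:
        if s not in mapping or r not in mapping:
            dropped.add((s, r, modality))
            continue
        for ms in mapping[s]:
            for mr in mapping[r]:
                mouse.add((ms, mr, modality))
    return mouse, dropped


def exact_wilcoxon_p(x1, x2):
    """Exhaustive-permutation two-sided rank-sum p-value (pure loops)."""
    pooled = list(x1) + list(x2)
    n1 = len(x1)
    n = len(pooled)
    ranks = rankdata(pooled)
    w_obs = sum(ranks[:n1])
    mu = n1 * (n + 1) / 2.0
    hits = 0
    total = 0
    for idx in combinations(range(n), n1):
        s = sum(ranks[i] for i in idx)
        total += 1
        if abs(s - mu) >= abs(w_obs - mu) - 1e-9:
            hits += 1
    return hits / total
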