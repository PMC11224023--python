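"""Knowledge-base ingestion and gene role-set derivation.

Parses snapshot files of the aggregated interaction resources (an
OmniPath-style ligand-receptor interaction table, a CellPhoneDB-style
protein role table, an ExPASy-style enzyme catalog and a curated
ion-channel list) and derives the four gene role sets used to assemble
the neuroimmune interactome:

* receptors  -- proteins flagged as receptors in the role table;
* ligands    -- source participants of directed ligand-receptor
                interactions, excluding known receptors;
* enzymes    -- catalog members with at least one EC class, excluding
                kinases and phosphatases (intracellular signaling
                intermediaries, not intercellular messengers);
* ion channels -- the curated channel list minus any overlap with
                receptors or ligands.

All assembly happens on human gene symbols; UniProt accessions are
carried alongside for export and never guessed.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

#: Source-database labels admitted by default when filtering the
#: interaction table; matching is exact and case-sensitive.
DEFAULT_ALLOWED_RESOURCES = frozenset(
    {
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
)

#: Subset label marking the ligand-receptor-focused interactions.
LIGREC_SUBSET_TAG = "ligrecextra"

#: NCBI taxon identifiers accepted as human.
HUMAN_TAX_IDS = frozenset({"9606"})


@dataclass(frozen=True)
class RawInteractionRow:
    """One interaction-table row after parsing (pre- or post-filter)."""

    source_id: str
    target_id: str
    source_symbol: str
    target_symbol: str
    is_directed: bool
    curation_effort: int
    resources: frozenset
    subsets: frozenset
    organism: str

    def __post_init__(self):
        if not self.source_id or not self.target_id:
            raise ValueError("interaction row with empty identifier")
        if self.curation_effort < 0:
            raise ValueError("negative curation_effort")


@dataclass(frozen=True)
class ProteinRoleRow:
    uniprot_id: str
    symbol: str
    is_receptor: bool


@dataclass(frozen=True)
class EnzymeCatalogRow:
    uniprot_id: str
    symbol: str
    ec_classes: frozenset
    is_kinase: bool
    is_phosphatase: bool


@dataclass
class GeneRoleSets:
    """The four role sets with per-gene provenance and accession map."""

    receptors: frozenset
    ligands: frozenset
    enzymes: frozenset
    ion_channels: frozenset
    provenance: dict = field(default_factory=dict)
    symbol_to_uniprot: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.ligands & self.receptors:
            raise ValueError(
                f"ligand/receptor overlap: {sorted(self.ligands & self.receptors)}"
            )
        bad = self.ion_channels & (self.receptors | self.ligands)
        if bad:
            raise ValueError(f"ion channels overlapping receptors/ligands: {sorted(bad)}")

    def to_json(self, path) -> None:
        payload = {
            "receptors": sorted(self.receptors),
            "ligands": sorted(self.ligands),
            "enzymes": sorted(self.enzymes),
            "ion_channels": sorted(self.ion_channels),
            "provenance": {k: self.provenance[k] for k in sorted(self.provenance)},
            "symbol_to_uniprot": {
                k: self.symbol_to_uniprot[k] for k in sorted(self.symbol_to_uniprot)
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path) -> "GeneRoleSets":
        payload = json.loads(Path(path).read_text())
        return cls(
            receptors=frozenset(payload["receptors"]),
            ligands=frozenset(payload["ligands"]),
            enzymes=frozenset(payload["enzymes"]),
            ion_channels=frozenset(payload["ion_channels"]),
            provenance=dict(payload.get("provenance", {})),
            symbol_to_uniprot=dict(payload.get("symbol_to_uniprot", {})),
        )


def _parse_bool(token: str) -> bool:
    return str(token).strip().lower() in {"1", "true", "t", "yes"}


def load_interaction_table(
    path,
    allowed_resources: Iterable[str] = DEFAULT_ALLOWED_RESOURCES,
    subset_tag: str = LIGREC_SUBSET_TAG,
    human_tax_ids: Iterable[str] = HUMAN_TAX_IDS,
) -> list:
    """Parse and filter the interaction TSV.

    Retains rows with curation_effort > 0, a human taxon, the
    ligand-receptor subset tag and at least one admitted resource label,
    then collapses duplicate (source, target) pairs keeping the maximum
    curation effort and the union of resources. Row counts are logged
    after each filter.
    """
    allowed = frozenset(allowed_resources)
    if not allowed:
        raise ValueError("allowed_resources must be nonempty")
    human = frozenset(human_tax_ids)

    required = {
        "source",
        "target",
        "source_genesymbol",
        "target_genesymbol",
        "is_directed",
        "curation_effort",
        "sources",
        "subset",
        "ncbi_tax_id",
    }
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            missing = sorted(required - set(reader.fieldnames or []))
            raise ValueError(f"{path}: missing columns {missing}")
        for lineno, rec in enumerate(reader, start=2):
            try:
                row = RawInteractionRow(
                    source_id=rec["source"].strip(),
                    target_id=rec["target"].strip(),
                    source_symbol=rec["source_genesymbol"].strip(),
                    target_symbol=rec["target_genesymbol"].strip(),
                    is_directed=_parse_bool(rec["is_directed"]),
                    curation_effort=int(rec["curation_effort"]),
                    resources=frozenset(
                        s for s in rec["sources"].split(";") if s
                    ),
                    subsets=frozenset(s for s in rec["subset"].split(";") if s),
                    organism=rec["ncbi_tax_id"].strip(),
                )
            except (KeyError, ValueError, TypeError, AttributeError) as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from exc
            rows.append(row)

    logger.info("interaction table: %d rows parsed", len(rows))
    rows = [r for r in rows if r.curation_effort > 0]
    logger.info("after curation_effort > 0: %d rows", len(rows))
    rows = [r for r in rows if r.organism in human]
    logger.info("after human-only filter: %d rows", len(rows))
    rows = [r for r in rows if subset_tag in r.subsets]
    logger.info("after subset '%s' filter: %d rows", subset_tag, len(rows))
    rows = [r for r in rows if r.resources & allowed]
    logger.info("after resource filter: %d rows", len(rows))

    # collapse duplicates by (source_id, target_id): max curation effort,
    # union of resources/subsets; a pair directed in any duplicate is directed
    merged: dict = {}
    for r in rows:
        key = (r.source_id, r.target_id)
        if key not in merged:
            merged[key] = r
        else:
            old = merged[key]
            merged[key] = RawInteractionRow(
                source_id=old.source_id,
                target_id=old.target_id,
                source_symbol=old.source_symbol,
                target_symbol=old.target_symbol,
                is_directed=old.is_directed or r.is_directed,
                curation_effort=max(old.curation_effort, r.curation_effort),
                resources=old.resources | r.resources,
                subsets=old.subsets | r.subsets,
                organism=old.organism,
            )
    out = sorted(merged.values(), key=lambda r: (r.source_id, r.target_id))
    if not out:
        logger.warning("interaction table %s: no rows survived filtering", path)
    logger.info("after deduplication: %d rows", len(out))
    return out


def load_protein_roles(path) -> list:
    """Read the CellPhoneDB-style protein role CSV (uniprot, gene_name, receptor)."""
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, rec in enumerate(reader, start=2):
            try:
                rows.append(
                    ProteinRoleRow(
                        uniprot_id=rec["uniprot"].strip(),
                        symbol=rec["gene_name"].strip(),
                        is_receptor=_parse_bool(rec["receptor"]),
                    )
                )
            except (KeyError, AttributeError) as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}") from exc
    return rows


def load_enzyme_catalog(path) -> list:
    """Read the enzyme catalog TSV (uniprot, gene_name, ec_classes, flags)."""
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, rec in enumerate(reader, start=2):
            try:
                rows.append(
                    EnzymeCatalogRow(
                        uniprot_id=rec["uniprot"].strip(),
                        symbol=rec["gene_name"].strip(),
                        ec_classes=frozenset(
                            c for c in rec["ec_classes"].split(";") if c
                        ),
                        is_kinase=_parse_bool(rec["is_kinase"]),
                        is_phosphatase=_parse_bool(rec["is_phosphatase"]),
                    )
                )
            except (KeyError, AttributeError) as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}") from exc
    return rows


def load_ion_channel_list(path) -> frozenset:
    """Read the one-symbol-per-line curated ion-channel list."""
    symbols = set()
    for line in Path(path).read_text().splitlines():
        sym = line.strip()
        if sym and not sym.startswith("#"):
            symbols.add(sym)
    return frozenset(symbols)


def derive_receptor_set(role_rows: Iterable[ProteinRoleRow]) -> frozenset:
    """Symbols flagged as receptors; conflicting duplicate accessions error."""
    seen: dict = {}
    for row in role_rows:
        if row.uniprot_id in seen and seen[row.uniprot_id].is_receptor != row.is_receptor:
            raise ValueError(
                f"conflicting receptor flags for accession {row.uniprot_id}"
            )
        seen[row.uniprot_id] = row
    return frozenset(r.symbol for r in seen.values() if r.is_receptor)


def derive_ligand_set(
    rows: Iterable[RawInteractionRow], receptors: frozenset
) -> frozenset:
    """Source symbols of directed interactions, minus known receptors."""
    return frozenset(r.source_symbol for r in rows if r.is_directed) - receptors


def derive_enzyme_set(catalog: Iterable[EnzymeCatalogRow]) -> frozenset:
    """Catalog members with EC classes that are neither kinases nor phosphatases."""
    out = set()
    for row in catalog:
        if not row.ec_classes:
            continue
        if row.is_kinase or row.is_phosphatase:
            continue
        out.add(row.symbol)
    return frozenset(out)


def derive_ion_channel_set(
    channel_list: Iterable[str], receptors: frozenset, ligands: frozenset
) -> frozenset:
    """Curated channel list minus overlaps with receptors and ligands."""
    return frozenset(channel_list) - receptors - ligands


def build_role_sets(
    interaction_rows: Iterable[RawInteractionRow],
    role_rows: Iterable[ProteinRoleRow],
    enzyme_rows: Iterable[EnzymeCatalogRow],
    channel_symbols: Iterable[str],
) -> GeneRoleSets:
    """Derive all four role sets, provenance and the symbol->accession map."""
    interaction_rows = list(interaction_rows)
    role_rows = list(role_rows)
    enzyme_rows = list(enzyme_rows)

    receptors = derive_receptor_set(role_rows)
    ligands = derive_ligand_set(interaction_rows, receptors)
    enzymes = derive_enzyme_set(enzyme_rows)
    channels = derive_ion_channel_set(channel_symbols, receptors, ligands)

    provenance: dict = {}
    for sym in channels:
        provenance[sym] = "IDG"
    for sym in enzymes:
        provenance.setdefault(sym, "ExPASy")
    for sym in ligands:
        provenance[sym] = "OmniPath"
    for sym in receptors:
        provenance[sym] = "CellPhoneDB"

    sym2acc: dict = {}
    for row in interaction_rows:
        sym2acc.setdefault(row.source_symbol, row.source_id)
        sym2acc.setdefault(row.target_symbol, row.target_id)
    for row in enzyme_rows:
        sym2acc.setdefault(row.symbol, row.uniprot_id)
    for row in role_rows:
        sym2acc.setdefault(row.symbol, row.uniprot_id)

    roles = GeneRoleSets(
        receptors=receptors,
        ligands=ligands,
        enzymes=enzymes,
        ion_channels=channels,
        provenance=provenance,
        symbol_to_uniprot=sym2acc,
    )
    roles.validate()
    logger.info(
        "role sets: %d receptors, %d ligands, %d enzymes, %d ion channels",
        len(receptors),
        len(ligands),
        len(enzymes),
        len(channels),
    )
    return roles


def load_and_build_role_sets(
    omnipath_path,
    cpdb_path,
    enzyme_path,
    channel_path,
    allowed_resources: Iterable[str] = DEFAULT_ALLOWED_RESOURCES,
) -> tuple:
    """Convenience wrapper: parse all four snapshots and derive role sets.

    Returns ``(roles, interaction_rows)`` so the caller can reuse the
    filtered interaction rows for ligand-receptor assembly.
    """
    rows = load_interaction_table(omnipath_path, allowed_resources=allowed_resources)
    roles = build_role_sets(
        rows,
        load_protein_roles(cpdb_path),
        load_enzyme_catalog(enzyme_path),
        load_ion_channel_list(channel_path),
    )
    return roles, rows
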