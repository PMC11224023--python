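"""Three-modality interactome assembly, deduplication, ortholog mapping, export.

The interactome connects immune sender genes to sensory-neuron receiver
genes through three molecular routes:

* ``ligand_receptor``  -- a secreted/surface ligand binding a receptor,
  taken from the filtered interaction table;
* ``enzyme_receptor``  -- an enzyme whose small-molecule product (from
  controls-production-of triples) interacts with a receptor per curated
  statements;
* ``ion_channel``      -- a ligand, or an enzyme product, acting on an
  ion channel; these statements must be backed by a structured database
  or by at least two text-mined sentences.

Every record keeps its evidence list and, for indirect routes, the
intermediate product, so each edge is traceable to its provenance.
Deduplication is per (sender, receiver, modality); the same gene pair may
therefore appear once per modality.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

from .kb_ingest import GeneRoleSets, RawInteractionRow

logger = logging.getLogger(__name__)

MODALITIES = ("ligand_receptor", "enzyme_receptor", "ion_channel")

#: source_api labels treated as structured-database support for statements.
DEFAULT_STRUCTURED_SOURCES = frozenset(
    {"signor", "biogrid", "hprd", "reactome", "intact", "pathway_commons", "drugbank"}
)

SIF_RELATION = "controls-production-of"


@dataclass(frozen=True)
class EvidenceRecord:
    kind: str  # structured_database | text_mining
    statement_type: str  # Complex | Activation | other
    sentence_count: int
    source_label: str

    def __post_init__(self):
        if self.kind not in {"structured_database", "text_mining"}:
            raise ValueError(f"unknown evidence kind {self.kind!r}")
        if self.sentence_count > 0 and self.kind != "text_mining":
            raise ValueError("sentence_count > 0 requires text_mining evidence")


@dataclass(frozen=True)
class EnzymeProductLink:
    enzyme_symbol: str
    product_id: str
    product_name: str


@dataclass(frozen=True)
class InteractionRecord:
    modality: str
    sender_gene: str
    receiver_gene: str
    evidence: tuple  # tuple of EvidenceRecord, nonempty
    intermediate_product: Optional[str] = None
    sender_uniprot: str = ""
    receiver_uniprot: str = ""
    human_ref: Optional[tuple] = None  # (sender, receiver) before ortholog mapping

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if not self.evidence:
            raise ValueError("record without evidence")

    @property
    def key(self) -> tuple:
        return (self.sender_gene, self.receiver_gene, self.modality)


@dataclass
class Interactome:
    records: dict  # key -> InteractionRecord
    species: str = "human"

    @property
    def modality_counts(self) -> dict:
        counts = {m: 0 for m in MODALITIES}
        for rec in self.records.values():
            counts[rec.modality] += 1
        return counts

    def __len__(self) -> int:
        return len(self.records)

    def sorted_records(self) -> list:
        return [self.records[k] for k in sorted(self.records)]


@dataclass(frozen=True)
class Statement:
    """One curated interaction statement (an input dialect, not re-mined text)."""

    stmt_type: str
    subj: str
    obj: str
    evidence: tuple  # of EvidenceRecord


def _statement_evidence(
    stmt_type: str, evid_items: list, structured_sources: frozenset
) -> tuple:
    out = []
    for item in evid_items:
        source = str(item.get("source_api", ""))
        text = item.get("text") or ""
        if source in structured_sources:
            out.append(
                EvidenceRecord(
                    kind="structured_database",
                    statement_type=stmt_type,
                    sentence_count=0,
                    source_label=source,
                )
            )
        else:
            out.append(
                EvidenceRecord(
                    kind="text_mining",
                    statement_type=stmt_type,
                    sentence_count=1 if text else 0,
                    source_label=source,
                )
            )
    return tuple(out)


def load_statements(
    path, structured_sources: Iterable[str] = DEFAULT_STRUCTURED_SOURCES
) -> list:
    """Read the JSONL statement file; only Complex/Activation types are kept."""
    structured = frozenset(structured_sources)
    statements = []
    n_other = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}: malformed JSON at line {lineno}") from exc
            stmt_type = rec.get("type", "other")
            if stmt_type not in {"Complex", "Activation"}:
                n_other += 1
                continue
            statements.append(
                Statement(
                    stmt_type=stmt_type,
                    subj=str(rec["subj"]),
                    obj=str(rec["obj"]),
                    evidence=_statement_evidence(
                        stmt_type, rec.get("evidence", []), structured
                    ),
                )
            )
    if n_other:
        logger.info("statements: skipped %d non-Complex/Activation statements", n_other)
    return statements


def _has_sufficient_evidence(evidence: Iterable[EvidenceRecord]) -> bool:
    """Structured-database support, or >= 2 text-mined supporting sentences."""
    total_sentences = 0
    for ev in evidence:
        if ev.kind == "structured_database":
            return True
        total_sentences += ev.sentence_count
    return total_sentences >= 2


def assemble_ligand_receptor(
    rows: Iterable[RawInteractionRow],
    roles: GeneRoleSets,
    evidence_index: Optional[Mapping] = None,
) -> list:
    """One record per directed (ligand, receptor) pair in the filtered table.

    Evidence comes from ``evidence_index`` keyed by (ligand, receptor)
    when available; otherwise the interaction table's own curation stands
    as a single structured-database evidence record.
    """
    evidence_index = evidence_index or {}
    records = []
    n_skipped = 0
    for row in rows:
        if not row.is_directed:
            continue
        src, tgt = row.source_symbol, row.target_symbol
        if src not in roles.ligands or tgt not in roles.receptors:
            n_skipped += 1
            continue
        evid = tuple(evidence_index.get((src, tgt), ()))
        if not evid:
            evid = (
                EvidenceRecord(
                    kind="structured_database",
                    statement_type="other",
                    sentence_count=0,
                    source_label="interaction_table",
                ),
            )
        records.append(
            InteractionRecord(
                modality="ligand_receptor",
                sender_gene=src,
                receiver_gene=tgt,
                evidence=evid,
                sender_uniprot=row.source_id,
                receiver_uniprot=row.target_id,
            )
        )
    if n_skipped:
        logger.info("ligand-receptor assembly: %d rows failed role gating", n_skipped)
    return records


def build_enzyme_product_map(sif_path, enzymes: frozenset) -> list:
    """Parse the SIF file and keep controls-production-of links from enzymes."""
    links = set()
    n_unknown_rel = 0
    with open(sif_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{sif_path}: malformed SIF row at line {lineno}")
            controller, relation, product = parts
            if relation != SIF_RELATION:
                n_unknown_rel += 1
                continue
            if controller not in enzymes:
                continue
            links.add(
                EnzymeProductLink(
                    enzyme_symbol=controller, product_id=product, product_name=product
                )
            )
    if n_unknown_rel:
        logger.info("SIF: ignored %d rows with other relations", n_unknown_rel)
    return sorted(links, key=lambda l: (l.enzyme_symbol, l.product_id))


def _accession(roles: GeneRoleSets, symbol: str) -> str:
    return roles.symbol_to_uniprot.get(symbol, "")


def assemble_enzyme_interactions(
    links: Iterable[EnzymeProductLink],
    statements: Iterable[Statement],
    roles: GeneRoleSets,
) -> list:
    """Enzyme -> product -> receptor records from product/receptor statements.

    Activation statements are used in their stated direction (product as
    subject); Complex statements are undirected and oriented by role.
    Product -> ion-channel statements are handled by
    :func:`assemble_ion_channel_interactions`, not here.
    """
    by_product: dict = {}
    for link in links:
        by_product.setdefault(link.product_id, []).append(link.enzyme_symbol)

    records = []
    for stmt in statements:
        pairs = _orient(stmt, by_product, roles, partner_role=roles.receptors)
        for product, receptor in pairs:
            for enzyme in sorted(set(by_product[product])):
                records.append(
                    InteractionRecord(
                        modality="enzyme_receptor",
                        sender_gene=enzyme,
                        receiver_gene=receptor,
                        evidence=stmt.evidence,
                        intermediate_product=product,
                        sender_uniprot=_accession(roles, enzyme),
                        receiver_uniprot=_accession(roles, receptor),
                    )
                )
    return records


def _orient(
    stmt: Statement, by_product: Mapping, roles: GeneRoleSets, partner_role: frozenset
) -> list:
    """Yield (product_id, partner) pairs for a statement, respecting direction.

    Activation statements count only in their stated subject->object
    direction; Complex statements are symmetric and oriented by role
    (sender side = the enzyme product).
    """
    pairs = []
    if stmt.subj in by_product and stmt.obj in partner_role:
        pairs.append((stmt.subj, stmt.obj))
    if stmt.stmt_type == "Complex" and stmt.obj in by_product and stmt.subj in partner_role:
        pairs.append((stmt.obj, stmt.subj))
    return pairs


def _orient_ligand(
    stmt: Statement, roles: GeneRoleSets, partner_role: frozenset
) -> list:
    pairs = []
    if stmt.subj in roles.ligands and stmt.obj in partner_role:
        pairs.append((stmt.subj, stmt.obj))
    if stmt.stmt_type == "Complex" and stmt.obj in roles.ligands and stmt.subj in partner_role:
        pairs.append((stmt.obj, stmt.subj))
    return pairs


def assemble_ion_channel_interactions(
    statements: Iterable[Statement],
    roles: GeneRoleSets,
    links: Iterable[EnzymeProductLink] = (),
) -> list:
    """Ligand->channel and enzyme->product->channel records with evidence gating.

    A record is retained only when some evidence is a structured database
    or the text-mined sentences total at least two.
    """
    by_product: dict = {}
    for link in links:
        by_product.setdefault(link.product_id, []).append(link.enzyme_symbol)

    records = []
    n_filtered = 0
    for stmt in statements:
        if not _has_sufficient_evidence(stmt.evidence):
            n_filtered += 1
            continue
        for ligand, channel in _orient_ligand(stmt, roles, roles.ion_channels):
            records.append(
                InteractionRecord(
                    modality="ion_channel",
                    sender_gene=ligand,
                    receiver_gene=channel,
                    evidence=stmt.evidence,
                    sender_uniprot=_accession(roles, ligand),
                    receiver_uniprot=_accession(roles, channel),
                )
            )
        for product, channel in _orient(stmt, by_product, roles, roles.ion_channels):
            for enzyme in sorted(set(by_product[product])):
                records.append(
                    InteractionRecord(
                        modality="ion_channel",
                        sender_gene=enzyme,
                        receiver_gene=channel,
                        evidence=stmt.evidence,
                        intermediate_product=product,
                        sender_uniprot=_accession(roles, enzyme),
                        receiver_uniprot=_accession(roles, channel),
                    )
                )
    if n_filtered:
        logger.info(
            "ion-channel assembly: %d statements failed the evidence filter",
            n_filtered,
        )
    return records


def _merge(a: InteractionRecord, b: InteractionRecord) -> InteractionRecord:
    """Merge two records sharing a key: union evidence, keep first product."""
    evid = list(a.evidence)
    for ev in b.evidence:
        if ev not in evid:
            evid.append(ev)
    return replace(
        a,
        evidence=tuple(evid),
        intermediate_product=a.intermediate_product or b.intermediate_product,
        sender_uniprot=a.sender_uniprot or b.sender_uniprot,
        receiver_uniprot=a.receiver_uniprot or b.receiver_uniprot,
    )


def deduplicate_union(
    lr: Iterable[InteractionRecord],
    enz: Iterable[InteractionRecord],
    ion: Iterable[InteractionRecord],
) -> Interactome:
    """Union the three modalities keyed by (sender, receiver, modality)."""
    records: dict = {}
    for rec in list(lr) + list(enz) + list(ion):
        if rec.key in records:
            records[rec.key] = _merge(records[rec.key], rec)
        else:
            records[rec.key] = rec
    itx = Interactome(records=records, species="human")
    counts = itx.modality_counts
    assert len(itx) == sum(counts.values())
    logger.info(
        "interactome: %d records (%s)",
        len(itx),
        ", ".join(f"{m}={counts[m]}" for m in MODALITIES),
    )
    return itx


@dataclass
class OrthologMap:
    pairs: frozenset  # of (human_symbol, mouse_symbol)
    unmapped: frozenset = frozenset()

    def targets(self, human_symbol: str) -> list:
        return sorted(m for h, m in self.pairs if h == human_symbol)


def load_ortholog_map(path) -> OrthologMap:
    """Read the human->mouse ortholog TSV (human_symbol, mouse_symbol)."""
    pairs = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"human_symbol", "mouse_symbol"}.issubset(
            reader.fieldnames
        ):
            raise ValueError(f"{path}: expected columns human_symbol, mouse_symbol")
        for rec in reader:
            h = rec["human_symbol"].strip()
            m = rec["mouse_symbol"].strip()
            if h and m:
                pairs.add((h, m))
    if not pairs:
        raise ValueError(f"{path}: empty ortholog table")
    return OrthologMap(pairs=frozenset(pairs))


def map_orthologs(itx: Interactome, omap: OrthologMap) -> tuple:
    """Expand a human interactome over mouse orthologs.

    Each record is expanded over the Cartesian product of its endpoints'
    mouse orthologs; records with any unmapped endpoint are dropped.
    Returns ``(mouse_interactome, dropped_human_keys)``.
    """
    if itx.species != "human":
        raise ValueError("ortholog mapping expects a human interactome")
    if not omap.pairs:
        raise ValueError("empty ortholog table")

    by_human: dict = {}
    for h, m in omap.pairs:
        by_human.setdefault(h, set()).add(m)

    records: dict = {}
    dropped = []
    for rec in itx.sorted_records():
        senders = sorted(by_human.get(rec.sender_gene, ()))
        receivers = sorted(by_human.get(rec.receiver_gene, ()))
        if not senders or not receivers:
            dropped.append(rec.key)
            continue
        for ms in senders:
            for mr in receivers:
                mouse = replace(
                    rec,
                    sender_gene=ms,
                    receiver_gene=mr,
                    human_ref=(rec.sender_gene, rec.receiver_gene),
                )
                if mouse.key in records:
                    records[mouse.key] = _merge(records[mouse.key], mouse)
                else:
                    records[mouse.key] = mouse
    if dropped:
        logger.info("ortholog mapping dropped %d records with unmapped endpoints", len(dropped))
    return Interactome(records=records, species="mouse"), dropped


EXPORT_COLUMNS = [
    "interaction_name",
    "ligand",
    "receptor",
    "sender_uniprot",
    "receiver_uniprot",
    "modality",
    "intermediate_product",
    "evidence_summary",
]


def export_cellchat_db(itx: Interactome, roles: GeneRoleSets, out_path) -> None:
    """Write the interactome as a headered TSV compatible with downstream scoring.

    Proteins are identified by UniProt accessions where known, with a
    symbol fallback (warned). The evidence list is serialized as JSON in
    ``evidence_summary`` so the table round-trips losslessly through
    :func:`read_cellchat_db`. Rows are sorted by key for determinism.
    """
    with open(out_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(EXPORT_COLUMNS)
        for rec in itx.sorted_records():
            s_acc = rec.sender_uniprot or roles.symbol_to_uniprot.get(rec.sender_gene, "")
            r_acc = rec.receiver_uniprot or roles.symbol_to_uniprot.get(
                rec.receiver_gene, ""
            )
            if not s_acc or not r_acc:
                logger.warning(
                    "missing accession for %s -> %s; writing symbol fallback",
                    rec.sender_gene,
                    rec.receiver_gene,
                )
            evid = json.dumps(
                [
                    {
                        "kind": ev.kind,
                        "statement_type": ev.statement_type,
                        "sentence_count": ev.sentence_count,
                        "source_label": ev.source_label,
                    }
                    for ev in rec.evidence
                ],
                sort_keys=True,
            )
            writer.writerow(
                [
                    f"{rec.sender_gene}_{rec.receiver_gene}",
                    rec.sender_gene,
                    rec.receiver_gene,
                    s_acc or rec.sender_gene,
                    r_acc or rec.receiver_gene,
                    rec.modality,
                    rec.intermediate_product or "",
                    evid,
                ]
            )


def read_cellchat_db(path, species: str = "human") -> Interactome:
    """Read an exported interactome TSV back into an :class:`Interactome`."""
    records: dict = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for rec in reader:
            evid = tuple(
                EvidenceRecord(
                    kind=e["kind"],
                    statement_type=e["statement_type"],
                    sentence_count=int(e["sentence_count"]),
                    source_label=e["source_label"],
                )
                for e in json.loads(rec["evidence_summary"])
            )
            record = InteractionRecord(
                modality=rec["modality"],
                sender_gene=rec["ligand"],
                receiver_gene=rec["receptor"],
                evidence=evid,
                intermediate_product=rec["intermediate_product"] or None,
                sender_uniprot=rec["sender_uniprot"],
                receiver_uniprot=rec["receiver_uniprot"],
            )
            records[record.key] = record
    return Interactome(records=records, species=species)


def assemble_interactome(
    interaction_rows: Iterable[RawInteractionRow],
    roles: GeneRoleSets,
    sif_path,
    statements_path,
    structured_sources: Iterable[str] = DEFAULT_STRUCTURED_SOURCES,
) -> Interactome:
    """Run the full three-modality assembly from parsed inputs."""
    statements = load_statements(statements_path, structured_sources)
    links = build_enzyme_product_map(sif_path, roles.enzymes)
    lr = assemble_ligand_receptor(interaction_rows, roles)
    enz = assemble_enzyme_interactions(links, statements, roles)
    ion = assemble_ion_channel_interactions(statements, roles, links)
    return deduplicate_union(lr, enz, ion)
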