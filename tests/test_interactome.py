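"""Three-modality assembly, evidence gating, dedup, orthologs, export."""

import json
from dataclasses import replace

import pytest

from nimx.interactome import (
    EvidenceRecord,
    InteractionRecord,
    assemble_interactome,
    assemble_ion_channel_interactions,
    assemble_ligand_receptor,
    build_enzyme_product_map,
    deduplicate_union,
    export_cellchat_db,
    load_ortholog_map,
    load_statements,
    map_orthologs,
    read_cellchat_db,
    Statement,
)


def ev(kind="structured_database", sentences=0, stmt="Activation"):
    return EvidenceRecord(
        kind=kind, statement_type=stmt, sentence_count=sentences, source_label="x"
    )


def record(sender, receiver, modality="ligand_receptor", product=None, evidence=None):
    return InteractionRecord(
        modality=modality,
        sender_gene=sender,
        receiver_gene=receiver,
        intermediate_product=product,
        evidence=evidence or (ev(),),
    )


@pytest.fixture(scope="module")
def assembled(fixture_kb, fixture_roles):
    kb_dir, _ = fixture_kb
    roles, rows = fixture_roles
    return assemble_interactome(
        rows, roles, kb_dir / "pc_sif.tsv", kb_dir / "statements.jsonl"
    )


def test_anchor_ligand_receptor_records_present(assembled):
    keys = set(assembled.records)
    assert ("THBS1", "CD47", "ligand_receptor") in keys
    assert ("OSM", "IL6ST", "ligand_receptor") in keys


def test_role_gating_blocks_non_receptor_targets(fixture_roles):
    roles, rows = fixture_roles
    records = assemble_ligand_receptor(rows, roles)
    receivers = {r.receiver_gene for r in records}
    assert receivers <= roles.receptors  # sink targets never become receivers
    senders = {r.sender_gene for r in records}
    assert senders <= roles.ligands
    assert "UNDL01" not in senders  # undirected row contributes nothing


def test_every_record_has_nonempty_evidence_and_enzyme_product(assembled):
    for rec in assembled.records.values():
        assert rec.evidence
        if rec.modality == "enzyme_receptor":
            assert rec.intermediate_product


def test_enzyme_product_map_filters_relation_and_membership(fixture_kb, fixture_roles):
    kb_dir, _ = fixture_kb
    roles, _ = fixture_roles
    links = build_enzyme_product_map(kb_dir / "pc_sif.tsv", roles.enzymes)
    by_enzyme = {}
    for link in links:
        by_enzyme.setdefault(link.enzyme_symbol, set()).add(link.product_id)
    assert "CHEBI:15551" in by_enzyme["PTGS2"]  # prostaglandin E2
    assert "CHEBI:16958" in by_enzyme["ALDH3A2"]  # beta-alanine
    assert "KINA01" not in by_enzyme  # kinase is not an enzyme-set member
    assert "THBS1" not in by_enzyme
    assert all("99990" not in p for ps in by_enzyme.values() for p in ps)  # unknown relation


def test_enzyme_records_carry_intermediate_products(assembled):
    keys = set(assembled.records)
    assert ("PTGS2", "PTGER4", "enzyme_receptor") in keys
    assert assembled.records[("PTGS2", "PTGER4", "enzyme_receptor")].intermediate_product == "CHEBI:15551"
    assert ("ALDH3A2", "MRGPRD", "enzyme_receptor") in keys


def test_reversed_activation_statement_produces_no_record(assembled):
    # the fixture plants Activation PTGER4 -> PGE2 (receptor as subject)
    assert ("PTGS2", "PTGER4", "ion_channel") not in assembled.records
    for rec in assembled.records.values():
        assert rec.receiver_gene != "CHEBI:15551"


def test_ion_channel_evidence_boundary(fixture_roles):
    roles, _ = fixture_roles
    channel = sorted(roles.ion_channels)[0]
    ligand = sorted(roles.ligands)[0]

    def stmt(n_sentences, with_db=False):
        evid = tuple(
            [ev("structured_database")] * int(with_db)
            + [ev("text_mining", 1)] * n_sentences
        )
        return Statement("Activation", ligand, channel, evid)

    assert assemble_ion_channel_interactions([stmt(1)], roles) == []
    assert len(assemble_ion_channel_interactions([stmt(2)], roles)) == 1
    assert len(assemble_ion_channel_interactions([stmt(0, with_db=True)], roles)) == 1


def test_channel_records_never_text_only_below_two_sentences(assembled):
    for rec in assembled.records.values():
        if rec.modality != "ion_channel":
            continue
        has_db = any(e.kind == "structured_database" for e in rec.evidence)
        n_sent = sum(e.sentence_count for e in rec.evidence)
        assert has_db or n_sent >= 2


def test_ngf_trpv1_retained(assembled):
    assert ("NGF", "TRPV1", "ion_channel") in assembled.records


def test_statement_loader_skips_other_types(tmp_path):
    path = tmp_path / "stmts.jsonl"
    path.write_text(
        json.dumps({"type": "Phosphorylation", "subj": "A", "obj": "B", "evidence": []})
        + "\n"
        + json.dumps(
            {"type": "Activation", "subj": "A", "obj": "B",
             "evidence": [{"source_api": "signor", "text": ""}]}
        )
        + "\n"
    )
    statements = load_statements(path)
    assert len(statements) == 1
    assert statements[0].evidence[0].kind == "structured_database"


def test_dedup_union_counts_and_idempotence():
    lr = [record("A", "B"), record("A", "B"), record("C", "B")]
    enz = [record("E", "B", "enzyme_receptor", product="X")]
    ion = [record("A", "B", "ion_channel")]  # same pair, different modality
    itx = deduplicate_union(lr, enz, ion)
    assert len(itx) == 4
    assert itx.modality_counts == {
        "ligand_receptor": 2,
        "enzyme_receptor": 1,
        "ion_channel": 1,
    }
    assert len(itx) == sum(itx.modality_counts.values())


def test_dedup_merges_evidence_on_key_collision():
    a = record("A", "B", evidence=(ev("structured_database"),))
    b = record("A", "B", evidence=(ev("text_mining", 2),))
    itx = deduplicate_union([a, b], [], [])
    assert len(itx.records[("A", "B", "ligand_receptor")].evidence) == 2


def test_ortholog_expansion_and_drop(tmp_path):
    table = tmp_path / "orth.tsv"
    table.write_text(
        "human_symbol\tmouse_symbol\nTHBS1\tThbs1\nCD47\tCd47\nDUP\tDupa\nDUP\tDupb\n"
    )
    omap = load_ortholog_map(table)
    itx = deduplicate_union(
        [record("THBS1", "CD47"), record("DUP", "CD47"), record("GONE", "CD47")], [], []
    )
    mouse, dropped = map_orthologs(itx, omap)
    keys = set(mouse.records)
    assert ("Thbs1", "Cd47", "ligand_receptor") in keys
    assert ("Dupa", "Cd47", "ligand_receptor") in keys
    assert ("Dupb", "Cd47", "ligand_receptor") in keys
    assert dropped == [("GONE", "CD47", "ligand_receptor")]
    # never invents symbols
    known_mouse = {m for _, m in omap.pairs}
    for s, r, _ in keys:
        assert s in known_mouse and r in known_mouse
    # back-reference to the human record
    assert mouse.records[("Thbs1", "Cd47", "ligand_receptor")].human_ref == ("THBS1", "CD47")


def test_ortholog_mapping_requires_human_interactome(tmp_path):
    table = tmp_path / "orth.tsv"
    table.write_text("human_symbol\tmouse_symbol\nA\ta\n")
    omap = load_ortholog_map(table)
    itx = deduplicate_union([record("A", "A")], [], [])
    mouse, _ = map_orthologs(itx, omap)
    with pytest.raises(ValueError):
        map_orthologs(mouse, omap)


def test_empty_ortholog_table_errors(tmp_path):
    table = tmp_path / "orth.tsv"
    table.write_text("human_symbol\tmouse_symbol\n")
    with pytest.raises(ValueError, match="empty"):
        load_ortholog_map(table)


def test_export_round_trip_and_determinism(tmp_path, assembled, fixture_roles):
    roles, _ = fixture_roles
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    export_cellchat_db(assembled, roles, p1)
    export_cellchat_db(assembled, roles, p2)
    assert p1.read_bytes() == p2.read_bytes()
    back = read_cellchat_db(p1)
    expected = {k: replace(v, human_ref=None) for k, v in assembled.records.items()}
    assert back.records == expected
    n_lines = len(p1.read_text().splitlines())
    assert n_lines == len(assembled) + 1  # header + one row per record
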