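"""The matcher: orientation handling, comparators, serialization, oracle."""

import numpy as np
import pytest

from ligrec import (
    LigrecError,
    PairDatabase,
    PairRecord,
    annotate_comparators,
    match_interactions,
    read_interaction_table,
    write_interaction_table,
)
from ligrec import datasets

from conftest import brute_force_match, make_profile, random_instance


def test_lthsc_table_contains_cxcr4_cxcl12_row(reference_tables):
    """Stem cells express the chemokine receptor; the stroma its ligand."""
    rows = [
        r
        for r in reference_tables["LT-HSC"]
        if r.pop_gene == "chemokine (c-x-c motif) receptor 4"
        and r.stroma_gene == "chemokine (c-x-c motif) ligand 12"
    ]
    assert len(rows) == 1
    row = rows[0]
    assert row.pop_intensity == 372
    assert row.stroma_intensity == 12222
    assert row.direction == "pop_receptor__stroma_ligand"


def test_empty_gate_gives_empty_table(pair_db):
    pop = datasets.population_profile("proB")
    stroma = datasets.stroma_profile("proB", "OP9")
    table = match_interactions(set(), pop, stroma, pair_db)
    assert len(table) == 0


def test_empty_db_warns_and_gives_empty_table(caplog):
    pop = make_profile("p", {"a": 10.0})
    stroma = make_profile("s", {"b": 10.0})
    with caplog.at_level("WARNING", logger="ligrec.matching"):
        table = match_interactions(None, pop, stroma, PairDatabase([]))
    assert len(table) == 0
    assert any("empty pair database" in r.message for r in caplog.records)


def test_absent_genes_cannot_match():
    db = PairDatabase([PairRecord(pair_id="1", gene_a="a", gene_b="b")])
    pop = make_profile("p", {"a": 10.0}, present={"a": True})
    stroma = make_profile("s", {"b": 10.0}, present={"b": False})
    assert len(match_interactions(None, pop, stroma, db)) == 0
    stroma2 = make_profile("s", {"b": 10.0}, present={"b": True})
    assert len(match_interactions(None, pop, stroma2, db)) == 1


def test_both_directions_emitted_when_both_sides_qualify():
    """A pair expressed on both sides yields two rows, flagged autocrine."""
    db = PairDatabase(
        [PairRecord(pair_id="1", gene_a="r", gene_b="l", role_a="receptor", role_b="ligand")]
    )
    pop = make_profile("p", {"r": 10.0, "l": 20.0})
    stroma = make_profile("s", {"r": 30.0, "l": 40.0})
    table = match_interactions(None, pop, stroma, db)
    directions = {r.direction for r in table}
    assert directions == {"pop_receptor__stroma_ligand", "pop_ligand__stroma_receptor"}
    assert all(r.autocrine for r in table)


def test_gate_restricts_population_side_only():
    db = PairDatabase([PairRecord(pair_id="1", gene_a="a", gene_b="b")])
    pop = make_profile("p", {"a": 10.0, "b": 5.0})
    stroma = make_profile("s", {"a": 7.0, "b": 9.0})
    table = match_interactions({"a"}, pop, stroma, db)
    assert [(r.pop_gene, r.stroma_gene) for r in table] == [("a", "b")]


def test_matcher_equals_nested_loop_oracle_on_random_instances():
    rng = np.random.default_rng(2024)
    for _ in range(40):
        gate, pop, stroma, db = random_instance(rng)
        table = match_interactions(gate, pop, stroma, db)
        got = {(r.pop_gene, r.stroma_gene) for r in table}
        assert got == brute_force_match(gate, pop, stroma, db)
        # soundness: every row's pair exists in the db
        for row in table:
            assert row.pair_key in {r.unordered_key for r in db}


def test_comparator_annotation_values_and_na(reference_tables):
    table = reference_tables["LT-HSC"]
    cxcl12 = next(
        r for r in table if r.stroma_gene == "chemokine (c-x-c motif) ligand 12"
    )
    assert cxcl12.comparator("NIH3T3") == 23
    assert cxcl12.comparator("Osteoblasts") == 798

    bare = datasets.matched_table("LT-HSC", with_comparators=False)
    missing_gene = make_profile("Partial", {"not a stroma gene": 5.0})
    annotated = annotate_comparators(bare, [missing_gene])
    assert len(annotated) == len(bare)
    assert all(r.comparator("Partial") is None for r in annotated)


def test_empty_comparator_list_is_identity(reference_tables):
    table = datasets.matched_table("preB", with_comparators=False)
    assert annotate_comparators(table, []) is table


def test_duplicate_comparator_labels_rejected(reference_tables):
    prof = make_profile("X", {"a": 1.0})
    with pytest.raises(LigrecError, match="not unique"):
        annotate_comparators(datasets.matched_table("preB"), [prof, prof])


def test_write_read_write_produces_identical_bytes(tmp_path, reference_tables):
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_interaction_table(reference_tables["proB"], p1)
    back = read_interaction_table(p1)
    write_interaction_table(back, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_identical_inputs_produce_byte_identical_output(tmp_path):
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_interaction_table(datasets.matched_table("CLP"), p1)
    write_interaction_table(datasets.matched_table("CLP"), p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_rows_sorted_by_stroma_then_population_symbol(reference_tables):
    table = reference_tables["matureB"]
    keys = [(r.stroma_symbol.casefold(), r.pop_symbol.casefold()) for r in table]
    assert keys == sorted(keys)
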