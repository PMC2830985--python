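"""Supportive-vs-non-supportive stroma candidate screen."""

import pytest

from ligrec import nominate_candidates
from ligrec import datasets
from ligrec.degating import INTENSITY_FLOOR

from conftest import make_profile


@pytest.fixture(scope="module")
def prob_screen_inputs():
    return (
        datasets.stroma_profile("proB", "OP9"),
        datasets.stroma_profile("proB", "NIH3T3"),
        datasets.matched_table("proB"),
    )


def brute_force_candidates(supportive, nonsupportive, table, min_fold, min_intensity):
    """Independent filter over the table's stroma-side genes."""
    out = set()
    for gene in {r.stroma_gene for r in table}:
        supp = supportive.intensity(gene)
        nonsupp = (
            nonsupportive.intensity(gene) if gene in nonsupportive.genes else 0.0
        )
        if supp >= min_intensity and supp / max(nonsupp, INTENSITY_FLOOR) >= min_fold:
            out.add(gene)
    return out


def test_bmp4_nominated_with_activin_receptor_evidence(prob_screen_inputs):
    cands = nominate_candidates(*prob_screen_inputs)
    bmp4 = next(c for c in cands if c.ligand == "bone morphogenetic protein 4")
    assert bmp4.supportive_intensity == 1335
    assert bmp4.nonsupportive_intensity == 66
    assert bmp4.fold_change == pytest.approx(1335 / 66)
    assert {sym for _, sym, _ in bmp4.receptors} == {
        "activin receptor IIA",
        "activin receptor IIB",
    }
    assert dict((sym, v) for _, sym, v in bmp4.receptors)["activin receptor IIB"] == 178


def test_cxcl12_nominated_and_ranked_first(prob_screen_inputs):
    cands = nominate_candidates(*prob_screen_inputs)
    cxcl12 = next(
        c for c in cands if c.ligand == "chemokine (c-x-c motif) ligand 12"
    )
    assert cxcl12.supportive_intensity == 12222
    assert cxcl12.nonsupportive_intensity == 23
    assert cxcl12.rank == 1  # by far the largest contrast
    assert [sym for _, sym, _ in cxcl12.receptors] == [
        "chemokine (C-X-C motif) receptor 4"
    ]


def test_il7_not_in_default_candidate_set(prob_screen_inputs):
    """IL-7 (189 vs 92, ~2x) distinguishes the stromata too weakly; the screen
    finds supportive-stroma-specific factors, not every lymphopoietic one."""
    cands = nominate_candidates(*prob_screen_inputs)
    assert all(c.ligand != "interleukin 7" for c in cands)


def test_candidate_set_equals_brute_force_oracle(prob_screen_inputs):
    supportive, nonsupportive, table = prob_screen_inputs
    for min_fold, min_intensity in [(5, 100), (2, 50), (10, 400), (1, 0)]:
        got = {
            c.ligand
            for c in nominate_candidates(
                supportive, nonsupportive, table, min_fold, min_intensity
            )
        }
        assert got == brute_force_candidates(
            supportive, nonsupportive, table, min_fold, min_intensity
        )


def test_soundness_and_rank_invariants(prob_screen_inputs):
    supportive, nonsupportive, table = prob_screen_inputs
    cands = nominate_candidates(supportive, nonsupportive, table)
    stroma_genes = {r.stroma_gene for r in table}
    assert [c.rank for c in cands] == list(range(1, len(cands) + 1))
    folds = [c.fold_change for c in cands]
    assert folds == sorted(folds, reverse=True)
    for c in cands:
        assert c.ligand in stroma_genes
        assert c.receptors  # never empty
        assert c.fold_change >= 5.0


def test_monotonicity_in_both_thresholds(prob_screen_inputs):
    supportive, nonsupportive, table = prob_screen_inputs
    base = {c.ligand for c in nominate_candidates(supportive, nonsupportive, table, 2, 50)}
    tighter_fold = {
        c.ligand for c in nominate_candidates(supportive, nonsupportive, table, 8, 50)
    }
    tighter_level = {
        c.ligand for c in nominate_candidates(supportive, nonsupportive, table, 2, 300)
    }
    assert tighter_fold <= base
    assert tighter_level <= base


def test_vacuous_threshold_gives_empty_result(prob_screen_inputs):
    supportive, nonsupportive, table = prob_screen_inputs
    assert nominate_candidates(supportive, nonsupportive, table, min_fold=1e6) == []


def test_empty_table_warns_and_returns_empty(caplog):
    from ligrec.matching import InteractionTable

    with caplog.at_level("WARNING", logger="ligrec.candidates"):
        out = nominate_candidates(
            make_profile("s", {"a": 500.0}),
            make_profile("n", {"a": 1.0}),
            InteractionTable("pop", "stroma", []),
        )
    assert out == []
    assert any("empty interaction table" in r.message for r in caplog.records)


def test_absent_nonsupportive_gene_uses_intensity_floor():
    from ligrec.matching import InteractionRow, InteractionTable

    table = InteractionTable(
        "pop",
        "stroma",
        [
            InteractionRow(
                pop_gene="r1",
                pop_symbol="R1",
                pop_intensity=200.0,
                stroma_gene="l1",
                stroma_symbol="L1",
                stroma_intensity=400.0,
                direction="adhesion_pair",
            )
        ],
    )
    cands = nominate_candidates(
        make_profile("s", {"l1": 400.0}),
        make_profile("n", {}),  # gene entirely absent from the comparator
        table,
    )
    assert len(cands) == 1
    assert cands[0].fold_change == pytest.approx(400.0)
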