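"""Differential-expression gating: Welch t, moderated t, fold-change gate."""

import math

import numpy as np
import pytest
from scipy import stats

from ligrec import ValidationError, differential_genes, fold_change_gate
from ligrec.degating import welch_t_test, write_gene_list, read_gene_list

from conftest import make_profile


def replicate_profiles(rng, n_genes=50, n_reps=3, effect_genes=(), effect=5.0):
    """Two profiles with log-normal noise; ``effect_genes`` boosted in pop."""
    keys = [f"g{i}" for i in range(n_genes)]
    mu = rng.normal(7, 1, n_genes)
    pop_vals, ref_vals = {}, {}
    for i, k in enumerate(keys):
        boost = effect if k in effect_genes else 0.0
        pop_vals[k] = 2.0 ** (mu[i] + boost + rng.normal(0, 0.5, n_reps))
        ref_vals[k] = 2.0 ** (mu[i] + rng.normal(0, 0.5, n_reps))
    pop = make_profile("pop", {k: np.mean(v) for k, v in pop_vals.items()}, replicates=pop_vals)
    ref = make_profile("ref", {k: np.mean(v) for k, v in ref_vals.items()}, replicates=ref_vals)
    return pop, ref


def test_welch_t_matches_scipy_oracle():
    rng = np.random.default_rng(3)
    for _ in range(50):
        x = rng.normal(10, 1, int(rng.integers(2, 6)))
        y = rng.normal(11, 2, int(rng.integers(2, 6)))
        t, p = welch_t_test(x, y)
        t_ref, p_ref = stats.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(t_ref)
        assert p == pytest.approx(p_ref)


def test_identical_groups_give_empty_list():
    reps = {"g1": (100.0, 110.0, 90.0)}
    pop = make_profile("pop", {"g1": 100.0}, replicates=reps)
    ref = make_profile("ref", {"g1": 100.0}, replicates=reps)
    assert len(differential_genes(pop, ref)) == 0


def test_strong_synthetic_gene_retained_at_alpha_001():
    """log2 means 10 vs 15 at sd 0.1, n=3/3: the Welch-t oracle gives p<<0.01."""
    rng = np.random.default_rng(1)
    x_log2 = 15 + rng.normal(0, 0.1, 3)
    y_log2 = 10 + rng.normal(0, 0.1, 3)
    # oracle first: direct Welch computation on the same log values
    _, p_oracle = stats.ttest_ind(x_log2, y_log2, equal_var=False)
    assert p_oracle < 0.01
    pop = make_profile("pop", {"g": 0}, replicates={"g": 2.0**x_log2 - 1})
    ref = make_profile("ref", {"g": 0}, replicates={"g": 2.0**y_log2 - 1})
    gate = differential_genes(pop, ref, alpha=0.01)
    assert "g" in gate
    assert gate.entries["g"].p_value == pytest.approx(p_oracle)
    assert gate.entries["g"].direction == "up_in_population"


def test_gene_at_p_above_alpha_excluded():
    pop = make_profile("p", {"g": 0}, replicates={"g": (100.0, 140.0, 90.0)})
    ref = make_profile("r", {"g": 0}, replicates={"g": (95.0, 120.0, 130.0)})
    _, p = welch_t_test(
        np.log2(np.array([100, 140, 90.0]) + 1), np.log2(np.array([95, 120, 130.0]) + 1)
    )
    assert p > 0.01  # sanity: this toy case is genuinely non-significant
    assert "g" not in differential_genes(pop, ref, alpha=0.01)


def test_single_replicate_welch_raises_instructive_error():
    pop = make_profile("p", {"g": 100.0})
    ref = make_profile("r", {"g": 700.0})
    with pytest.raises(ValidationError, match="fold_change_gate"):
        differential_genes(pop, ref)


def test_alpha_monotonicity_shrink_only():
    rng = np.random.default_rng(5)
    pop, ref = replicate_profiles(rng, effect_genes={"g0", "g1"}, effect=2.0)
    previous = None
    for alpha in (0.1, 0.05, 0.01, 0.001):
        genes = differential_genes(pop, ref, alpha=alpha).genes
        if previous is not None:
            assert genes <= previous
        previous = genes


def test_swap_preserves_set_and_flips_direction():
    rng = np.random.default_rng(6)
    pop, ref = replicate_profiles(rng, n_genes=30, effect_genes={"g0"}, effect=3.0)
    fwd = differential_genes(pop, ref, alpha=0.05)
    rev = differential_genes(ref, pop, alpha=0.05)
    assert fwd.genes == rev.genes
    for k in fwd.genes:
        assert fwd.entries[k].direction != rev.entries[k].direction
        assert fwd.entries[k].log2_fold_change == pytest.approx(
            -rev.entries[k].log2_fold_change
        )


@pytest.mark.parametrize("test", ["welch_t", "moderated_t"])
def test_planted_de_genes_recovered_with_high_power(test):
    """n=3/3, |log2FC|=5, sd=0.5: power > 0.9 over 200 simulated genes."""
    rng = np.random.default_rng(7)
    planted = {f"g{i}" for i in range(200)}
    pop, ref = replicate_profiles(rng, n_genes=250, effect_genes=planted, effect=5.0)
    gate = differential_genes(pop, ref, alpha=0.01, test=test)
    power = len(gate.genes & planted) / len(planted)
    assert power > 0.9


def test_moderated_t_shrinks_variance_outliers():
    """A gene with a freak tiny sample variance should not dominate: its
    moderated p must be larger than its raw Welch p."""
    rng = np.random.default_rng(8)
    pop, ref = replicate_profiles(rng, n_genes=100)
    # hand-plant a small mean shift with near-zero within-group variance
    reps_pop = {"g0": (2**8.0, 2**8.001, 2**8.002)}
    reps_ref = {"g0": (2**7.9, 2**7.901, 2**7.902)}
    pop.genes.update(make_profile("x", {"g0": 0}, replicates=reps_pop).genes)
    ref.genes.update(make_profile("x", {"g0": 0}, replicates=reps_ref).genes)
    welch = differential_genes(pop, ref, alpha=1.0, test="welch_t")
    moderated = differential_genes(pop, ref, alpha=1.0, test="moderated_t")
    assert moderated.entries["g0"].p_value > welch.entries["g0"].p_value


def test_bh_adjustment_never_decreases_pvalues():
    rng = np.random.default_rng(9)
    pop, ref = replicate_profiles(rng, n_genes=80, effect_genes={"g0"}, effect=4.0)
    raw = differential_genes(pop, ref, alpha=1.0)
    adj = differential_genes(pop, ref, alpha=1.0, adjust="bh")
    for k in adj.genes:
        assert adj.entries[k].p_value >= raw.entries[k].p_value - 1e-15


def test_fold_change_gate_bmp4_case_and_floor():
    pop = make_profile("pop", {"bmp4": 1335.0, "flat": 100.0, "zero": 0.0})
    ref = make_profile("ref", {"bmp4": 66.0, "flat": 100.0, "zero": 50.0})
    gate = fold_change_gate(pop, ref, min_fold=5.0)
    assert "bmp4" in gate  # 1335/66 > 5
    assert "flat" not in gate  # ratio 1
    assert "zero" in gate  # floor: 50/max(0,1) = 50
    assert gate.entries["zero"].direction == "up_in_reference"
    assert gate.entries["bmp4"].p_value == 1.0


def test_fold_gate_monotone_in_min_fold():
    rng = np.random.default_rng(10)
    pop = make_profile("p", {f"g{i}": float(rng.uniform(1, 2000)) for i in range(50)})
    ref = make_profile("r", {f"g{i}": float(rng.uniform(1, 2000)) for i in range(50)})
    previous = None
    for fold in (1.5, 2, 5, 10):
        genes = fold_change_gate(pop, ref, fold).genes
        if previous is not None:
            assert genes <= previous
        previous = genes


def test_gene_list_write_read_round_trip(tmp_path):
    pop = make_profile("p", {"a": 1000.0, "b": 10.0})
    ref = make_profile("r", {"a": 10.0, "b": 1000.0})
    gate = fold_change_gate(pop, ref, 5.0)
    path = tmp_path / "de.tsv"
    write_gene_list(gate, path)
    back = read_gene_list(path)
    assert back.genes == gate.genes
    for k in gate.genes:
        assert back.entries[k].direction == gate.entries[k].direction
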