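"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ligrec import PairDatabase, PairRecord, PopulationProfile
from ligrec import datasets
from ligrec.expression import GeneExpression


def make_profile(name, values, present=None, replicates=None):
    """Tiny-profile builder: values maps gene key -> mean intensity."""
    genes = {}
    for key, v in values.items():
        reps = tuple(replicates[key]) if replicates and key in replicates else (float(v),)
        genes[key] = GeneExpression(
            key=key,
            symbol=key.upper(),
            mean_intensity=float(np.mean(reps)),
            replicate_intensities=reps,
            present=True if present is None else present.get(key, True),
        )
    return PopulationProfile(name=name, genes=genes)


def brute_force_match(gate_keys, pop, stroma, db):
    """Exhaustive nested-loop reference for the matcher.

    Loops over every db pair and both side assignments; returns the set of
    (pop_gene, stroma_gene) tuples that satisfy the gate/presence rules.
    Deliberately ignores direction and intensities: soundness of the pair set
    is what it certifies.
    """
    out = set()
    for rec in db:
        for pk, sk in ((rec.gene_a, rec.gene_b), (rec.gene_b, rec.gene_a)):
            ok_pop = (gate_keys is None or pk in gate_keys) and pop.is_present(pk)
            ok_stroma = stroma.is_present(sk)
            if ok_pop and ok_stroma:
                out.add((pk, sk))
    return out


def random_instance(rng, max_genes=50, max_pairs=25):
    """Random matcher instance: profiles with random presence and a random db."""
    n_genes = int(rng.integers(10, max_genes + 1))
    genes = [f"g{i}" for i in range(n_genes)]
    n_pairs = int(rng.integers(1, max_pairs + 1))
    records = []
    seen = set()
    for j in range(n_pairs):
        a, b = rng.choice(n_genes, size=2, replace=False)
        key = frozenset((genes[a], genes[b]))
        if key in seen:
            continue
        seen.add(key)
        records.append(
            PairRecord(
                pair_id=f"p{j}",
                gene_a=genes[a],
                gene_b=genes[b],
                role_a=str(rng.choice(["receptor", "ligand", "adhesion", "unknown"])),
                role_b=str(rng.choice(["ligand", "adhesion", "unknown"])),
            )
        )
    db = PairDatabase(records)

    def rand_profile(name):
        values = {g: float(rng.uniform(1, 5000)) for g in genes}
        present = {g: bool(rng.random() < 0.7) for g in genes}
        return make_profile(name, values, present=present)

    pop, stroma = rand_profile("pop"), rand_profile("stroma")
    gate_keys = None
    if rng.random() < 0.7:
        gate_keys = {g for g in genes if rng.random() < 0.5}
    return gate_keys, pop, stroma, db


@pytest.fixture(scope="session")
def reference_tables():
    """Matched interaction tables for all eight bundled populations."""
    return {pop: datasets.matched_table(pop) for pop in datasets.POPULATIONS}


@pytest.fixture(scope="session")
def pair_db():
    return datasets.pair_database()
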