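"""Bundled reference dataset: hematopoietic populations vs OP9 stroma.

Ships the interaction tables for eight mouse bone-marrow populations
(LT-HSC, MPP, LMPP, CLP, GMP, proB, preB, matureB) matched against the
B-lymphopoiesis-supportive OP9 stromal line, with NIH3T3 fibroblast and MC3T3
osteoblast comparator intensities.  Genes carry printed names only, so the
canonical key is the case-folded name.  Stroma-side intensities were printed
per table and differ slightly between tables for a few genes; profiles are
therefore constructed per population, never merged across tables.

Role annotations (receptor / ligand / adhesion) are standard biology for
these well-characterised partners and drive only the direction column.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

from .database import PairDatabase, PairRecord, canonical_key
from .expression import PopulationProfile
from .matching import InteractionTable, annotate_comparators, match_interactions

POPULATIONS = ("LT-HSC", "MPP", "LMPP", "CLP", "GMP", "proB", "preB", "matureB")

COMPARATOR_LABELS = ("NIH3T3", "Osteoblasts")

#: Gene role by case-folded name; names absent here default to "unknown".
_ROLE = {
    "activin receptor iia": "receptor",
    "activin receptor iib": "receptor",
    "activin a receptor, type 1": "receptor",
    "bone morphogenetic protein 4": "ligand",
    "bone morphogenetic protein 15": "ligand",
    "bone morphogenetic protein receptor, type 1a": "receptor",
    "chemokine (c-x-c motif) receptor 4": "receptor",
    "chemokine (c-x-c motif) ligand 12": "ligand",
    "chemokine (c-c motif) receptor 2": "receptor",
    "chemokine (c-c motif) receptor 9": "receptor",
    "chemokine (c-c motif) ligand 2": "ligand",
    "chemokine (c-c motif) ligand 25": "ligand",
    "epidermal growth factor receptor": "receptor",
    "epiregulin": "ligand",
    "transforming growth factor alpha": "ligand",
    "insulin-like growth factor 2": "ligand",
    "insulin-like growth factor 2 receptor": "receptor",
    "interleukin 1 receptor, type i": "receptor",
    "interleukin 1 receptor, type ii": "receptor",
    "interleukin 1 receptor antagonist": "ligand",
    "interleukin 2 receptor, gamma chain": "receptor",
    "interleukin 7": "ligand",
    "jagged 2": "ligand",
    "notch gene homolog 3 (drosophila)": "receptor",
    "oncostatin m": "ligand",
    "oncostatin m receptor": "receptor",
    "kinase insert domain protein receptor": "receptor",
    "neuropilin 1": "receptor",
    "vascular endothelial growth factor a": "ligand",
    "vascular endothelial growth factor b": "ligand",
    "platelet derived growth factor, b polypeptide": "ligand",
    "platelet derived growth factor receptor, alpha polypeptide": "receptor",
    "platelet derived growth factor receptor, beta polypeptide": "receptor",
    "tumor necrosis factor": "ligand",
    "tumor necrosis factor receptor superfamily, member 1a": "receptor",
    "tumor necrosis factor receptor superfamily, member 1b": "receptor",
    "lymphotoxin a": "ligand",
    "lymphotoxin b receptor": "receptor",
    "transforming growth factor, beta 1": "ligand",
    "transforming growth factor, beta receptor ii": "receptor",
    "transforming growth factor, beta receptor iii": "receptor",
    "integrin alpha 4": "adhesion",
    "integrin beta 1 (fibronectin receptor beta)": "adhesion",
    "integrin beta 2": "adhesion",
    "integrin beta 7": "adhesion",
    "junction adhesion molecule 2": "adhesion",
    "junction adhesion molecule 3": "adhesion",
    "vascular cell adhesion molecule 1": "adhesion",
    "neural cell adhesion molecule 1": "adhesion",
    "l1 cell adhesion molecule": "adhesion",
    "cd28 antigen": "adhesion",
    "cd80 antigen": "adhesion",
}


@lru_cache(maxsize=1)
def reference_frame() -> pd.DataFrame:
    """The raw bundled table as a DataFrame (one row per printed interaction)."""
    with resources.files("ligrec.data").joinpath("interaction_tables.tsv").open(
        "r", encoding="utf-8"
    ) as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", dtype=str)
    for col in ("pop_intensity", "stroma_intensity", "nih3t3", "osteoblasts"):
        df[col] = df[col].astype(float)
    return df


def _table_rows(population: str) -> pd.DataFrame:
    df = reference_frame()
    sub = df[df["population"] == population]
    if sub.empty:
        raise KeyError(
            f"unknown population {population!r}; available: {POPULATIONS}"
        )
    return sub


def population_profile(population: str) -> PopulationProfile:
    """Gene-level profile of one hematopoietic population (all genes present)."""
    sub = _table_rows(population)
    values, symbols = {}, {}
    for _, row in sub.iterrows():
        key = canonical_key(None, row["pop_symbol"])
        values[key] = row["pop_intensity"]
        symbols[key] = row["pop_symbol"]
    return PopulationProfile.from_values(population, values, symbols=symbols)


def stroma_profile(population: str, which: str = "OP9") -> PopulationProfile:
    """Stroma-side profile printed alongside one population's table.

    ``which`` selects OP9 (the stroma column) or one of the comparators
    (NIH3T3, Osteoblasts), all keyed by the stroma-side gene.
    """
    column = {"OP9": "stroma_intensity", "NIH3T3": "nih3t3", "Osteoblasts": "osteoblasts"}
    if which not in column:
        raise KeyError(f"unknown stromal profile {which!r}; one of {sorted(column)}")
    sub = _table_rows(population)
    values, symbols = {}, {}
    for _, row in sub.iterrows():
        key = canonical_key(None, row["stroma_symbol"])
        values[key] = row[column[which]]
        symbols[key] = row["stroma_symbol"]
    return PopulationProfile.from_values(which, values, symbols=symbols)


@lru_cache(maxsize=1)
def pair_database() -> PairDatabase:
    """Union of all unordered gene pairs across the eight bundled tables."""
    df = reference_frame()
    seen: set[frozenset[str]] = set()
    records = []
    for _, row in df.iterrows():
        key_a = canonical_key(None, row["pop_symbol"])
        key_b = canonical_key(None, row["stroma_symbol"])
        unordered = frozenset((key_a, key_b))
        if unordered in seen:
            continue
        seen.add(unordered)
        records.append(
            PairRecord(
                pair_id=f"ref{len(records) + 1:03d}",
                gene_a=key_a,
                gene_b=key_b,
                symbol_a=row["pop_symbol"],
                symbol_b=row["stroma_symbol"],
                role_a=_ROLE.get(key_a, "unknown"),
                role_b=_ROLE.get(key_b, "unknown"),
                source="bundled reference tables",
            )
        )
    return PairDatabase(records)


def matched_table(population: str, with_comparators: bool = True) -> InteractionTable:
    """Run the matcher on the bundled fixtures for one population.

    Uses presence-only gating (the printed profiles are single means, already
    the product of the original differential-expression selection) against the
    per-population OP9 profile and the union pair database.
    """
    table = match_interactions(
        None,
        population_profile(population),
        stroma_profile(population, "OP9"),
        pair_database(),
    )
    if with_comparators:
        table = annotate_comparators(
            table,
            [stroma_profile(population, label) for label in COMPARATOR_LABELS],
        )
    return table


def printed_row_set(population: str) -> set[tuple]:
    """The printed rows as comparison tuples, straight from the bundled TSV.

    Tuples are (pop_key, pop_intensity, stroma_key, stroma_intensity,
    nih3t3, osteoblasts) — independent of the matcher, for oracle checks.
    """
    sub = _table_rows(population)
    return {
        (
            canonical_key(None, row["pop_symbol"]),
            float(row["pop_intensity"]),
            canonical_key(None, row["stroma_symbol"]),
            float(row["stroma_intensity"]),
            float(row["nih3t3"]),
            float(row["osteoblasts"]),
        )
        for _, row in sub.iterrows()
    }
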