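"""Supportive-vs-non-supportive stroma candidate screen.

Nominates stromal factors that could explain a functional difference between
two stromal cell types — e.g. a bone-marrow stromal line that supports
B-lymphopoiesis versus a fibroblast line that does not.  A stroma-side gene
from a matched interaction table is nominated when it is well expressed in
the supportive stroma and enriched at least ``min_fold`` over the
non-supportive one; its cognate receptors on the target population come from
the matched population-side partners, so every candidate arrives with
receptor evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .degating import INTENSITY_FLOOR
from .errors import ValidationError
from .expression import PopulationProfile
from .matching import InteractionTable

logger = logging.getLogger(__name__)

DEFAULT_MIN_FOLD = 5.0
DEFAULT_MIN_INTENSITY = 100.0


@dataclass(frozen=True)
class CandidateFactor:
    """A nominated stromal ligand with its receptor evidence."""

    ligand: str
    ligand_symbol: str
    supportive_intensity: float
    nonsupportive_intensity: float
    fold_change: float
    receptors: tuple[tuple[str, str, float], ...]  # (gene, symbol, intensity)
    rank: int


def nominate_candidates(
    supportive: PopulationProfile,
    nonsupportive: PopulationProfile,
    target_table: InteractionTable,
    min_fold: float = DEFAULT_MIN_FOLD,
    min_intensity: float = DEFAULT_MIN_INTENSITY,
) -> list[CandidateFactor]:
    """Screen the stroma-side genes of ``target_table``.

    A gene is emitted iff its supportive-stroma intensity is at least
    ``min_intensity`` and its fold over the non-supportive stroma (denominator
    floored at 1.0; a gene absent there counts as the floor) is at least
    ``min_fold``.  Results are ranked by descending fold change, ties broken
    by ligand symbol; ranks are consecutive from 1.
    """
    if min_fold < 1:
        raise ValidationError("min_fold must be >= 1")
    if min_intensity < 0:
        raise ValidationError("min_intensity must be >= 0")
    if len(target_table) == 0:
        logger.warning("empty interaction table: no candidates to screen")
        return []

    by_gene: dict[str, list] = {}
    for row in target_table.rows:
        by_gene.setdefault(row.stroma_gene, []).append(row)

    raw = []
    for gene, rows in by_gene.items():
        if gene not in supportive.genes:
            logger.warning(
                "stroma gene %r from the table is missing from the supportive "
                "profile %r; skipped",
                gene,
                supportive.name,
            )
            continue
        supp = supportive.intensity(gene)
        nonsupp = (
            nonsupportive.intensity(gene) if gene in nonsupportive.genes else 0.0
        )
        fold = supp / max(nonsupp, INTENSITY_FLOOR)
        if supp >= min_intensity and fold >= min_fold:
            receptors = sorted(
                {
                    (r.pop_gene, r.pop_symbol, r.pop_intensity)
                    for r in rows
                },
                key=lambda t: t[1].casefold(),
            )
            raw.append(
                (
                    fold,
                    rows[0].stroma_symbol,
                    gene,
                    supp,
                    nonsupp,
                    tuple(receptors),
                )
            )

    raw.sort(key=lambda t: (-t[0], t[1].casefold()))
    return [
        CandidateFactor(
            ligand=gene,
            ligand_symbol=symbol,
            supportive_intensity=supp,
            nonsupportive_intensity=nonsupp,
            fold_change=fold,
            receptors=receptors,
            rank=i + 1,
        )
        for i, (fold, symbol, gene, supp, nonsupp, receptors) in enumerate(raw)
    ]


def write_candidates(candidates: list[CandidateFactor], path: str | Path) -> None:
    rows = [
        {
            "rank": c.rank,
            "ligand": c.ligand,
            "ligand_symbol": c.ligand_symbol,
            "supportive_intensity": c.supportive_intensity,
            "nonsupportive_intensity": c.nonsupportive_intensity,
            "fold_change": round(c.fold_change, 4),
            "receptors": ";".join(
                f"{sym}({intensity:g})" for _, sym, intensity in c.receptors
            ),
        }
        for c in candidates
    ]
    pd.DataFrame(
        rows,
        columns=[
            "rank",
            "ligand",
            "ligand_symbol",
            "supportive_intensity",
            "nonsupportive_intensity",
            "fold_change",
            "receptors",
        ],
    ).to_csv(path, sep="\t", index=False)
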