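"""Receptor–ligand matching between a population gene list and a stroma.

The core operation of the package: every database pair is tested in both
orientations — one partner must pass the population's differential-expression
gate *and* be present (detection call) in the population profile, the other
partner must be present in the stromal profile.  Matched rows carry both
sides' mean intensities and, optionally, the stromal partner's intensity in
comparator cell types (e.g. a non-supportive fibroblast line).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .database import PairDatabase, PairRecord
from .degating import DifferentialGeneList
from .errors import FormatError, LigrecError
from .expression import PopulationProfile

logger = logging.getLogger(__name__)

DIRECTIONS = (
    "pop_receptor__stroma_ligand",
    "pop_ligand__stroma_receptor",
    "adhesion_pair",
)

_BASE_COLUMNS = (
    "pop_gene",
    "pop_symbol",
    "pop_intensity",
    "stroma_gene",
    "stroma_symbol",
    "stroma_intensity",
    "direction",
)

#: Sentinel written for a comparator that lacks the gene.
NA = "NA"


@dataclass(frozen=True)
class InteractionRow:
    pop_gene: str
    pop_symbol: str
    pop_intensity: float
    stroma_gene: str
    stroma_symbol: str
    stroma_intensity: float
    direction: str
    comparators: tuple[tuple[str, float | None], ...] = ()
    autocrine: bool = False

    @property
    def pair_key(self) -> frozenset[str]:
        return frozenset((self.pop_gene, self.stroma_gene))

    def comparator(self, label: str) -> float | None:
        return dict(self.comparators).get(label)


@dataclass
class InteractionTable:
    """Deterministically ordered set of matched interaction rows."""

    population: str
    stroma: str
    rows: list[InteractionRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    @property
    def comparator_labels(self) -> tuple[str, ...]:
        labels: list[str] = []
        for row in self.rows:
            for name, _ in row.comparators:
                if name not in labels:
                    labels.append(name)
        return tuple(labels)

    def sorted(self) -> "InteractionTable":
        rows = sorted(
            self.rows,
            key=lambda r: (r.stroma_symbol.casefold(), r.pop_symbol.casefold(), r.direction),
        )
        return InteractionTable(self.population, self.stroma, rows)

    @property
    def pair_keys(self) -> set[frozenset[str]]:
        return {r.pair_key for r in self.rows}


def _direction(pop_role: str, stroma_role: str) -> str:
    if pop_role == "receptor" and stroma_role == "ligand":
        return "pop_receptor__stroma_ligand"
    if pop_role == "ligand" and stroma_role == "receptor":
        return "pop_ligand__stroma_receptor"
    return "adhesion_pair"


def match_interactions(
    gate: DifferentialGeneList | set[str] | None,
    pop: PopulationProfile,
    stroma: PopulationProfile,
    db: PairDatabase,
) -> InteractionTable:
    """Enumerate database pairs connecting ``pop`` to ``stroma``.

    A row is emitted for every pair and orientation where the population-side
    partner (i) passes ``gate`` and (ii) is present in ``pop``, while the
    stroma-side partner (iii) is present in ``stroma``.  ``gate`` may be a
    :class:`DifferentialGeneList`, a plain set of canonical gene keys, or
    ``None`` to gate on presence alone (the single-replicate workflow).
    Pairs whose partners satisfy both sides in both orientations produce two
    rows flagged as autocrine candidates rather than being suppressed.
    """
    if len(db) == 0:
        logger.warning("empty pair database: no interactions can be matched")
    gate_keys = None if gate is None else set(gate.genes if hasattr(gate, "genes") else gate)
    if gate_keys is not None:
        missing = {k for k in gate_keys if k not in pop.genes}
        if missing:
            logger.warning(
                "%d gated gene(s) missing from population profile %r (skipped)",
                len(missing),
                pop.name,
            )

    def pop_side_ok(key: str) -> bool:
        return (gate_keys is None or key in gate_keys) and pop.is_present(key)

    rows: dict[tuple[str, str, str], InteractionRow] = {}
    for rec in db:
        for pop_key, stroma_key in ((rec.gene_a, rec.gene_b), (rec.gene_b, rec.gene_a)):
            if not pop_side_ok(pop_key) or not stroma.is_present(stroma_key):
                continue
            autocrine = pop_side_ok(stroma_key) and stroma.is_present(pop_key)
            row = InteractionRow(
                pop_gene=pop_key,
                pop_symbol=pop.symbol(pop_key),
                pop_intensity=pop.intensity(pop_key),
                stroma_gene=stroma_key,
                stroma_symbol=stroma.symbol(stroma_key),
                stroma_intensity=stroma.intensity(stroma_key),
                direction=_direction(rec.role_of(pop_key), rec.role_of(stroma_key)),
                autocrine=autocrine,
            )
            rows.setdefault((row.pop_gene, row.stroma_gene, row.direction), row)
    table = InteractionTable(pop.name, stroma.name, list(rows.values()))
    return table.sorted()


def annotate_comparators(
    table: InteractionTable, comparators: Sequence[PopulationProfile]
) -> InteractionTable:
    """Attach each comparator's intensity for every row's stromal gene.

    A comparator lacking the gene contributes the ``NA`` sentinel; row count
    and order are unchanged.  Comparator labels must be unique.
    """
    labels = [c.name for c in comparators]
    if len(set(labels)) != len(labels):
        raise LigrecError(f"comparator labels are not unique: {labels}")
    if not comparators:
        return table
    new_rows = []
    for row in table.rows:
        extra = tuple(
            (
                c.name,
                c.intensity(row.stroma_gene) if row.stroma_gene in c.genes else None,
            )
            for c in comparators
        )
        new_rows.append(replace(row, comparators=row.comparators + extra))
    return InteractionTable(table.population, table.stroma, new_rows)


def _fmt(value: float) -> str:
    v = float(value)
    return str(int(v)) if v.is_integer() else repr(v)


def write_interaction_table(table: InteractionTable, path: str | Path) -> None:
    """Write the table as TSV in canonical sort order.

    Columns: the base layout plus one column per comparator label.  Output is
    byte-deterministic for identical inputs.
    """
    table = table.sorted()
    labels = table.comparator_labels
    lines = ["\t".join(_BASE_COLUMNS + labels)]
    for row in table.rows:
        cells = [
            row.pop_gene,
            row.pop_symbol,
            _fmt(row.pop_intensity),
            row.stroma_gene,
            row.stroma_symbol,
            _fmt(row.stroma_intensity),
            row.direction,
        ]
        comp = dict(row.comparators)
        for label in labels:
            v = comp.get(label)
            cells.append(NA if v is None else _fmt(v))
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_interaction_table(
    path: str | Path, population: str = "", stroma: str = ""
) -> InteractionTable:
    """Read a TSV written by :func:`write_interaction_table`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in _BASE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")
    labels = [c for c in df.columns if c not in _BASE_COLUMNS]
    rows = []
    for _, r in df.iterrows():
        comps = tuple(
            (label, None if str(r[label]) == NA else float(r[label]))
            for label in labels
        )
        rows.append(
            InteractionRow(
                pop_gene=str(r["pop_gene"]),
                pop_symbol=str(r["pop_symbol"]),
                pop_intensity=float(r["pop_intensity"]),
                stroma_gene=str(r["stroma_gene"]),
                stroma_symbol=str(r["stroma_symbol"]),
                stroma_intensity=float(r["stroma_intensity"]),
                direction=str(r["direction"]),
                comparators=comps,
            )
        )
    return InteractionTable(population or path.stem, stroma, rows)
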