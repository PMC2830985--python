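"""Curated receptor–ligand pair database.

The database is the atom of the whole analysis: a flat table of gene pairs
whose protein products form a signaling or adhesion interface.  Genes are
keyed by their numeric Entrez (locus link) identifier when available; when a
record carries only a gene symbol, the case-folded symbol serves as the key.
Pairs are stored in file order, directed as written, but deduplicated on the
unordered key — direction semantics are applied at match time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .errors import FormatError, RowError, ValidationError

logger = logging.getLogger(__name__)

#: Recognised role annotations for a pair member.
ROLES = ("receptor", "ligand", "adhesion", "unknown")

PAIR_TABLE_COLUMNS = (
    "pair_id",
    "gene_a",
    "symbol_a",
    "role_a",
    "gene_b",
    "symbol_b",
    "role_b",
    "source",
)


def canonical_key(gene: str | None, symbol: str | None = None) -> str:
    """Canonical gene key: Entrez identifier, else case-folded symbol.

    Returns an empty string when neither field carries information; callers
    decide whether that is an error.
    """
    g = (str(gene) if gene is not None else "").strip()
    if g and g.lower() not in ("na", "nan", "none"):
        return g
    s = (str(symbol) if symbol is not None else "").strip()
    if not s or s.lower() in ("na", "nan", "none"):
        return ""
    logger.debug("no numeric identifier for %r; keying on case-folded symbol", s)
    return s.casefold()


@dataclass(frozen=True)
class PairRecord:
    """One curated gene pair (receptor–ligand or adhesion partners)."""

    pair_id: str
    gene_a: str
    gene_b: str
    symbol_a: str = ""
    symbol_b: str = ""
    role_a: str = "unknown"
    role_b: str = "unknown"
    source: str = ""

    def __post_init__(self) -> None:
        if self.role_a not in ROLES or self.role_b not in ROLES:
            raise ValidationError(
                f"pair {self.pair_id!r}: roles must be one of {ROLES}, "
                f"got ({self.role_a!r}, {self.role_b!r})"
            )

    @property
    def unordered_key(self) -> frozenset[str]:
        return frozenset((self.gene_a, self.gene_b))

    def partner_of(self, gene: str) -> str:
        if gene == self.gene_a:
            return self.gene_b
        if gene == self.gene_b:
            return self.gene_a
        raise KeyError(gene)

    def role_of(self, gene: str) -> str:
        if gene == self.gene_a:
            return self.role_a
        if gene == self.gene_b:
            return self.role_b
        raise KeyError(gene)

    def validate(self) -> None:
        if not self.gene_a or not self.gene_b:
            raise ValidationError(f"pair {self.pair_id!r}: empty gene identifier")
        if self.gene_a == self.gene_b:
            raise ValidationError(
                f"pair {self.pair_id!r}: partners are identical under the "
                f"canonical key ({self.gene_a!r})"
            )
        if self.role_a == self.role_b == "receptor":
            raise ValidationError(
                f"pair {self.pair_id!r}: both partners annotated as receptor"
            )


class PairDatabase:
    """Validated, order-preserving collection of :class:`PairRecord`.

    Maintains an index from canonical gene key to the records containing it,
    covering every gene in the records and nothing else.
    """

    def __init__(self, records: Iterable[PairRecord]):
        self._records: list[PairRecord] = []
        self._index: dict[str, list[PairRecord]] = {}
        seen: dict[frozenset[str], PairRecord] = {}
        for rec in records:
            rec.validate()
            key = rec.unordered_key
            if key in seen:
                logger.warning(
                    "duplicate pair %s-%s (id %r collapses into %r)",
                    rec.symbol_a or rec.gene_a,
                    rec.symbol_b or rec.gene_b,
                    rec.pair_id,
                    seen[key].pair_id,
                )
                continue
            seen[key] = rec
            self._records.append(rec)
            self._index.setdefault(rec.gene_a, []).append(rec)
            self._index.setdefault(rec.gene_b, []).append(rec)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[PairRecord]:
        return iter(self._records)

    @property
    def records(self) -> tuple[PairRecord, ...]:
        return tuple(self._records)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self._index)

    def pairs_for_gene(self, gene: str) -> tuple[PairRecord, ...]:
        """All records whose either partner matches ``gene``.

        The query is canonicalised the same way record keys are, so symbol
        queries in any letter case hit symbol-keyed records.  Unknown genes
        yield an empty tuple.
        """
        key = canonical_key(None, gene) or canonical_key(gene)
        hits = self._index.get(gene) or self._index.get(key) or []
        return tuple(hits)

    def validated(self) -> "PairDatabase":
        """Re-validate; a no-op on an already-valid database (idempotent)."""
        return PairDatabase(self._records)


def pairs_for_gene(db: PairDatabase, gene: str) -> tuple[PairRecord, ...]:
    """Functional alias for :meth:`PairDatabase.pairs_for_gene`."""
    return db.pairs_for_gene(gene)


def load_pair_table(path: str | Path) -> PairDatabase:
    """Read a tab-separated pair table into a validated :class:`PairDatabase`.

    The file is UTF-8, tab-separated, with a header row; lines starting with
    ``#`` are ignored.  Only the gene identifier columns (``gene_a``/``gene_b``
    or the ``symbol_a``/``symbol_b`` fallbacks) are required.  Duplicate
    unordered pairs are collapsed with a logged warning; row order is
    preserved.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    has_gene = {"gene_a", "gene_b"}.issubset(df.columns)
    has_symbol = {"symbol_a", "symbol_b"}.issubset(df.columns)
    if not (has_gene or has_symbol):
        missing = [c for c in ("gene_a", "gene_b") if c not in df.columns]
        raise FormatError(
            f"{path.name}: missing required column(s) {missing} "
            "(or symbol_a/symbol_b fallbacks)"
        )

    def col(row: pd.Series, name: str) -> str:
        return str(row[name]).strip() if name in df.columns else ""

    records = []
    for i, (_, row) in enumerate(df.iterrows()):
        sym_a, sym_b = col(row, "symbol_a"), col(row, "symbol_b")
        key_a = canonical_key(col(row, "gene_a"), sym_a)
        key_b = canonical_key(col(row, "gene_b"), sym_b)
        # pandas drops commented lines before numbering, so report the data
        # row index (header-relative), the stable reference for the caller.
        if not key_a or not key_b:
            raise RowError("empty gene identifier field", line=i + 2)
        records.append(
            PairRecord(
                pair_id=col(row, "pair_id") or f"pair{i + 1:04d}",
                gene_a=key_a,
                gene_b=key_b,
                symbol_a=sym_a or col(row, "gene_a"),
                symbol_b=sym_b or col(row, "gene_b"),
                role_a=col(row, "role_a") or "unknown",
                role_b=col(row, "role_b") or "unknown",
                source=col(row, "source"),
            )
        )
    return PairDatabase(records)


def write_pair_table(db: PairDatabase, path: str | Path) -> None:
    """Write the database back to the tab-separated pair-table format."""
    rows = [
        {
            "pair_id": r.pair_id,
            "gene_a": r.gene_a,
            "symbol_a": r.symbol_a,
            "role_a": r.role_a,
            "gene_b": r.gene_b,
            "symbol_b": r.symbol_b,
            "role_b": r.role_b,
            "source": r.source,
        }
        for r in db
    ]
    pd.DataFrame(rows, columns=list(PAIR_TABLE_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )
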