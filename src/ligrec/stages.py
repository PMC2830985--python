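"""Stage dynamics: ubiquitous vs stage-restricted interaction pairs.

Given matched interaction tables for an ordered developmental series of
populations (default: long-term stem cells through mature B cells), each
unordered gene pair is classified *ubiquitous* when it occurs at every stage
of the series and *restricted* otherwise.  Direction is collapsed for
staging: the claim is about the partner pair, not about which side carries
the receptor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigurationError
from .matching import InteractionTable

#: Default developmental series (flattened; GMP branches off the B path).
DEFAULT_SERIES = (
    "LT-HSC",
    "MPP",
    "LMPP",
    "CLP",
    "GMP",
    "proB",
    "preB",
    "matureB",
)


@dataclass
class PairStageMap:
    """Occurrence of each unordered pair across the population series."""

    series: tuple[str, ...]
    occurrence: dict[frozenset[str], set[str]] = field(default_factory=dict)
    symbols: dict[frozenset[str], tuple[str, str]] = field(default_factory=dict)

    def classification(self, pair: frozenset[str]) -> str:
        return (
            "ubiquitous"
            if self.occurrence[pair] == set(self.series)
            else "restricted"
        )

    @property
    def classes(self) -> dict[frozenset[str], str]:
        return {pair: self.classification(pair) for pair in self.occurrence}

    def pairs_in(self, population: str) -> set[frozenset[str]]:
        return {p for p, occ in self.occurrence.items() if population in occ}


def classify_pairs(
    tables: Iterable[InteractionTable],
    series: Sequence[str] = DEFAULT_SERIES,
) -> PairStageMap:
    """Build the occurrence map and ubiquitous/restricted classes.

    Each table's population label must appear in ``series`` and no two tables
    may share a label.  Pairs absent from every table are absent from the map.
    """
    series = tuple(series)
    if len(set(series)) != len(series):
        raise ConfigurationError(f"series has repeated labels: {series}")
    result = PairStageMap(series=series)
    seen_labels: set[str] = set()
    for table in tables:
        label = table.population
        if label not in series:
            raise ConfigurationError(
                f"table population {label!r} is not in the series {series}"
            )
        if label in seen_labels:
            raise ConfigurationError(f"population {label!r} supplied twice")
        seen_labels.add(label)
        for row in table.rows:
            pair = row.pair_key
            result.occurrence.setdefault(pair, set()).add(label)
            result.symbols.setdefault(
                pair, tuple(sorted((row.pop_symbol, row.stroma_symbol)))
            )
    return result


@dataclass(frozen=True)
class StageTransition:
    from_population: str
    to_population: str
    gained: tuple[frozenset[str], ...]
    lost: tuple[frozenset[str], ...]


def stage_transition_report(
    stage_map: PairStageMap, path: Sequence[str] | None = None
) -> list[StageTransition]:
    """Gained and lost pairs along consecutive populations of a linear path.

    ``path`` defaults to the map's full series; it must be a sequence of at
    least two series labels.  For each adjacent (a, b), ``gained`` holds pairs
    present at b but not a, ``lost`` the reverse, so |gained| − |lost| equals
    the difference in per-population pair counts.
    """
    labels = tuple(path) if path is not None else stage_map.series
    if len(labels) < 2:
        raise ConfigurationError("a transition report needs a path of length >= 2")
    for label in labels:
        if label not in stage_map.series:
            raise ConfigurationError(f"{label!r} is not in the series")

    def sort_key(pair: frozenset[str]):
        return stage_map.symbols.get(pair, tuple(sorted(pair)))

    report = []
    for a, b in zip(labels, labels[1:]):
        in_a, in_b = stage_map.pairs_in(a), stage_map.pairs_in(b)
        report.append(
            StageTransition(
                from_population=a,
                to_population=b,
                gained=tuple(sorted(in_b - in_a, key=sort_key)),
                lost=tuple(sorted(in_a - in_b, key=sort_key)),
            )
        )
    return report


def write_stage_map(stage_map: PairStageMap, path: str | Path) -> None:
    """TSV with columns gene_a, gene_b, n_populations, populations, class."""
    rows = []
    for pair in stage_map.occurrence:
        sym = stage_map.symbols.get(pair, tuple(sorted(pair)))
        occ = [s for s in stage_map.series if s in stage_map.occurrence[pair]]
        rows.append(
            {
                "gene_a": sym[0],
                "gene_b": sym[1],
                "n_populations": len(occ),
                "populations": ",".join(occ),
                "class": stage_map.classification(pair),
            }
        )
    rows.sort(key=lambda r: (r["gene_a"].casefold(), r["gene_b"].casefold()))
    pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "n_populations", "populations", "class"]
    ).to_csv(path, sep="\t", index=False)
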