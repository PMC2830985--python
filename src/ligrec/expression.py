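"""Expression-table parsing and probe-set to gene aggregation.

Input profiles are assumed RMA-normalized, on the *linear* intensity scale,
with Affymetrix-style present/marginal/absent (P/M/A) detection calls per
replicate array.  Probe sets are collapsed to one value per gene before any
matching; by default the probe set with the largest mean intensity represents
the gene, and a gene counts as present when its representing probe set is
called P in at least one replicate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .database import canonical_key
from .errors import FormatError, RowError, ValidationError

logger = logging.getLogger(__name__)

CALLS = ("P", "M", "A")

_FIXED_COLUMNS = ("probe_set", "accession", "description", "gene", "symbol")


@dataclass(frozen=True)
class ProbeRecord:
    """One probe set's measurements across replicate arrays."""

    probe_set: str
    accession: str
    description: str
    gene: str
    symbol: str
    intensities: tuple[float, ...]
    calls: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.intensities) != len(self.calls) or not self.intensities:
            raise ValidationError(
                f"probe set {self.probe_set!r}: intensities and calls must "
                "have equal, nonzero length"
            )
        for v in self.intensities:
            if not math.isfinite(v) or v < 0:
                raise ValidationError(
                    f"probe set {self.probe_set!r}: intensity {v!r} is not a "
                    "finite non-negative number"
                )
        for c in self.calls:
            if c not in CALLS:
                raise ValidationError(
                    f"probe set {self.probe_set!r}: call {c!r} not in {CALLS}"
                )

    @property
    def mean_intensity(self) -> float:
        return float(np.mean(self.intensities))

    @property
    def key(self) -> str:
        return canonical_key(self.gene, self.symbol)


@dataclass(frozen=True)
class GeneExpression:
    """Gene-level expression state inside one population."""

    key: str
    symbol: str
    mean_intensity: float
    replicate_intensities: tuple[float, ...]
    present: bool


@dataclass
class PopulationProfile:
    """Gene-level expression of one cell population.

    ``genes`` maps the canonical gene key to a :class:`GeneExpression`; keys
    are unique by construction after aggregation.
    """

    name: str
    genes: dict[str, GeneExpression] = field(default_factory=dict)

    def __contains__(self, key: str) -> bool:
        return key in self.genes

    def __len__(self) -> int:
        return len(self.genes)

    def intensity(self, key: str) -> float:
        return self.genes[key].mean_intensity

    def is_present(self, key: str) -> bool:
        g = self.genes.get(key)
        return g is not None and g.present

    def symbol(self, key: str) -> str:
        g = self.genes.get(key)
        return g.symbol if g is not None else key

    @property
    def n_replicates(self) -> int:
        if not self.genes:
            return 0
        return min(len(g.replicate_intensities) for g in self.genes.values())

    @classmethod
    def from_values(
        cls,
        name: str,
        values: Mapping[str, float],
        symbols: Mapping[str, str] | None = None,
        present: Mapping[str, bool] | None = None,
    ) -> "PopulationProfile":
        """Build a single-replicate profile from gene → intensity values.

        Convenience constructor for printed per-gene means; every gene is
        present unless stated otherwise.
        """
        genes = {}
        for key, v in values.items():
            genes[key] = GeneExpression(
                key=key,
                symbol=(symbols or {}).get(key, key),
                mean_intensity=float(v),
                replicate_intensities=(float(v),),
                present=(present or {}).get(key, True),
            )
        return cls(name=name, genes=genes)


def read_expression_table(path: str | Path) -> list[ProbeRecord]:
    """Parse a probe-level expression TSV.

    Expected columns: ``probe_set, accession, description, gene, symbol,
    intensity_1..intensity_k, call_1..call_k`` with k ≥ 1.  Lines starting
    with ``#`` are ignored.  Ragged intensity/call column sets, non-numeric
    intensities, and call tokens outside {P, M, A} (case-insensitive) are
    rejected with the offending line number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in _FIXED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")
    int_cols = sorted(
        (c for c in df.columns if c.startswith("intensity_")),
        key=lambda c: int(c.split("_")[1]),
    )
    call_cols = sorted(
        (c for c in df.columns if c.startswith("call_")),
        key=lambda c: int(c.split("_")[1]),
    )
    if not int_cols:
        raise FormatError(f"{path.name}: no intensity_<k> columns found")
    if len(int_cols) != len(call_cols):
        raise FormatError(
            f"{path.name}: {len(int_cols)} intensity column(s) but "
            f"{len(call_cols)} call column(s)"
        )

    records = []
    for i, (_, row) in enumerate(df.iterrows()):
        line = i + 2  # 1-based, counting the header
        intensities = []
        for c in int_cols:
            raw = str(row[c]).strip()
            try:
                v = float(raw)
            except ValueError:
                raise RowError(f"non-numeric intensity {raw!r} in {c}", line)
            intensities.append(v)
        calls = []
        for c in call_cols:
            token = str(row[c]).strip().upper()
            if token not in CALLS:
                raise RowError(f"call {row[c]!r} in {c} not one of P/M/A", line)
            calls.append(token)
        try:
            records.append(
                ProbeRecord(
                    probe_set=str(row["probe_set"]).strip(),
                    accession=str(row["accession"]).strip(),
                    description=str(row["description"]).strip(),
                    gene=str(row["gene"]).strip(),
                    symbol=str(row["symbol"]).strip(),
                    intensities=tuple(intensities),
                    calls=tuple(calls),
                )
            )
        except ValidationError as exc:
            raise RowError(str(exc), line) from exc
    return records


def _is_present(
    calls: Iterable[str], rule: str = "any", marginal_as_present: bool = False
) -> bool:
    ok = {"P", "M"} if marginal_as_present else {"P"}
    hits = [c in ok for c in calls]
    if rule == "any":
        return any(hits)
    if rule == "all":
        return all(hits)
    raise ValidationError(f"unknown presence rule {rule!r}")


def aggregate_probesets(
    records: Iterable[ProbeRecord],
    name: str,
    method: str = "max_mean",
    presence_rule: str = "any",
    marginal_as_present: bool = False,
) -> PopulationProfile:
    """Collapse probe-set records to a gene-level :class:`PopulationProfile`.

    ``max_mean`` (default) lets the probe set with the largest mean intensity
    represent the gene — its replicate values and calls carry over.
    ``mean_of_means`` averages the probe-set means instead; the gene is
    present when any of its probe sets qualifies.  A gene is present when the
    deciding probe set is called P in at least one replicate (``presence_rule
    = "any"``; set ``"all"`` to require every replicate).  Marginal calls
    count as absent unless ``marginal_as_present``.
    """
    if method not in ("max_mean", "mean_of_means"):
        raise ValidationError(f"unknown aggregation method {method!r}")
    by_gene: dict[str, list[ProbeRecord]] = {}
    for rec in records:
        key = rec.key
        if not key:
            logger.warning("probe set %s has no gene identifier; skipped", rec.probe_set)
            continue
        by_gene.setdefault(key, []).append(rec)

    genes: dict[str, GeneExpression] = {}
    for key, recs in by_gene.items():
        if method == "max_mean":
            best = max(recs, key=lambda r: r.mean_intensity)
            genes[key] = GeneExpression(
                key=key,
                symbol=best.symbol or best.gene,
                mean_intensity=best.mean_intensity,
                replicate_intensities=best.intensities,
                present=_is_present(best.calls, presence_rule, marginal_as_present),
            )
        else:
            means = np.array([r.mean_intensity for r in recs])
            reps = np.mean([r.intensities for r in recs], axis=0)
            genes[key] = GeneExpression(
                key=key,
                symbol=recs[0].symbol or recs[0].gene,
                mean_intensity=float(means.mean()),
                replicate_intensities=tuple(float(v) for v in reps),
                present=any(
                    _is_present(r.calls, presence_rule, marginal_as_present)
                    for r in recs
                ),
            )
    return PopulationProfile(name=name, genes=genes)


def read_profile(
    path: str | Path, name: str | None = None, **aggregate_kwargs
) -> PopulationProfile:
    """Read an expression TSV and aggregate it in one step."""
    path = Path(path)
    records = read_expression_table(path)
    return aggregate_probesets(records, name or path.stem, **aggregate_kwargs)


def write_profile_table(profile: PopulationProfile, path: str | Path) -> None:
    """Write a gene-level profile in the probe-level TSV layout.

    Each gene becomes one pseudo probe set (named after the gene key) so the
    file round-trips through :func:`read_expression_table` /
    :func:`aggregate_probesets`.  Calls are P when the gene is present, A
    otherwise, for every replicate.
    """
    genes = sorted(profile.genes.values(), key=lambda g: g.key)
    k = max((len(g.replicate_intensities) for g in genes), default=1)
    rows = []
    for g in genes:
        if len(g.replicate_intensities) != k:
            raise ValidationError(
                f"{profile.name}: ragged replicate counts cannot be serialised"
            )
        row = {
            "probe_set": f"{g.key}_at",
            "accession": "",
            "description": "",
            "gene": g.key,
            "symbol": g.symbol,
        }
        for j, v in enumerate(g.replicate_intensities, start=1):
            row[f"intensity_{j}"] = repr(float(v))
            row[f"call_{j}"] = "P" if g.present else "A"
        rows.append(row)
    cols = list(_FIXED_COLUMNS)
    for j in range(1, k + 1):
        cols += [f"intensity_{j}", f"call_{j}"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
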