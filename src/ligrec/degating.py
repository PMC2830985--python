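"""Differential-expression gating of a population against a stromal reference.

The matcher consumes, per hematopoietic population, the list of genes that
differ from the stromal reference at p < alpha (default 0.01, uncorrected).
Tests run on log2(intensity + 1).  Two tests are offered: a plain Welch t
(default) and a moderated t that shrinks per-gene variances toward a pooled
empirical-Bayes prior, useful at the 2–3 replicates typical of microarray
designs.  When replicates are unavailable (e.g. profiles built from printed
per-gene means) a fold-change-only gate stands in.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import ValidationError
from .expression import PopulationProfile

logger = logging.getLogger(__name__)

#: Variance floor guarding zero within-group variance.
VAR_FLOOR = 1e-8

#: Linear-intensity floor used as fold-change denominator.
INTENSITY_FLOOR = 1.0

DIRECTIONS = ("up_in_population", "up_in_reference")


@dataclass(frozen=True)
class DifferentialEntry:
    p_value: float
    log2_fold_change: float
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"unknown direction {self.direction!r}")


@dataclass
class DifferentialGeneList:
    """Genes passing the gate, with test statistics and direction."""

    population: str
    reference: str
    alpha: float
    entries: dict[str, DifferentialEntry] = field(default_factory=dict)
    symbols: dict[str, str] = field(default_factory=dict)

    def __contains__(self, key: str) -> bool:
        return key in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> set[str]:
        return set(self.entries)


def _log2p1(values) -> np.ndarray:
    return np.log2(np.asarray(values, dtype=float) + 1.0)


def welch_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch t-test; returns (t, p).

    Written out explicitly (rather than delegated) so the variance floor is
    applied; cross-checked against scipy in the test suite.
    """
    n1, n2 = len(x), len(y)
    v1 = max(float(np.var(x, ddof=1)), VAR_FLOOR)
    v2 = max(float(np.var(y, ddof=1)), VAR_FLOOR)
    se2 = v1 / n1 + v2 / n2
    t = (float(np.mean(x)) - float(np.mean(y))) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return t, p


def _fit_f_dist_prior(s2: np.ndarray, df_resid: float) -> tuple[float, float]:
    """Moment fit of a scaled inverse-chi-square prior to sample variances.

    Matches mean and variance of log(s²) using digamma/trigamma, the standard
    empirical-Bayes recipe for variance shrinkage.  Returns (d0, s0²); d0 may
    be ``inf`` when the observed spread is no wider than sampling noise alone,
    in which case all variances shrink to the common value.
    """
    z = np.log(np.maximum(s2, VAR_FLOOR))
    e = z - special.digamma(df_resid / 2.0) + math.log(df_resid / 2.0)
    n = len(z)
    mean_e = float(np.mean(e))
    var_e = float(np.sum((e - mean_e) ** 2) / max(n - 1, 1))
    excess = var_e - float(special.polygamma(1, df_resid / 2.0))
    if excess <= 0:
        return math.inf, math.exp(mean_e)

    # invert trigamma(d0/2) = excess by Newton iteration on y = d0/2
    y = 0.5 + 1.0 / excess
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        delta = tri * (1.0 - tri / excess) / float(special.polygamma(2, y))
        y += delta
        if abs(delta) < 1e-10 * y:
            break
    d0 = 2.0 * y
    s0_sq = math.exp(mean_e + special.digamma(y) - math.log(y))
    return d0, s0_sq


def _moderated_t(
    xs: np.ndarray, ys: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised moderated t over genes (rows) with pooled two-group variance."""
    n1, n2 = xs.shape[1], ys.shape[1]
    df_resid = n1 + n2 - 2
    pooled = (
        np.var(xs, axis=1, ddof=1) * (n1 - 1) + np.var(ys, axis=1, ddof=1) * (n2 - 1)
    ) / df_resid
    d0, s0_sq = _fit_f_dist_prior(pooled, df_resid)
    if math.isinf(d0):
        s2_post = np.full_like(pooled, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df_resid * pooled) / (d0 + df_resid)
        df_total = d0 + df_resid
    s2_post = np.maximum(s2_post, VAR_FLOOR)
    t = (xs.mean(axis=1) - ys.mean(axis=1)) / np.sqrt(s2_post * (1 / n1 + 1 / n2))
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return t, p


def differential_genes(
    pop: PopulationProfile,
    ref: PopulationProfile,
    alpha: float = 0.01,
    test: str = "welch_t",
    adjust: str | None = None,
) -> DifferentialGeneList:
    """Per-gene two-sample test of ``pop`` vs ``ref`` on log2(intensity + 1).

    Gene universes are intersected before testing.  Genes with p < ``alpha``
    are retained; no multiple-testing correction is applied unless ``adjust =
    "bh"`` (Benjamini–Hochberg).  Both profiles need at least two replicates
    per gene; with single-replicate profiles use :func:`fold_change_gate`.
    """
    if test not in ("welch_t", "moderated_t"):
        raise ValidationError(f"unknown test {test!r}")
    if adjust not in (None, "bh"):
        raise ValidationError(f"unknown adjustment {adjust!r}")
    common = sorted(set(pop.genes) & set(ref.genes))
    result = DifferentialGeneList(
        population=pop.name, reference=ref.name, alpha=alpha
    )
    if not common:
        return result
    xs, ys, keys = [], [], []
    for key in common:
        x = pop.genes[key].replicate_intensities
        y = ref.genes[key].replicate_intensities
        if len(x) < 2 or len(y) < 2:
            raise ValidationError(
                f"gene {key!r} has fewer than 2 replicates in one group; "
                "replicate-based tests need >=2 per side — use "
                "fold_change_gate for single-replicate profiles"
            )
        xs.append(_log2p1(x))
        ys.append(_log2p1(y))
        keys.append(key)
    xs, ys = np.array(xs), np.array(ys)

    if test == "welch_t":
        pvals = np.array([welch_t_test(x, y)[1] for x, y in zip(xs, ys)])
    else:
        _, pvals = _moderated_t(xs, ys)
    if adjust == "bh":
        pvals = _benjamini_hochberg(pvals)
    lfc = xs.mean(axis=1) - ys.mean(axis=1)

    for key, p, f in zip(keys, pvals, lfc):
        if p < alpha:
            result.entries[key] = DifferentialEntry(
                p_value=float(p),
                log2_fold_change=float(f),
                direction="up_in_population" if f >= 0 else "up_in_reference",
            )
            result.symbols[key] = pop.genes[key].symbol
    return result


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone step-up)."""
    n = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def fold_change_gate(
    pop: PopulationProfile,
    ref: PopulationProfile,
    min_fold: float,
) -> DifferentialGeneList:
    """Fold-change-only gate for single-replicate profiles.

    Retains genes whose linear-intensity ratio in either direction is at
    least ``min_fold``; denominators are floored at 1.0 so a silent reference
    gene cannot blow up the ratio.  p-values are recorded as the absent-marker
    value 1.0.
    """
    if min_fold < 1:
        raise ValidationError("min_fold must be >= 1")
    result = DifferentialGeneList(
        population=pop.name, reference=ref.name, alpha=1.0
    )
    for key in sorted(set(pop.genes) & set(ref.genes)):
        a = pop.genes[key].mean_intensity
        b = ref.genes[key].mean_intensity
        ratio_up = a / max(b, INTENSITY_FLOOR)
        ratio_dn = b / max(a, INTENSITY_FLOOR)
        if max(ratio_up, ratio_dn) >= min_fold:
            lfc = math.log2(max(a, INTENSITY_FLOOR)) - math.log2(
                max(b, INTENSITY_FLOOR)
            )
            result.entries[key] = DifferentialEntry(
                p_value=1.0,
                log2_fold_change=lfc,
                direction="up_in_population" if lfc >= 0 else "up_in_reference",
            )
            result.symbols[key] = pop.genes[key].symbol
    return result


def write_gene_list(gate: DifferentialGeneList, path: str | Path) -> None:
    rows = [
        {
            "gene": key,
            "symbol": gate.symbols.get(key, key),
            "p_value": entry.p_value,
            "log2_fold_change": entry.log2_fold_change,
            "direction": entry.direction,
        }
        for key, entry in sorted(gate.entries.items())
    ]
    pd.DataFrame(
        rows, columns=["gene", "symbol", "p_value", "log2_fold_change", "direction"]
    ).to_csv(path, sep="\t", index=False)


def read_gene_list(
    path: str | Path, population: str = "", reference: str = "", alpha: float = 1.0
) -> DifferentialGeneList:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    gate = DifferentialGeneList(population=population, reference=reference, alpha=alpha)
    for _, row in df.iterrows():
        key = str(row["gene"]).strip()
        gate.entries[key] = DifferentialEntry(
            p_value=float(row.get("p_value", 1.0) or 1.0),
            log2_fold_change=float(row.get("log2_fold_change", 0.0) or 0.0),
            direction=str(row.get("direction", "up_in_population"))
            or "up_in_population",
        )
        gate.symbols[key] = str(row.get("symbol", key)) or key
    return gate
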