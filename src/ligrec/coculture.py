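"""Stromal response to co-culture: expression filter and 2^ΔΔCt quantification.

Two analyses of how a stromal cell responds to contact with hematopoietic
cells.  The expression filter retains genes whose level exceeds a floor and
whose fold change between co-cultured and control conditions passes a
threshold (plus a p-value clause when replicates exist).  The qPCR side
implements relative quantification: ΔΔCt is the difference-of-differences of
threshold cycles between the gene of interest and a reference gene (HPRT by
default) across control and sample, and fold change is 2^ΔΔCt.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .degating import (
    INTENSITY_FLOOR,
    DifferentialEntry,
    DifferentialGeneList,
    welch_t_test,
    _log2p1,
)
from .errors import ValidationError
from .expression import PopulationProfile

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ResponseFilterConfig:
    """Thresholds for the co-culture response filter.

    ``min_level`` is on the linear intensity scale and must be cleared by the
    *maximum* of the two conditions, so strongly induced genes that start near
    zero are kept.  Fold denominators are floored at 1.0.
    """

    min_level: float = 100.0
    min_fold: float = 5.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.min_level < 0:
            raise ValidationError("min_level must be >= 0")
        if self.min_fold < 1:
            raise ValidationError("min_fold must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ValidationError("alpha must be in (0, 1]")


def response_genes(
    cocultured: PopulationProfile,
    control: PopulationProfile,
    config: ResponseFilterConfig = ResponseFilterConfig(),
) -> DifferentialGeneList:
    """Genes whose expression responds to co-culture.

    A gene is retained when max(intensity across the two conditions) exceeds
    ``min_level``, the linear fold change in either direction (denominators
    floored at 1.0) is at least ``min_fold``, and — when both profiles carry
    at least two replicates — a Welch t-test on log2(x+1) gives p < ``alpha``.
    With single-replicate profiles the p clause is skipped with a logged
    notice.  Direction ``up_in_population`` means induced in co-culture.
    """
    common = sorted(set(cocultured.genes) & set(control.genes))
    result = DifferentialGeneList(
        population=cocultured.name, reference=control.name, alpha=config.alpha
    )
    have_replicates = (
        cocultured.n_replicates >= 2 and control.n_replicates >= 2
    )
    if not have_replicates:
        logger.info(
            "single-replicate profile(s): the p < %g clause is skipped",
            config.alpha,
        )
    for key in common:
        a = cocultured.genes[key].mean_intensity
        b = control.genes[key].mean_intensity
        if max(a, b) <= config.min_level:
            continue
        fold = max(
            a / max(b, INTENSITY_FLOOR),
            b / max(a, INTENSITY_FLOOR),
        )
        if fold < config.min_fold:
            continue
        p = 1.0
        if have_replicates:
            _, p = welch_t_test(
                _log2p1(cocultured.genes[key].replicate_intensities),
                _log2p1(control.genes[key].replicate_intensities),
            )
            if p >= config.alpha:
                continue
        lfc = math.log2(max(a, INTENSITY_FLOOR)) - math.log2(
            max(b, INTENSITY_FLOOR)
        )
        result.entries[key] = DifferentialEntry(
            p_value=p,
            log2_fold_change=lfc,
            direction="up_in_population" if lfc >= 0 else "up_in_reference",
        )
        result.symbols[key] = cocultured.genes[key].symbol
    return result


@dataclass(frozen=True)
class DdCtMeasurement:
    """One relative-quantification measurement.

    ``ddct = (ct_goi_control − ct_ref_control) − (ct_goi_sample −
    ct_ref_sample)`` and ``fold_change = 2**ddct``: a gene needing fewer
    cycles in the sample than its reference predicts is induced (fold > 1).
    """

    gene: str
    ct_goi_sample: float
    ct_ref_sample: float
    ct_goi_control: float
    ct_ref_control: float
    ddct: float
    fold_change: float
    reference_gene: str = "HPRT"


def ddct_fold_change(
    gene: str,
    ct_goi_sample: float,
    ct_ref_sample: float,
    ct_goi_control: float,
    ct_ref_control: float,
    reference_gene: str = "HPRT",
) -> DdCtMeasurement:
    """Compute ΔΔCt and its 2^ΔΔCt fold change.

    Each gene-of-interest Ct is normalized against the reference gene's Ct
    from the *same* cDNA (sample with sample, control with control).  All four
    Cts equal gives exactly fold 1.0; raising ``ct_goi_sample`` by one cycle
    halves the fold.
    """
    cts = {
        "ct_goi_sample": ct_goi_sample,
        "ct_ref_sample": ct_ref_sample,
        "ct_goi_control": ct_goi_control,
        "ct_ref_control": ct_ref_control,
    }
    for name, v in cts.items():
        if not math.isfinite(float(v)):
            raise ValidationError(f"{name} is not finite: {v!r}")
    ddct = (float(ct_goi_control) - float(ct_ref_control)) - (
        float(ct_goi_sample) - float(ct_ref_sample)
    )
    return DdCtMeasurement(
        gene=gene,
        ct_goi_sample=float(ct_goi_sample),
        ct_ref_sample=float(ct_ref_sample),
        ct_goi_control=float(ct_goi_control),
        ct_ref_control=float(ct_ref_control),
        ddct=ddct,
        fold_change=2.0**ddct,
        reference_gene=reference_gene,
    )


def read_ddct_table(
    path: str | Path, reference_gene: str = "HPRT"
) -> list[DdCtMeasurement]:
    """Batch ΔΔCt from a CSV with columns gene, ct_goi_sample, ct_ref_sample,
    ct_goi_control, ct_ref_control."""
    df = pd.read_csv(path, comment="#")
    required = [
        "gene",
        "ct_goi_sample",
        "ct_ref_sample",
        "ct_goi_control",
        "ct_ref_control",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"missing column(s) {missing} in {Path(path).name}")
    return [
        ddct_fold_change(
            gene=str(row["gene"]),
            ct_goi_sample=float(row["ct_goi_sample"]),
            ct_ref_sample=float(row["ct_ref_sample"]),
            ct_goi_control=float(row["ct_goi_control"]),
            ct_ref_control=float(row["ct_ref_control"]),
            reference_gene=reference_gene,
        )
        for _, row in df.iterrows()
    ]
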