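"""Gene-level expression quantification (RPKM), detection, and qPCR arithmetic."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .core_io import CountTable, GeneModel

__all__ = ["ExpressionTable", "QpcrMeasurement", "rpkm", "detect_expressed", "ddct_fold_change"]


@dataclass
class ExpressionTable:
    """Per-gene RPKM per sample with a detection flag.

    RPKM = reads per kilobase of union-exon gene model per million mapped
    reads; a gene is "detected" when any sample reaches the threshold.
    """

    rpkm: pd.DataFrame  # genes x samples
    detected: pd.Series  # bool per gene
    threshold: float = 1.0


def rpkm(counts: CountTable, models: Sequence[GeneModel]) -> pd.DataFrame:
    """RPKM per gene and sample.

    rpkm[g, s] = counts[g, s] / (exon_kb_g) / (library_size_s / 1e6), with
    exon length taken from the merged union-exon model. Genes present in the
    count table but lacking a model (or with zero exon length) are excluded
    with a warning.
    """
    length = {m.gene_id: m.exon_length_bp for m in models}
    missing = [g for g in counts.gene_ids if length.get(g, 0) <= 0]
    if missing:
        warnings.warn(f"{len(missing)} gene(s) without usable model excluded")
    keep = [g for g in counts.gene_ids if g not in set(missing)]
    kb = pd.Series({g: length[g] / 1000.0 for g in keep})
    millions = counts.library_size / 1e6
    return counts.counts.loc[keep].div(kb, axis=0).div(millions, axis=1)


def detect_expressed(rpkm_table: pd.DataFrame, threshold: float = 1.0) -> ExpressionTable:
    """Flag genes with RPKM >= threshold (inclusive) in at least one sample."""
    detected = (rpkm_table >= threshold).any(axis=1)
    return ExpressionTable(rpkm=rpkm_table, detected=detected, threshold=threshold)


@dataclass(frozen=True)
class QpcrMeasurement:
    """Ct values for a target and reference gene in treated and control wells."""

    ct_target_treated: float
    ct_reference_treated: float
    ct_target_control: float
    ct_reference_control: float

    def __post_init__(self) -> None:
        for v in (
            self.ct_target_treated,
            self.ct_reference_treated,
            self.ct_target_control,
            self.ct_reference_control,
        ):
            if not (v > 0 and v == v and v != float("inf")):
                raise ValueError("Ct values must be finite and positive")

    @property
    def ddct(self) -> float:
        return (self.ct_target_treated - self.ct_reference_treated) - (
            self.ct_target_control - self.ct_reference_control
        )


def ddct_fold_change(m: QpcrMeasurement) -> float:
    """Relative expression by the 2^-ddCt method (fold change treated/control)."""
    return 2.0 ** (-m.ddct)
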