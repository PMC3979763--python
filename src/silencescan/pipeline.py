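"""End-to-end analysis of a (synthetic or real) knockdown study.

Ties the stages together the way the study design dictates: RPKM +
detection, the two-timepoint MA-test DE call, peak filtering and TSS
association, the DE-versus-binding contingency test, and the histone
silenced/control ratio comparison. Also computes recovery metrics against a
simulation's planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import diffexpr, enrichment, expression, histone, peaks_motifs
from .simulate import SimulatedStudy

__all__ = ["PipelineResult", "run_pipeline", "recovery_metrics"]


@dataclass
class PipelineResult:
    rpkm: pd.DataFrame
    detected: pd.Series
    de_calls: pd.DataFrame
    gene_peak_map: dict
    enrichment_all: enrichment.EnrichmentResult
    enrichment_up: enrichment.EnrichmentResult | None
    window_counts: pd.DataFrame | None
    histone_mw: dict[str, tuple[float, float]]


def run_pipeline(
    study: SimulatedStudy,
    fdr: float = 0.001,
    fc: float = 1.5,
    min_peak_height: float = 12.0,
    tss_window: int = 5000,
    ratio_mark: str | None = None,
) -> PipelineResult:
    """Run the full analysis on a simulated study bundle."""
    rpkm = expression.rpkm(study.counts, study.models)
    expr = expression.detect_expressed(rpkm)
    detected = expr.detected

    day2 = diffexpr.ma_test_table(study.counts, "silenced_d2", "control_d2")
    day4 = diffexpr.ma_test_table(study.counts, "silenced_d4", "control_d4")
    calls = diffexpr.call_de(day2, day4, fdr=fdr, fc=fc)

    kept = peaks_motifs.filter_peaks(study.peaks, min_height=min_peak_height)
    gpm = peaks_motifs.associate_peaks_to_genes(kept, study.models, window_bp=tss_window)

    universe = [g for g in detected.index if detected[g]]
    tab_all = enrichment.build_contingency(calls, gpm, universe, "all")
    enr_all = enrichment.chi_square_2x2(tab_all)
    enr_up = None
    tab_up = enrichment.build_contingency(calls, gpm, universe, "up")
    if min(tab_up.a + tab_up.c, tab_up.b + tab_up.d) > 0:
        enr_up = enrichment.chi_square_2x2(tab_up)

    window_counts = None
    histone_mw: dict[str, tuple[float, float]] = {}
    if study.histone:
        marks = sorted({m for (m, _c) in study.histone})
        tracks = {
            m: {"silenced": study.histone[(m, "silenced")], "control": study.histone[(m, "control")]}
            for m in marks
        }
        ref = study.histone[(marks[0] if "H3K4me3" not in marks else "H3K4me3", "control")]
        chosen = {g.gene_id: histone.select_tss(g, ref) for g in study.models}
        non_de = [g for g in universe if calls.loc[g, "status"] == "not_de"]
        window_counts = histone.tss_window_counts(
            study.models, tracks, chosen, non_de_genes=non_de
        )
        up_genes = [g for g in universe if calls.loc[g, "status"] == "up"]
        use_marks = [ratio_mark] if ratio_mark else marks
        for m in use_marks:
            a = window_counts.loc[up_genes, f"{m}_ratio"].dropna()
            b = window_counts.loc[non_de, f"{m}_ratio"].dropna()
            histone_mw[m] = enrichment.mann_whitney(a, b)

    return PipelineResult(
        rpkm=rpkm,
        detected=detected,
        de_calls=calls,
        gene_peak_map=gpm,
        enrichment_all=enr_all,
        enrichment_up=enr_up,
        window_counts=window_counts,
        histone_mw=histone_mw,
    )


def recovery_metrics(study: SimulatedStudy, result: PipelineResult) -> dict[str, float]:
    """Compare DE calls against the planted truth.

    sensitivity: fraction of planted DE genes called up or down;
    fdr: fraction of called genes that were not planted;
    direction_accuracy: among correctly called genes, fraction whose call
    sign matches the planted day-2 direction.
    """
    truth = study.truth.genes
    called = result.de_calls["status"].isin(["up", "down"])
    planted = truth["is_de"]
    tp = (called & planted).sum()
    fp = (called & ~planted).sum()
    sens = tp / planted.sum() if planted.sum() else float("nan")
    fdr = fp / called.sum() if called.sum() else 0.0
    dir_ok = 0
    both = result.de_calls.index[called & planted]
    for g in both:
        sign = 1 if result.de_calls.loc[g, "status"] == "up" else -1
        if sign == truth.loc[g, "direction"]:
            dir_ok += 1
    return {
        "sensitivity": float(sens),
        "fdr": float(fdr),
        "direction_accuracy": dir_ok / len(both) if len(both) else float("nan"),
        "n_called": int(called.sum()),
        "n_planted": int(planted.sum()),
    }
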