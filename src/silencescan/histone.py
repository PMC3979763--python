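"""Histone-mark signal aggregation around anchor sets and silenced/control
enrichment ratios.

Footprints average per-base signal in fixed-width bins around anchor
coordinates (peak summits or TSS), strand-aware: minus-strand anchors are
mirrored so that positive offsets always mean downstream. Per-gene window
counts use a 2-kb window downstream of the TSS; for multi-TSS genes the TSS
with the highest reference-mark (H3K4me3, control) count is selected first.
Silenced/control ratios are normalized by a global scale factor computed
from all non-DE genes, so a genome-wide efficiency difference between the
two libraries cancels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import GeneModel, Peak, SignalTrack

__all__ = [
    "FootprintProfile",
    "footprint",
    "downstream_window",
    "select_tss",
    "tss_window_counts",
    "rank_by_fold_change",
    "group_targets_by_response",
]

Anchor = tuple[str, int, str]  # (chrom, position, strand)


@dataclass
class FootprintProfile:
    """Binned average signal around a set of anchors.

    ``bin_edges`` are offsets relative to the anchor in bp (length
    n_bins + 1, tiling [-half_window, half_window) exactly);
    ``mean_signal[i]`` is the mean over anchors of the per-base signal summed
    within bin i, scaled to a depth of 1e7 reads.
    """

    anchor_count: int
    bin_edges: np.ndarray
    mean_signal: np.ndarray
    mark: str = ""
    normalization: float = 1.0  # reads-per-1e7 scale factor applied

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


def footprint(
    anchors: Iterable[Anchor],
    track: SignalTrack,
    half_window: int = 1750,
    bin_width: int = 50,
    mark: str = "",
) -> FootprintProfile:
    """Average signal profile around anchors.

    The window [-half_window, half_window) is cut into bins of ``bin_width``
    (must tile the window exactly). Minus-strand anchors are mirrored about
    offset 0. Anchors whose window leaves the chromosome are dropped with a
    warning; if none remain this is an error. Signal is scaled to
    reads-per-1e7 using the track's total read count.
    """
    width = 2 * half_window
    if width % bin_width:
        raise ValueError("bin width must tile the window exactly")
    n_bins = width // bin_width
    edges = np.arange(-half_window, half_window + 1, bin_width)
    scale = 1e7 / track.total_reads if track.total_reads > 0 else 1.0

    total = np.zeros(n_bins)
    used = dropped = 0
    for chrom, pos, strand in anchors:
        if chrom not in track.data:
            dropped += 1
            continue
        lo, hi = pos - half_window, pos + half_window
        if lo < 0 or hi > track.chrom_length(chrom):
            dropped += 1
            continue
        window = track.values(chrom, lo, hi)
        if strand == "-":
            window = window[::-1]
        total += window.reshape(n_bins, bin_width).sum(axis=1)
        used += 1
    if dropped:
        warnings.warn(f"{dropped} anchor(s) dropped (chromosome edge or missing)")
    if used == 0:
        raise ValueError("all anchors dropped")
    return FootprintProfile(
        anchor_count=used,
        bin_edges=edges,
        mean_signal=total * scale / used,
        mark=mark,
        normalization=scale,
    )


def downstream_window(tss: int, strand: str, window: int = 2000) -> tuple[int, int]:
    """Half-open window of ``window`` bp downstream of (and including) the
    TSS on the coding strand; minus-strand genes count leftward."""
    if strand == "-":
        return tss - window + 1, tss + 1
    return tss, tss + window


def select_tss(
    gene: GeneModel, reference_track: SignalTrack, window: int = 2000
) -> int:
    """For a multi-TSS gene, the TSS with the highest downstream read count
    in the reference track (H3K4me3, control sample); ties go to the
    smallest coordinate. Single-TSS genes return theirs unchanged."""
    if len(gene.tss_list) == 1:
        return gene.tss_list[0]
    best = None
    for t in sorted(gene.tss_list):
        s, e = downstream_window(t, gene.strand, window)
        count = reference_track.window_sum(gene.chrom, s, e)
        if best is None or count > best[0]:
            best = (count, t)
    return best[1]


def tss_window_counts(
    genes: Sequence[GeneModel],
    tracks: Mapping[str, Mapping[str, SignalTrack]],
    chosen_tss: Mapping[str, int],
    non_de_genes: Iterable[str],
    window: int = 2000,
) -> pd.DataFrame:
    """Downstream-window signal per gene and mark, with normalized
    silenced/control ratios.

    ``tracks[mark]`` maps ``"silenced"``/``"control"`` to tracks. The ratio
    for gene g is (count_sil / count_ctrl) * (sum_nonDE ctrl / sum_nonDE sil),
    i.e. scaled so the non-DE gene set is centered at 1. Genes with zero
    control count get a NaN ratio and are flagged.
    """
    non_de = set(non_de_genes)
    rows = []
    for g in genes:
        tss = chosen_tss[g.gene_id]
        s, e = downstream_window(tss, g.strand, window)
        row: dict = {"gene_id": g.gene_id, "chosen_tss": tss}
        for mark, pair in tracks.items():
            row[f"{mark}_silenced"] = pair["silenced"].window_sum(g.chrom, s, e)
            row[f"{mark}_control"] = pair["control"].window_sum(g.chrom, s, e)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("gene_id")
    for mark in tracks:
        nd = df.index.isin(non_de)
        ctrl_sum = df.loc[nd, f"{mark}_control"].sum()
        sil_sum = df.loc[nd, f"{mark}_silenced"].sum()
        if sil_sum <= 0 or ctrl_sum <= 0:
            raise ValueError(f"{mark}: non-DE normalization sums must be positive")
        norm = ctrl_sum / sil_sum
        ctrl = df[f"{mark}_control"]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = df[f"{mark}_silenced"] / ctrl * norm
        ratio[ctrl == 0] = np.nan
        df[f"{mark}_ratio"] = ratio
        df[f"{mark}_flagged"] = ctrl == 0
    return df


def rank_by_fold_change(
    window_counts: pd.DataFrame, mark: str, k: int = 300
) -> list[str]:
    """Top-k genes by normalized silenced/control ratio for ``mark``,
    descending; ties broken lexicographically by gene id. Exported as a
    ranked list for external GO analysis against the expressed background."""
    col = f"{mark}_ratio"
    ratios = window_counts[col].dropna()
    if len(ratios) < k:
        warnings.warn(f"only {len(ratios)} eligible genes for k={k}")
    order = sorted(ratios.items(), key=lambda kv: (-kv[1], kv[0]))
    return [g for g, _r in order[:k]]


def group_targets_by_response(
    de_table: pd.DataFrame,
    gene_peak_map: Mapping[str, list],
    peaks: Sequence[Peak],
    threshold: float = 2.0,
) -> tuple[list[Anchor], list[Anchor]]:
    """Split bound-gene peak summits by expression response.

    Peaks associated (TSS window) with genes whose fold change is at least
    ``threshold`` (|M| >= log2 threshold, inclusive) become anchors, split
    into (up_anchors, down_anchors) by the sign of M. ``de_table`` must carry
    an ``M_day2`` column (the adjusted day-2 log2 fold change).
    """
    log2thr = np.log2(threshold)
    by_name = {p.name: p for p in peaks}
    up: list[Anchor] = []
    down: list[Anchor] = []
    for gene_id, assoc in gene_peak_map.items():
        if gene_id not in de_table.index:
            continue
        m = de_table.loc[gene_id, "M_day2"]
        if not np.isfinite(m) or abs(m) < log2thr:
            continue
        dest = up if m > 0 else down
        for peak_name, _dist in assoc:
            p = by_name.get(peak_name)
            if p is not None:
                dest.append((p.chrom, p.summit, "."))
    return up, down
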