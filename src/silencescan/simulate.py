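"""Self-consistent synthetic study generator with known ground truth.

Emulates the statistical structure of a two-timepoint transcription-factor
knockdown experiment:

* a gene annotation with 1-3 transcripts per gene (exercising union-exon
  merging and multi-TSS selection), both strands, non-overlapping genes;
* four count samples (silenced/control x day2/day4) drawn binomially from
  a log-normal baseline with planted log2 fold changes in the silenced
  condition, correlated in sign between the two days;
* ChIP-seq peaks placed preferentially near the TSS of up-regulated genes,
  each carrying a planted core motif (GGCTCGC) near the summit, a configured
  fraction with high per-base conservation and a configured fraction with an
  overlapping CCTAGG palindrome;
* histone-mark coverage with a Gaussian bump 120 bp downstream of each
  expressed gene's TSS, amplitude coupled to the planted expression change
  in the silenced tracks, with per-base Poisson noise.

Everything is deterministic given the seed. Defaults are the study
conditions (2,000 genes, 10% DE at |log2FC| in [2, 3], 1e6-read libraries,
within-5-kb peak odds ratio 3); see docs/methods.md for the rationale of
each default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (
    ConservationTrack,
    CountTable,
    GeneModel,
    GenomicInterval,
    Peak,
    SignalTrack,
    revcomp,
    write_bedgraph,
    write_counts,
    write_fasta,
    write_peaks,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedStudy",
    "simulate_annotation",
    "simulate_counts",
    "simulate_peaks_and_tracks",
    "simulate_histone_coverage",
    "simulate_study",
    "write_study",
    "write_transcripts_gtf",
]

SAMPLES = ("silenced_d2", "control_d2", "silenced_d4", "control_d4")

_MOTIF_INSERT = "GGCTCGC"  # core GCTCG at offset 1
_PAL_INSERT = "CCTAGGCTCGC"  # CCTAGG palindrome overlapping the core's leading G
_PAL_CORE_OFFSET = 5


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study. Defaults are the study conditions."""

    n_genes: int = 2000
    n_chromosomes: int = 2
    gene_spacing_bp: int = 12000
    chrom_lengths: dict[str, int] | None = None  # derived from spacing if None
    # expression: log-normal baseline on the log2 scale
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.2
    exonic_fraction: float = 0.75  # fraction of mapped reads landing in genes
    # planted differential expression
    de_fraction: float = 0.10
    effect_size_log2: tuple[float, float] = (2.0, 3.0)  # |M| ~ U(low, high)
    day_correlation: float = 0.95  # P(same sign day2/day4) = (1 + rho)/2
    library_sizes: dict[str, int] = field(
        default_factory=lambda: {s: 1_000_000 for s in SAMPLES}
    )
    # peaks and motifs
    peak_rate_null: float = 0.246  # per-gene rate of a peak within 5 kb of TSS
    peak_enrichment_odds: float = 3.0  # odds ratio for up-regulated genes
    n_background_peaks: int = 200
    intergenic_tail_bp: int = 500_000  # gene-free space hosting background peaks
    peak_half_width: int = 150
    motif_conserved_fraction: float = 0.22
    palindrome_fraction: float = 0.5
    # histone coverage
    histone_marks: tuple[str, ...] = ("H3K4me3", "H3K9ac")
    histone_base: float = 1.0  # baseline coverage per base
    histone_amplitude: float = 15.0  # bump peak height at median expression
    histone_coupling: float = 0.5  # silenced amplitude *= 2^(coupling * log2FC)
    histone_bump_offset: int = 120  # bump center, bp downstream of TSS
    histone_bump_sigma: float = 300.0
    minor_tss_amplitude: float = 0.2  # relative bump height at inactive TSS
    read_length: int = 50

    def __post_init__(self) -> None:
        if not (0 <= self.de_fraction < 1):
            raise ValueError("de_fraction must lie in [0, 1)")
        if self.peak_enrichment_odds <= 0:
            raise ValueError("peak_enrichment_odds must be > 0")
        if any(v <= 0 for v in self.library_sizes.values()):
            raise ValueError("library sizes must be > 0")

    def resolved_chrom_lengths(self) -> dict[str, int]:
        if self.chrom_lengths is not None:
            return dict(self.chrom_lengths)
        per = -(-self.n_genes // self.n_chromosomes) if self.n_genes else 1
        length = (per + 1) * self.gene_spacing_bp + self.intergenic_tail_bp
        return {f"chr{i + 1}": length for i in range(self.n_chromosomes)}


@dataclass
class GroundTruth:
    """Planted truth, filled in progressively by the generator stages.

    ``genes`` is indexed by gene_id with columns: chrom, strand, tss (the
    active TSS), baseline_expr, is_de, direction, effect_d2, effect_d4,
    p_<sample> (true sampling proportions), has_peak, peak_name.
    ``motifs`` has one row per planted motif: peak_name, chrom, position
    (core start), strand, conserved, palindrome.
    """

    genes: pd.DataFrame
    motifs: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# Annotation


def simulate_annotation(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[GeneModel], list[tuple]]:
    """Generate gene models plus the transcript structures behind them.

    Returns ``(models, transcripts)`` where each transcript is
    ``(gene_id, tx_id, chrom, strand, [(exon_start, exon_end), ...])``.
    Genes are non-overlapping, on both strands, with 1-3 transcripts whose
    union reproduces the model's merged exons; plus-strand transcripts vary
    at the 5' end (distinct TSS), minus-strand ones symmetrically.
    """
    lengths = config.resolved_chrom_lengths()
    chroms = sorted(lengths)
    per_chrom = -(-config.n_genes // len(chroms)) if config.n_genes else 0
    for c in chroms:
        if per_chrom and lengths[c] < (per_chrom + 1) * config.gene_spacing_bp:
            raise ValueError(
                f"{c}: length {lengths[c]} cannot host {per_chrom} genes "
                f"at spacing {config.gene_spacing_bp}"
            )
    models: list[GeneModel] = []
    transcripts: list[tuple] = []
    for gi in range(config.n_genes):
        chrom = chroms[gi // per_chrom]
        slot = gi % per_chrom
        gene_id = f"G{gi:05d}"
        g0 = (slot + 1) * config.gene_spacing_bp + int(rng.integers(-500, 500))
        span = int(rng.integers(1500, 4001))
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 5))
        if n_exons == 1:
            exons = [(g0, g0 + span)]
        else:
            cuts = np.sort(rng.choice(np.arange(50, span - 50), 2 * (n_exons - 1), replace=False))
            bounds = [0, *cuts.tolist(), span]
            exons = [
                (g0 + bounds[2 * k], g0 + bounds[2 * k + 1]) for k in range(n_exons)
            ]
        n_tx = int(rng.integers(1, 4))
        txs = []
        for t in range(n_tx):
            if t == 0:
                use = exons  # first transcript spans everything
            elif strand == "+":
                drop = int(rng.integers(1, len(exons))) if len(exons) > 1 else 0
                use = exons[drop:]
            else:
                drop = int(rng.integers(1, len(exons))) if len(exons) > 1 else 0
                use = exons[: len(exons) - drop] or exons
            txs.append((gene_id, f"{gene_id}.t{t + 1}", chrom, strand, list(use)))
        transcripts.extend(txs)
        tss = sorted(
            {(ex[0][0] if strand == "+" else ex[-1][1] - 1) for (_g, _t, _c, _s, ex) in txs}
        )
        models.append(GeneModel(gene_id, chrom, strand, list(exons), tss))
    return models, transcripts


def write_transcripts_gtf(transcripts: Sequence[tuple], path: str | Path) -> None:
    """Write simulator transcripts as Ensembl-dialect GTF exon records."""
    with open(path, "w") as fh:
        for gene_id, tx_id, chrom, strand, exons in transcripts:
            for s, e in exons:
                attrs = f'gene_id "{gene_id}"; transcript_id "{tx_id}";'
                fh.write(f"{chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# Counts


def simulate_counts(
    config: SimulationConfig,
    models: Sequence[GeneModel],
    rng: np.random.Generator,
) -> tuple[CountTable, GroundTruth]:
    """Binomially sampled counts with planted fold changes.

    Per sample s and gene g, count ~ Bin(library_size_s, p_gs); the true
    proportions come from a log-normal baseline scaled so that expressed
    genes capture ``exonic_fraction`` of the control library, and the
    silenced samples multiply DE genes' proportions by 2^effect. Planted
    day-2 and day-4 effects share their sign with probability
    (1 + day_correlation)/2.
    """
    n = len(models)
    gene_ids = [m.gene_id for m in models]
    x = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)
    expr = np.exp2(x)
    p_base = expr / expr.sum() * config.exonic_fraction if n else expr

    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    is_de = np.zeros(n, dtype=bool)
    is_de[de_idx] = True
    direction = np.zeros(n, dtype=np.int64)
    direction[de_idx] = rng.choice([-1, 1], size=n_de)
    lo, hi = config.effect_size_log2
    eff2 = np.zeros(n)
    eff4 = np.zeros(n)
    eff2[de_idx] = direction[de_idx] * rng.uniform(lo, hi, n_de)
    same_sign = rng.random(n_de) < (1.0 + config.day_correlation) / 2.0
    sign4 = np.where(same_sign, direction[de_idx], -direction[de_idx])
    eff4[de_idx] = sign4 * rng.uniform(lo, hi, n_de)

    p = {
        "control_d2": p_base,
        "control_d4": p_base,
        "silenced_d2": p_base * np.exp2(eff2),
        "silenced_d4": p_base * np.exp2(eff4),
    }
    for s, ps in p.items():
        total = ps.sum()
        if total > 1.0:
            warnings.warn(f"{s}: true proportions sum to {total:.3f} > 1; rescaled")
            p[s] = ps * (0.99 / total)

    counts = pd.DataFrame(
        {s: rng.binomial(config.library_sizes[s], p[s]) for s in SAMPLES},
        index=gene_ids,
    )
    table = CountTable(
        counts=counts, library_size=pd.Series(config.library_sizes)[list(SAMPLES)]
    )
    genes = pd.DataFrame(
        {
            "chrom": [m.chrom for m in models],
            "strand": [m.strand for m in models],
            "tss": [
                m.tss_list[int(rng.integers(0, len(m.tss_list)))] for m in models
            ],
            "baseline_expr": expr,
            "is_de": is_de,
            "direction": direction,
            "effect_d2": eff2,
            "effect_d4": eff4,
            **{f"p_{s}": p[s] for s in SAMPLES},
        },
        index=gene_ids,
    )
    return table, GroundTruth(genes=genes)


# ---------------------------------------------------------------------------
# Peaks, genome, conservation


def simulate_peaks_and_tracks(
    config: SimulationConfig,
    models: Sequence[GeneModel],
    truth: GroundTruth,
    rng: np.random.Generator,
) -> tuple[list[Peak], dict[str, str], ConservationTrack]:
    """Peaks near up-regulated genes' TSS, a random genome with planted
    motifs near each summit, and a conservation track.

    Up-regulated genes receive a peak at odds ``peak_enrichment_odds`` times
    the background odds (``peak_rate_null``); every peak carries the core
    motif within 100 bp of its summit, a ``motif_conserved_fraction`` subset
    gets per-base conservation > 0.9 over the motif, a ``palindrome_fraction``
    subset gets an overlapping CCTAGG palindrome. Background peaks (no gene,
    no planted motif) exercise height filtering. The random background
    sequence is not guaranteed free of chance motif occurrences.
    """
    lengths = config.resolved_chrom_lengths()
    genome = {
        c: rng.integers(0, 4, size=lengths[c]).astype(np.uint8) for c in sorted(lengths)
    }
    cons: dict[str, np.ndarray] = {
        c: np.full(lengths[c], np.nan) for c in sorted(lengths)
    }

    odds_null = config.peak_rate_null / (1.0 - config.peak_rate_null)
    odds_up = config.peak_enrichment_odds * odds_null
    p_up = odds_up / (1.0 + odds_up)

    peaks: list[Peak] = []
    motif_rows: list[dict] = []
    has_peak = {}
    peak_name_of = {}
    hw = config.peak_half_width
    for m in models:
        row = truth.genes.loc[m.gene_id]
        upreg = bool(row["is_de"]) and row["direction"] > 0
        rate = p_up if upreg else config.peak_rate_null
        draw = rng.random() < rate
        has_peak[m.gene_id] = draw
        peak_name_of[m.gene_id] = ""
        if not draw:
            continue
        tss = int(row["tss"])
        L = lengths[m.chrom]
        summit = int(np.clip(tss + rng.integers(-4400, 4401), hw + 20, L - hw - 21))
        name = f"peak_{m.gene_id}"
        peak = Peak(
            GenomicInterval(m.chrom, summit - hw, summit + hw + 1),
            summit,
            float(rng.uniform(12, 60)),
            name,
        )
        peaks.append(peak)
        peak_name_of[m.gene_id] = name
        # plant the motif insert near the summit
        pal = rng.random() < config.palindrome_fraction
        conserved = rng.random() < config.motif_conserved_fraction
        insert = _PAL_INSERT if pal else _MOTIF_INSERT
        core_off = _PAL_CORE_OFFSET if pal else 1
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            insert = revcomp(insert)
            core_off = len(insert) - core_off - 5
        d = int(rng.integers(-90, 91))
        ins_start = summit + d - core_off
        _write_seq(genome[m.chrom], ins_start, insert)
        core_start = ins_start + core_off
        # conservation: low background across the peak, high over the motif
        bg_lo, bg_hi = summit - 120, summit + 121
        cons[m.chrom][bg_lo:bg_hi] = rng.uniform(0.05, 0.55, bg_hi - bg_lo)
        if conserved:
            cons[m.chrom][core_start - 3 : core_start + 8] = rng.uniform(0.93, 1.0, 11)
        motif_rows.append(
            {
                "peak_name": name,
                "gene_id": m.gene_id,
                "chrom": m.chrom,
                "position": core_start,
                "strand": strand,
                "conserved": conserved,
                "palindrome": pal,
            }
        )

    # background peaks far from every TSS
    all_tss = {
        c: np.array(
            sorted(t for m in models if m.chrom == c for t in m.tss_list), dtype=np.int64
        )
        for c in sorted(lengths)
    }
    # prefer the gene-free space past the last TSS; fall back to rejection
    # sampling over the whole chromosome
    free: dict[str, tuple[int, int]] = {}
    for c in sorted(lengths):
        lo = (int(all_tss[c].max()) + 5201) if all_tss[c].size else hw + 20
        hi = lengths[c] - hw - 21
        if hi > lo:
            free[c] = (lo, hi)
    placed = 0
    for i in range(config.n_background_peaks):
        ok = False
        for _try in range(10):
            c = sorted(lengths)[int(rng.integers(0, len(lengths)))]
            if c in free:
                summit = int(rng.integers(*free[c]))
            else:
                summit = int(rng.integers(hw + 20, lengths[c] - hw - 21))
                if all_tss[c].size and np.abs(all_tss[c] - summit).min() <= 5200:
                    continue
            ok = True
            break
        if not ok:
            warnings.warn("background peak placement failed after retries")
            continue
        peaks.append(
            Peak(
                GenomicInterval(c, summit - hw, summit + hw + 1),
                summit,
                float(rng.uniform(5, 60)),
                f"bg_peak_{placed:04d}",
            )
        )
        placed += 1

    truth.genes["has_peak"] = pd.Series(has_peak)
    truth.genes["peak_name"] = pd.Series(peak_name_of)
    truth.motifs = pd.DataFrame(motif_rows)
    genome_str = {c: _to_str(a) for c, a in genome.items()}
    return peaks, genome_str, ConservationTrack(cons)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _write_seq(arr: np.ndarray, start: int, seq: str) -> None:
    arr[start : start + len(seq)] = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _to_str(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


# ---------------------------------------------------------------------------
# Histone coverage


def simulate_histone_coverage(
    config: SimulationConfig,
    models: Sequence[GeneModel],
    truth: GroundTruth,
    rng: np.random.Generator,
) -> dict[tuple[str, str], SignalTrack]:
    """Per-mark, per-condition coverage tracks with Poisson noise.

    Coverage is a flat baseline plus a Gaussian bump centered
    ``histone_bump_offset`` bp downstream of each gene's active TSS
    (strand-aware), amplitude proportional to baseline expression; inactive
    TSS of multi-TSS genes receive a reduced bump (``minor_tss_amplitude``).
    In silenced tracks the amplitude of DE genes is multiplied by
    2^(histone_coupling * day-2 log2 effect).
    """
    lengths = config.resolved_chrom_lengths()
    median_expr = float(np.median(truth.genes["baseline_expr"])) or 1.0
    sigma = config.histone_bump_sigma
    half = int(4 * sigma)
    offsets = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (offsets / sigma) ** 2)

    tracks: dict[tuple[str, str], SignalTrack] = {}
    for mark in config.histone_marks:
        for cond in ("silenced", "control"):
            lam = {c: np.full(lengths[c], config.histone_base) for c in sorted(lengths)}
            for m in models:
                row = truth.genes.loc[m.gene_id]
                rel = min(float(row["baseline_expr"]) / median_expr, 20.0)
                amp = config.histone_amplitude * rel
                if cond == "silenced" and row["is_de"]:
                    amp *= 2.0 ** (config.histone_coupling * float(row["effect_d2"]))
                active = int(row["tss"])
                for t in m.tss_list:
                    a = amp if t == active else amp * config.minor_tss_amplitude
                    center = t + (
                        config.histone_bump_offset
                        if m.strand != "-"
                        else -config.histone_bump_offset
                    )
                    lo = max(center - half, 0)
                    hi = min(center + half + 1, lengths[m.chrom])
                    if lo < hi:
                        lam[m.chrom][lo:hi] += a * kernel[
                            lo - (center - half) : hi - (center - half)
                        ]
            data = {c: rng.poisson(v).astype(np.float64) for c, v in lam.items()}
            total = sum(a.sum() for a in data.values())
            tracks[(mark, cond)] = SignalTrack(
                data, total_reads=total / config.read_length, source_mapq_min=10
            )
    return tracks


# ---------------------------------------------------------------------------
# Whole-study convenience


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    models: list[GeneModel]
    transcripts: list[tuple]
    counts: CountTable
    truth: GroundTruth
    peaks: list[Peak]
    genome: dict[str, str]
    conservation: ConservationTrack
    histone: dict[tuple[str, str], SignalTrack]


def simulate_study(
    config: SimulationConfig | None = None,
    seed: int = 0,
    with_histone: bool = True,
) -> SimulatedStudy:
    """Run every generator stage off a single seeded RNG."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    models, transcripts = simulate_annotation(config, rng)
    counts, truth = simulate_counts(config, models, rng)
    peaks, genome, cons = simulate_peaks_and_tracks(config, models, truth, rng)
    histone = (
        simulate_histone_coverage(config, models, truth, rng) if with_histone else {}
    )
    return SimulatedStudy(
        config, models, transcripts, counts, truth, peaks, genome, cons, histone
    )


def write_study(study: SimulatedStudy, outdir: str | Path) -> None:
    """Write every emitted file format: GTF, counts TSV, peaks BED, genome
    FASTA, conservation bedGraph, per-mark signal bedGraphs, truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_transcripts_gtf(study.transcripts, outdir / "annotation.gtf")
    write_counts(study.counts, outdir / "counts.tsv")
    write_peaks(study.peaks, outdir / "peaks.bed")
    write_fasta(study.genome, outdir / "genome.fa")
    write_bedgraph(study.conservation, outdir / "conservation.bedgraph")
    for (mark, cond), track in study.histone.items():
        write_bedgraph(track, outdir / f"{mark}_{cond}.bedgraph")
    study.truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t")
    study.truth.motifs.to_csv(outdir / "truth_motifs.tsv", sep="\t", index=False)
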