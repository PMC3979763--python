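"""Shared genomic data model and text-format readers/writers.

All internal coordinates are 0-based half-open. BED and bedGraph are native
to that convention; GTF and wiggle (1-based) are converted at parse time and
converted back on write. Strand is one of ``+``, ``-``, ``.``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "Peak",
    "ConservationTrack",
    "SignalTrack",
    "CountTable",
    "revcomp",
    "merge_intervals",
    "read_annotation",
    "write_gtf",
    "read_peaks",
    "write_peaks",
    "read_track",
    "write_bedgraph",
    "read_fasta",
    "write_fasta",
    "read_counts",
    "write_counts",
]

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval.

    ``start``/``end`` are 0-based half-open; use :meth:`from_one_based` for
    1-based inclusive source coordinates (GTF, browser positions).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @classmethod
    def from_one_based(
        cls, chrom: str, start: int, end: int, strand: str = "."
    ) -> "GenomicInterval":
        """Build from 1-based inclusive coordinates (length = end - start + 1)."""
        return cls(chrom, start - 1, end, strand)

    @property
    def length(self) -> int:
        return self.end - self.start


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals: sorted, pairwise disjoint (touching merged)."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


@dataclass
class GeneModel:
    """A gene as the union of its transcripts' exons.

    ``intervals`` are merged, sorted, pairwise-disjoint exon intervals.
    ``tss_list`` keeps every distinct transcript start (5'-most base of each
    transcript, respecting strand); downstream TSS selection is explicit.
    """

    gene_id: str
    chrom: str
    strand: str
    intervals: list[tuple[int, int]]
    tss_list: list[int]

    def __post_init__(self) -> None:
        self.intervals = merge_intervals(self.intervals)
        if not self.tss_list:
            raise ValueError(f"{self.gene_id}: tss_list must be non-empty")

    @property
    def exon_length_bp(self) -> int:
        return sum(e - s for s, e in self.intervals)

    @property
    def span(self) -> tuple[int, int]:
        return self.intervals[0][0], self.intervals[-1][1]

    @property
    def tss(self) -> int:
        """The gene-level TSS: 5'-most transcript start respecting strand."""
        return min(self.tss_list) if self.strand != "-" else max(self.tss_list)


@dataclass
class Peak:
    """A called ChIP-seq peak with single-base summit and unitless height."""

    interval: GenomicInterval
    summit: int
    height: float
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside "
                f"[{self.interval.start}, {self.interval.end})"
            )
        if self.height < 0:
            raise ValueError("height must be >= 0")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


class _BaseTrack:
    """Dense per-base values per chromosome, stored as float arrays."""

    def __init__(self, data: Mapping[str, np.ndarray]):
        self.data = {c: np.asarray(v, dtype=np.float64) for c, v in data.items()}

    def chrom_length(self, chrom: str) -> int:
        return len(self.data[chrom])

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); out-of-range bases are padded
        with the track's absent value."""
        arr = self.data.get(chrom)
        absent = self._absent_value
        if arr is None:
            return np.full(end - start, absent)
        lo, hi = max(start, 0), min(end, len(arr))
        if lo >= hi:
            return np.full(end - start, absent)
        out = np.full(end - start, absent, dtype=np.float64)
        out[lo - start : hi - start] = arr[lo:hi]
        return out


class ConservationTrack(_BaseTrack):
    """Per-base conservation probabilities in [0, 1]; NaN marks absent bases."""

    _absent_value = math.nan

    def __init__(self, data: Mapping[str, np.ndarray]):
        super().__init__(data)
        for chrom, arr in self.data.items():
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError(f"{chrom}: conservation scores outside [0, 1]")

    def mean_over(self, chrom: str, start: int, end: int, absent_as: float = 0.0) -> float:
        """Arithmetic mean over [start, end); absent bases contribute ``absent_as``."""
        vals = self.values(chrom, start, end)
        return float(np.nanmean(np.where(np.isnan(vals), absent_as, vals)))


class SignalTrack(_BaseTrack):
    """Per-base non-negative coverage with bookkeeping for normalization."""

    _absent_value = 0.0

    def __init__(
        self,
        data: Mapping[str, np.ndarray],
        total_reads: float | None = None,
        source_mapq_min: int | None = None,
    ):
        super().__init__(data)
        for chrom, arr in self.data.items():
            if arr.size and arr.min() < 0:
                raise ValueError(f"{chrom}: negative coverage")
        if total_reads is None:
            total_reads = float(sum(a.sum() for a in self.data.values()))
        if total_reads < 0:
            raise ValueError("total_reads must be >= 0")
        self.total_reads = float(total_reads)
        self.source_mapq_min = source_mapq_min

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        return float(self.values(chrom, start, end).sum())


@dataclass
class CountTable:
    """Per-gene integer read counts per sample plus per-sample library sizes.

    ``library_size`` is the total number of mapped reads in each sample (not
    the column sum: mapped reads outside gene models count toward depth).
    """

    counts: pd.DataFrame  # genes x samples, non-negative integers
    library_size: pd.Series  # per sample

    def __post_init__(self) -> None:
        counts = self.counts
        if (counts.values < 0).any():
            raise ValueError("counts must be >= 0")
        if not np.allclose(counts.values, np.round(counts.values)):
            raise ValueError("counts must be integral")
        self.counts = counts.astype(np.int64)
        self.library_size = self.library_size.astype(np.int64).reindex(counts.columns)
        short = self.library_size < self.counts.sum(axis=0)
        if short.any():
            bad = list(self.library_size.index[short])
            raise ValueError(f"library_size smaller than column sum for {bad}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


# ---------------------------------------------------------------------------
# Annotation


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_annotation(path: str | Path, fmt: str | None = None) -> list[GeneModel]:
    """Read a GTF (Ensembl dialect) or refGene-style table into gene models.

    All transcripts of a gene are merged into union exons; 1-based inclusive
    GTF coordinates are converted to 0-based half-open. A gene whose
    transcripts sit on more than one chromosome is skipped with a warning.
    """
    path = Path(path)
    if fmt is None:
        fmt = "refgene" if path.suffix in (".txt", ".refgene") else "gtf"
    if fmt == "gtf":
        return _read_gtf(path)
    if fmt == "refgene":
        return _read_refgene(path)
    raise ValueError(f"unknown annotation format {fmt!r}")


def _read_gtf(path: Path) -> list[GeneModel]:
    # gene_id -> {chrom, strand, exons, transcript_id -> (chrom, strand, exon list)}
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab fields, got {len(fields)}")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                s0, e0 = int(start) - 1, int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if not (0 <= s0 < e0):
                raise ValueError(f"{path}:{lineno}: invalid interval {start}-{end}")
            a = _parse_gtf_attributes(attrs)
            gid = a.get("gene_id")
            tid = a.get("transcript_id", gid)
            if gid is None:
                raise ValueError(f"{path}:{lineno}: exon record without gene_id")
            g = genes.setdefault(gid, {"chroms": set(), "strand": strand, "tx": {}})
            g["chroms"].add(chrom)
            g["tx"].setdefault(tid, []).append((chrom, strand, s0, e0))
    return _assemble_genes(genes)


def _read_refgene(path: Path) -> list[GeneModel]:
    """UCSC refGene-style table: one transcript per line, already 0-based.

    Expected columns (tab): name, chrom, strand, txStart, txEnd, cdsStart,
    cdsEnd, exonCount, exonStarts, exonEnds, name2. A leading numeric ``bin``
    column is tolerated.
    """
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if fields and fields[0].isdigit() and len(fields) >= 12:
                fields = fields[1:]  # drop UCSC bin column
            if len(fields) < 11:
                raise ValueError(f"{path}:{lineno}: expected >= 11 refGene fields")
            name, chrom, strand = fields[0], fields[1], fields[2]
            try:
                starts = [int(x) for x in fields[8].rstrip(",").split(",")]
                ends = [int(x) for x in fields[9].rstrip(",").split(",")]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed exon lists") from exc
            gid = fields[10] or name
            g = genes.setdefault(gid, {"chroms": set(), "strand": strand, "tx": {}})
            g["chroms"].add(chrom)
            g["tx"][name] = [(chrom, strand, s, e) for s, e in zip(starts, ends)]
    return _assemble_genes(genes)


def _assemble_genes(genes: dict[str, dict]) -> list[GeneModel]:
    models = []
    for gid in sorted(genes):
        g = genes[gid]
        if len(g["chroms"]) > 1:
            warnings.warn(f"gene {gid} spans multiple chromosomes; skipped")
            continue
        chrom = next(iter(g["chroms"]))
        strand = g["strand"]
        exons: list[tuple[int, int]] = []
        tss: set[int] = set()
        for tx_exons in g["tx"].values():
            ivs = [(s, e) for (_c, _st, s, e) in tx_exons]
            exons.extend(ivs)
            lo = min(s for s, _ in ivs)
            hi = max(e for _, e in ivs)
            tss.add(lo if strand != "-" else hi - 1)
        models.append(GeneModel(gid, chrom, strand, exons, sorted(tss)))
    return models


def write_gtf(models: Sequence[GeneModel], path: str | Path) -> None:
    """Write union-exon gene models as single-transcript Ensembl-dialect GTF."""
    with open(path, "w") as fh:
        for m in models:
            for s, e in m.intervals:
                attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.gene_id}.t1";'
                fh.write(
                    f"{m.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Peaks


def read_peaks(
    path: str | Path,
    height_column: int = 4,
    summit_column: int = 5,
    summit_is_offset: bool = True,
) -> list[Peak]:
    """Read a BED-like peak file (MACS-style).

    Columns (0-based indices): chrom, start, end, name, then ``height_column``
    for the unitless peak height and ``summit_column`` for the summit, given
    as an offset from ``start`` (default) or an absolute position. Records
    whose summit falls outside [start, end) are rejected with a warning.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"peak{lineno}"
            height = float(fields[height_column]) if len(fields) > height_column else 0.0
            if len(fields) > summit_column:
                summit = int(fields[summit_column])
                if summit_is_offset:
                    summit += start
            else:
                summit = (start + end) // 2
            if not (start <= summit < end):
                warnings.warn(
                    f"{path}:{lineno}: summit {summit} outside [{start}, {end}); "
                    "record rejected"
                )
                continue
            peaks.append(Peak(GenomicInterval(chrom, start, end), summit, height, name))
    return peaks


def write_peaks(peaks: Sequence[Peak], path: str | Path) -> None:
    """Write peaks as BED6-like: chrom start end name height summit-offset."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.interval.start}\t{p.interval.end}\t{p.name}"
                f"\t{p.height:.6f}\t{p.summit - p.interval.start}\n"
            )


# ---------------------------------------------------------------------------
# Tracks (bedGraph / wiggle)


def read_track(path: str | Path, kind: str = "signal") -> ConservationTrack | SignalTrack:
    """Read a bedGraph or wiggle (fixedStep/variableStep) file.

    ``kind`` is ``"conservation"`` (absent bases NaN, values must lie in
    [0, 1]) or ``"signal"`` (absent bases 0). bedGraph intervals are expanded
    per base; overlapping bedGraph intervals raise an error naming the overlap.
    Wiggle positions are 1-based per the UCSC convention and converted.
    """
    if kind not in ("conservation", "signal"):
        raise ValueError(f"unknown track kind {kind!r}")
    intervals: dict[str, list[tuple[int, int, float]]] = {}

    def add(chrom: str, start: int, end: int, value: float) -> None:
        intervals.setdefault(chrom, []).append((start, end, value))

    mode = "bedgraph"
    chrom = ""
    pos = step = span = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                opts = dict(kv.split("=") for kv in line.split()[1:])
                chrom = opts["chrom"]
                pos = int(opts["start"]) - 1  # wiggle is 1-based
                step = int(opts.get("step", 1))
                span = int(opts.get("span", 1))
                mode = "fixed"
                continue
            if line.startswith("variableStep"):
                opts = dict(kv.split("=") for kv in line.split()[1:])
                chrom = opts["chrom"]
                span = int(opts.get("span", 1))
                mode = "variable"
                continue
            fields = line.split()
            if mode == "fixed" and len(fields) == 1:
                add(chrom, pos, pos + span, float(fields[0]))
                pos += step
            elif mode == "variable" and len(fields) == 2:
                start = int(fields[0]) - 1
                add(chrom, start, start + span, float(fields[1]))
            elif len(fields) == 4:
                mode = "bedgraph"
                add(fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
            else:
                raise ValueError(f"{path}:{lineno}: malformed track line {line!r}")

    absent = math.nan if kind == "conservation" else 0.0
    data: dict[str, np.ndarray] = {}
    for c, ivs in intervals.items():
        ivs.sort()
        for (s1, e1, _v1), (s2, e2, _v2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(
                    f"{path}: overlapping intervals on {c}: "
                    f"[{s1}, {e1}) and [{s2}, {e2})"
                )
        arr = np.full(max(e for _s, e, _v in ivs), absent)
        for s, e, v in ivs:
            arr[s:e] = v
        data[c] = arr
    if kind == "conservation":
        return ConservationTrack(data)
    return SignalTrack(data)


def write_bedgraph(
    track: _BaseTrack | Mapping[str, np.ndarray], path: str | Path, precision: int = 6
) -> None:
    """Write per-base values as run-length-compressed bedGraph.

    Absent bases (NaN) and zero-signal runs are omitted, matching what
    :func:`read_track` reconstructs.
    """
    data = track.data if isinstance(track, _BaseTrack) else track
    skip_zero = isinstance(track, SignalTrack)
    with open(path, "w") as fh:
        for chrom in sorted(data):
            arr = np.asarray(data[chrom], dtype=np.float64)
            arr = np.round(arr, precision)
            if arr.size == 0:
                continue
            # run boundaries where the value changes
            change = np.flatnonzero(~np.isclose(arr[1:], arr[:-1], equal_nan=True))
            starts = np.concatenate(([0], change + 1))
            ends = np.concatenate((change + 1, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if np.isnan(v) or (skip_zero and v == 0.0):
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.{precision}g}\n")


# ---------------------------------------------------------------------------
# FASTA and count tables


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a dict of upper-case sequences (pyfaidx-backed)."""
    from pyfaidx import Fasta

    with Fasta(str(path), rebuild=True, build_index=True) as fa:
        return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_counts(path: str | Path) -> CountTable:
    """Read a TSV count matrix whose first row after the header holds the
    per-sample library sizes (row id ``__library_size__``)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    lib = df.loc["__library_size__"]
    counts = df.drop(index="__library_size__")
    return CountTable(counts=counts, library_size=lib)


def write_counts(table: CountTable, path: str | Path) -> None:
    out = pd.concat(
        [table.library_size.rename("__library_size__").to_frame().T, table.counts]
    )
    out.to_csv(path, sep="\t")
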