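"""Peak filtering, core-motif scanning near summits, conservation scoring,
palindrome detection and peak-to-gene association.

The binding factor's core recognition site is the 5-mer GCTCG (extended
7-mer GGCTCGC). Scanning is symmetric over both strands by default: a
reverse-complement occurrence (CGAGC on the forward sequence) is reported as
a minus-strand hit. A "palindrome" is a window equal to its own reverse
complement (e.g. CCTAGG) that partially overlaps the matched core; its
presence distinguishes repressed from activated target promoters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .core_io import ConservationTrack, GeneModel, Peak, revcomp

__all__ = [
    "MotifHit",
    "CORE_MOTIF",
    "EXTENDED_MOTIF",
    "EMSA_PROBES",
    "filter_peaks",
    "scan_motif",
    "scan_sequence",
    "conservation_score",
    "detect_palindrome",
    "associate_peaks_to_genes",
]

CORE_MOTIF = "GCTCG"
EXTENDED_MOTIF = "GGCTCGC"

# Printed EMSA probe sequences (double-stranded in the assay): the wild-type
# Igf2 site, the wild-type Twist2 site, and the Twist2 point-mutant (MUT),
# motif-deletion (DEL) and palindrome-creating (PAL) variants.
EMSA_PROBES: dict[str, str] = {
    "Igf2_wt": "CTTCGCCTAGGCTCGCAGCGCGGGAGCGA",
    "Twist2_wt": "TGGGCGCTCCCGCAGAGGCTCGCTGTGATGCCTAAGCT",
    "Twist2_mut": "TGGGCGCTCCCGCAGAGGCTCACTGTGATGCCTAAGCT",
    "Twist2_pal": "TGGGCGCTCCCGCCTAGGCTCGCTGTGATGCCTAAGCT",
    "Twist2_del": "TGGGCGCTCCCGCAGAGCTGTGATGCCTAAGCT",
}


@dataclass
class MotifHit:
    """A core-motif match near a peak summit.

    ``position`` is the 0-based start of the matched window on the forward
    sequence; for minus-strand hits ``matched_seq`` is the reverse complement
    of that window (i.e. it equals the core motif).
    """

    peak_id: str
    chrom: str
    position: int
    strand: str
    matched_seq: str
    distance_to_summit: int
    extended_match: bool
    mean_conservation: float | None = None
    conserved: bool | None = None
    palindrome: bool | None = None
    palindrome_seq: str | None = None
    palindrome_pos: int | None = None

    @property
    def end(self) -> int:
        return self.position + len(self.matched_seq)


def filter_peaks(peaks: Sequence[Peak], min_height: float = 12.0) -> list[Peak]:
    """Peaks with height >= min_height (inclusive), input order preserved."""
    return [p for p in peaks if p.height >= min_height]


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def scan_sequence(
    seq: str,
    summit: int,
    core: str = CORE_MOTIF,
    flank: int = 100,
    both_strands: bool = True,
    extended: str = EXTENDED_MOTIF,
    peak_id: str = "",
    chrom: str = "",
    offset: int = 0,
) -> list[MotifHit]:
    """Report every core occurrence whose start lies within ``flank`` bp of
    ``summit`` (inclusive on both boundaries) on a forward sequence.

    ``seq`` is indexed by forward coordinates starting at ``offset`` (so a
    whole chromosome passes offset=0 and a window passes its genomic start).
    ``extended_match`` is set when the extended 7-mer covers the hit on the
    matched strand.
    """
    seq = seq.upper()
    core = core.upper()
    lo = max(summit - flank, offset)
    hi = min(summit + flank, offset + len(seq) - len(core))  # last allowed start

    ext_off = extended.find(core) if extended else -1
    hits: list[MotifHit] = []

    def emit(pos: int, strand: str, window: str, ext: str, ext_pos_off: int) -> None:
        if not (summit - flank <= pos <= summit + flank):
            return
        is_ext = False
        if ext_pos_off >= 0:
            s = pos - ext_pos_off - offset
            is_ext = seq[s : s + len(ext)] == ext
        hits.append(
            MotifHit(
                peak_id=peak_id,
                chrom=chrom,
                position=pos,
                strand=strand,
                matched_seq=window if strand == "+" else revcomp(window),
                distance_to_summit=pos - summit,
                extended_match=is_ext,
            )
        )

    if lo <= hi:
        region = seq[lo - offset : hi - offset + len(core)]
        for i in _find_all(region, core):
            emit(lo + i, "+", core, extended, ext_off)
        if both_strands:
            rc_core = revcomp(core)
            rc_ext = revcomp(extended) if extended else ""
            # core at offset ext_off in extended => rc_core at mirrored offset
            rc_off = (len(extended) - len(core) - ext_off) if ext_off >= 0 else -1
            for i in _find_all(region, rc_core):
                emit(lo + i, "-", rc_core, rc_ext, rc_off)
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def scan_motif(
    peak: Peak,
    genome: Mapping[str, str],
    core: str = CORE_MOTIF,
    flank: int = 100,
    both_strands: bool = True,
    extended: str = EXTENDED_MOTIF,
) -> list[MotifHit]:
    """Scan the genome around a peak's summit for the core motif."""
    if peak.chrom not in genome:
        raise KeyError(f"chromosome {peak.chrom!r} not in genome")
    seq = str(genome[peak.chrom])
    lo = max(peak.summit - flank - len(extended), 0)
    hi = min(peak.summit + flank + len(core) + len(extended), len(seq))
    return scan_sequence(
        seq[lo:hi],
        peak.summit,
        core=core,
        flank=flank,
        both_strands=both_strands,
        extended=extended,
        peak_id=peak.name,
        chrom=peak.chrom,
        offset=lo,
    )


def conservation_score(
    hit: MotifHit, track: ConservationTrack, threshold: float = 0.90
) -> MotifHit:
    """Attach the mean per-base conservation over the matched core bases.

    Absent bases contribute 0 (unscored regions must not inflate the mean);
    the hit is conserved iff the mean is strictly greater than ``threshold``.
    """
    mean = track.mean_over(hit.chrom, hit.position, hit.end, absent_as=0.0)
    hit.mean_conservation = mean
    hit.conserved = mean > threshold
    return hit


def _is_rc_palindrome(s: str) -> bool:
    return len(s) % 2 == 0 and s == revcomp(s)


def detect_palindrome(
    seq: str,
    core_start: int,
    core_len: int,
    min_len: int = 6,
    max_span: int = 20,
) -> tuple[bool | None, str | None, int | None]:
    """Find a reverse-complement palindrome overlapping the matched core.

    Searches every window of length >= ``min_len`` lying within ``max_span``
    bp of the core (window start >= core_start - max_span, window end <=
    core_end + max_span, clamped to the sequence) that overlaps the core by
    at least one base and equals its own reverse complement. Returns
    (flag, palindrome, start): the longest such window, leftmost on ties.

    Returns (None, None, None) with a warning when the sequence cannot host
    any qualifying window (insufficient context).
    """
    seq = seq.upper()
    core_end = core_start + core_len
    lo = max(core_start - max_span, 0)
    hi = min(core_end + max_span, len(seq))
    if hi - lo < min_len:
        warnings.warn("insufficient context for palindrome detection")
        return None, None, None
    best: tuple[int, int] | None = None  # (length, start)
    max_len = hi - lo
    for length in range(max_len - max_len % 2, min_len - 1, -2):
        for start in range(lo, hi - length + 1):
            end = start + length
            if end <= core_start or start >= core_end:
                continue  # must overlap the core by >= 1 bp
            window = seq[start:end]
            if _is_rc_palindrome(window):
                best = (length, start)
                break
        if best:
            break
    if best is None:
        return False, None, None
    length, start = best
    return True, seq[start : start + length], start


def score_palindrome(
    hit: MotifHit,
    genome: Mapping[str, str],
    min_len: int = 6,
    max_span: int = 20,
) -> MotifHit:
    """Run :func:`detect_palindrome` around a genomic hit and attach the flag."""
    seq = str(genome[hit.chrom])
    core_len = hit.end - hit.position
    lo = max(hit.position - max_span - 1, 0)
    flag, pal, pos = detect_palindrome(
        seq[lo : hit.end + max_span + 1],
        hit.position - lo,
        core_len,
        min_len=min_len,
        max_span=max_span,
    )
    hit.palindrome = flag
    hit.palindrome_seq = pal
    hit.palindrome_pos = None if pos is None else pos + lo
    return hit


def associate_peaks_to_genes(
    peaks: Sequence[Peak],
    models: Sequence[GeneModel],
    window_bp: int = 5000,
) -> dict[str, list[tuple[str, int]]]:
    """Map each gene to the peaks whose summit lies within ``window_bp`` of
    any of its TSS (inclusive, absolute distance on the same chromosome).

    Returns ``{gene_id: [(peak_name, signed_min_distance), ...]}`` with only
    genes that have at least one associated peak; a peak may associate with
    several genes.
    """
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    out: dict[str, list[tuple[str, int]]] = {}
    for gene in models:
        assoc = []
        for p in by_chrom.get(gene.chrom, []):
            dist = min(
                ((p.summit - t) for t in gene.tss_list), key=abs
            )
            if abs(dist) <= window_bp:
                assoc.append((p.name, dist))
        if assoc:
            out[gene.gene_id] = assoc
    return out
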