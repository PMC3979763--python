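"""Core-motif scanning, conservation scoring, palindrome detection and
peak-to-gene association, validated against the printed probe sequences and
brute-force oracles."""

import itertools

import numpy as np
import pytest

from silencescan.core_io import ConservationTrack, GenomicInterval, Peak, revcomp
from silencescan.peaks_motifs import (
    CORE_MOTIF,
    EMSA_PROBES,
    associate_peaks_to_genes,
    conservation_score,
    detect_palindrome,
    filter_peaks,
    scan_motif,
    scan_sequence,
    score_palindrome,
)
from silencescan.core_io import GeneModel


def _peak(chrom, start, end, summit, height=20.0, name="p"):
    return Peak(GenomicInterval(chrom, start, end), summit, height, name)


class TestFilterPeaks:
    def test_boundary_inclusive(self):
        peaks = [_peak("c", 0, 10, 5, h, f"p{h}") for h in (11, 12, 13)]
        kept = filter_peaks(peaks, min_height=12)
        assert [p.height for p in kept] == [12, 13]

    def test_empty(self):
        assert filter_peaks([], 12) == []

    def test_brute_force_count(self):
        rng = np.random.default_rng(0)
        heights = rng.uniform(0, 30, 10_000)
        peaks = [_peak("c", 0, 10, 5, h) for h in heights]
        assert len(filter_peaks(peaks, 12)) == int((heights >= 12).sum())


class TestScanMotif:
    def test_probe_scans_match_binding_pattern(self):
        # The shift assay showed binding for the wild-type, the palindrome
        # variant and the Igf2 probe; the point-mutant and deletion probes
        # lost the core and do not bind.
        expected_hits = {
            "Igf2_wt": 1,
            "Twist2_wt": 1,
            "Twist2_mut": 0,
            "Twist2_pal": 1,
            "Twist2_del": 0,
        }
        for name, seq in EMSA_PROBES.items():
            hits = scan_sequence(seq, summit=len(seq) // 2, flank=100)
            assert len(hits) == expected_hits[name], name
            for h in hits:
                assert h.strand == "+"
                assert h.matched_seq == CORE_MOTIF
                assert seq[h.position : h.position + 5] == CORE_MOTIF

    def test_wildtype_probe_has_extended_heptamer(self):
        (hit,) = scan_sequence(EMSA_PROBES["Twist2_wt"], summit=19, flank=100)
        assert hit.extended_match  # GGCTCGC covers the core

    def test_window_boundary_inclusive(self):
        # core start exactly at summit - flank is reported; one base further out is not
        flank = 100
        backbone = "A" * 400
        for offset, expect in [(-flank, 1), (-flank - 1, 0), (flank, 1), (flank + 1, 0)]:
            summit = 200
            pos = summit + offset
            seq = backbone[:pos] + CORE_MOTIF + backbone[pos + 5 :]
            hits = scan_sequence(seq, summit=summit, flank=flank)
            assert len(hits) == expect, offset

    def test_brute_force_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            summit = int(rng.integers(50, 250))
            flank = int(rng.integers(10, 100))
            hits = scan_sequence(seq, summit=summit, flank=flank)
            expected = []
            for i in range(len(seq) - 4):
                if abs(i - summit) > flank:
                    continue
                win = seq[i : i + 5]
                if win == CORE_MOTIF:
                    expected.append((i, "+"))
                if win == revcomp(CORE_MOTIF):
                    expected.append((i, "-"))
            assert sorted((h.position, h.strand) for h in hits) == sorted(expected)

    def test_strand_consistency_on_genome(self, small_study):
        # scanning the reverse-complemented chromosome yields the mirrored hit set
        chrom = small_study.peaks[0].chrom
        seq = small_study.genome[chrom]
        peak = small_study.peaks[0]
        hits = scan_motif(peak, {chrom: seq})
        L = len(seq)
        rc_peak = _peak(
            chrom, L - peak.interval.end, L - peak.interval.start, L - 1 - peak.summit
        )
        rc_hits = scan_motif(rc_peak, {chrom: revcomp(seq)})
        mirrored = sorted(
            (L - h.position - 5, "-" if h.strand == "+" else "+") for h in rc_hits
        )
        assert sorted((h.position, h.strand) for h in hits) == mirrored

    def test_missing_chromosome_errors(self):
        with pytest.raises(KeyError):
            scan_motif(_peak("chrX", 0, 10, 5), {"chr1": "ACGT"})


class TestConservation:
    def _hit(self, pos=10):
        hits = scan_sequence("A" * 10 + CORE_MOTIF + "A" * 10, summit=12, flank=100)
        return hits[0]

    def test_fully_conserved(self):
        track = ConservationTrack({"": np.ones(30)})
        hit = conservation_score(self._hit(), track)
        assert hit.mean_conservation == 1.0 and hit.conserved

    def test_boundary_is_strict(self):
        track = ConservationTrack({"": np.full(30, 0.90)})
        hit = conservation_score(self._hit(), track)
        assert hit.mean_conservation == pytest.approx(0.90)
        assert not hit.conserved

    def test_absent_bases_count_as_zero(self):
        arr = np.full(30, np.nan)
        arr[10:13] = 1.0  # 3 of 5 core bases scored
        hit = conservation_score(self._hit(), ConservationTrack({"": arr}))
        assert hit.mean_conservation == pytest.approx(3 / 5)

    def test_matches_independent_averaging_on_simulation(self, small_study):
        truth = small_study.truth.motifs
        for _, row in truth.iloc[::5].iterrows():
            hits = scan_sequence(
                small_study.genome[row.chrom],
                summit=int(row.position),
                flank=0,
                peak_id=row.peak_name,
                chrom=row.chrom,
            )
            target = [h for h in hits if h.position == row.position]
            assert target, "planted motif must be rediscovered"
            hit = conservation_score(target[0], small_study.conservation)
            arr = small_study.conservation.data[row.chrom][row.position : row.position + 5]
            manual = np.where(np.isnan(arr), 0.0, arr).mean()
            assert hit.mean_conservation == pytest.approx(manual)


class TestPalindrome:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("Igf2_wt", True),
            ("Twist2_wt", False),
            ("Twist2_pal", True),
        ],
    )
    def test_probe_palindromes(self, name, expected):
        seq = EMSA_PROBES[name]
        (hit,) = scan_sequence(seq, summit=len(seq) // 2, flank=100)
        flag, pal, _pos = detect_palindrome(seq, hit.position, 5)
        assert flag is expected, name
        if expected:
            # the hexamer palindrome (or a longer palindrome containing it):
            # the Igf2 probe's longest is the 8-mer GCCTAGGC
            assert "CCTAGG" in pal

    def test_insufficient_context_undefined(self):
        with pytest.warns(UserWarning, match="insufficient"):
            flag, _, _ = detect_palindrome("GCTCG", 0, 5, min_len=6, max_span=0)
        assert flag is None

    def test_brute_force_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(300):
            seq = "".join(rng.choice(list("ACGT"), size=60))
            core_start = int(rng.integers(5, 50))
            flag, pal, pos = detect_palindrome(seq, core_start, 5)
            # exhaustive: every window (any length >= 6, odd included) in range
            found = []
            lo, hi = max(core_start - 20, 0), min(core_start + 5 + 20, len(seq))
            for length in range(6, hi - lo + 1):
                for s in range(lo, hi - length + 1):
                    w = seq[s : s + length]
                    if s + length <= core_start or s >= core_start + 5:
                        continue
                    if w == revcomp(w):
                        found.append((length, s))
            assert flag == bool(found)
            if found:
                best_len = max(l for l, _ in found)
                best_start = min(s for l, s in found if l == best_len)
                assert (len(pal), pos) == (best_len, best_start)

    def test_all_palindromic_hexamer_plants_detected(self):
        # plant every reverse-complement-closed hexamer right before the core
        wt = EMSA_PROBES["Twist2_wt"]
        (hit,) = scan_sequence(wt, summit=len(wt) // 2, flank=100)
        start = hit.position - 5  # overlaps the core's leading base
        n_pal = 0
        for combo in itertools.product("ACGT", repeat=3):
            half = "".join(combo)
            hexamer = half + revcomp(half)
            assert hexamer == revcomp(hexamer)
            edited = wt[:start] + hexamer + wt[start + 6 :]
            flag, _, _ = detect_palindrome(edited, hit.position, 5)
            assert flag is True, hexamer
            n_pal += 1
        assert n_pal == 64

    def test_score_palindrome_on_genome(self, small_study):
        truth = small_study.truth.motifs
        planted = truth[truth.palindrome]
        assert len(planted) > 0
        for _, row in planted.iterrows():
            hits = scan_sequence(
                small_study.genome[row.chrom], summit=int(row.position), flank=0,
                chrom=row.chrom,
            )
            hit = [h for h in hits if h.position == row.position][0]
            hit = score_palindrome(hit, small_study.genome)
            assert hit.palindrome is True


class TestAssociation:
    def _models(self):
        return [
            GeneModel("g1", "chr1", "+", [(10_000, 12_000)], [10_000]),
            GeneModel("g2", "chr1", "-", [(40_000, 42_000)], [41_999]),
        ]

    def test_summit_at_tss(self):
        peaks = [_peak("chr1", 9_900, 10_100, 10_000)]
        gpm = associate_peaks_to_genes(peaks, self._models())
        assert gpm == {"g1": [("p", 0)]}

    def test_window_boundary_inclusive(self):
        at = _peak("chr1", 14_900, 15_100, 15_000, name="at")  # distance 5000
        beyond = _peak("chr1", 14_901, 15_101, 15_001, name="beyond")  # 5001
        gpm = associate_peaks_to_genes([at, beyond], self._models(), window_bp=5000)
        assert [n for n, _ in gpm["g1"]] == ["at"]

    def test_brute_force_on_simulation(self, small_study):
        gpm = associate_peaks_to_genes(small_study.peaks, small_study.models, 5000)
        for gene in small_study.models[::11]:
            expected = []
            for p in small_study.peaks:
                if p.chrom != gene.chrom:
                    continue
                d = min((abs(p.summit - t) for t in gene.tss_list))
                if d <= 5000:
                    expected.append(p.name)
            got = [n for n, _ in gpm.get(gene.gene_id, [])]
            assert sorted(got) == sorted(expected)

    def test_peak_near_planted_gene_is_associated(self, small_study):
        truth = small_study.truth.genes
        gpm = associate_peaks_to_genes(small_study.peaks, small_study.models, 5000)
        for gid, row in truth[truth.has_peak].iterrows():
            assert row.peak_name in [n for n, _ in gpm.get(gid, [])]
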