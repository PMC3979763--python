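"""Scan the printed gel-shift probe sequences for the binding core.

The five probes (Igf2 wild type; Twist2 wild type, point mutant, deletion
and palindrome variant) encode the assay's design: the core GCTCG is present
in exactly the three probes the factor binds, and a reverse-complement
palindrome overlapping the core marks the two "repressor-context" probes.
"""

from silencescan.peaks_motifs import EMSA_PROBES, detect_palindrome, scan_sequence

for name, seq in EMSA_PROBES.items():
    hits = scan_sequence(seq, summit=len(seq) // 2, flank=100)
    if not hits:
        print(f"{name:12s} no core motif")
        continue
    hit = hits[0]
    flag, pal, _ = detect_palindrome(seq, hit.position, 5)
    print(
        f"{name:12s} core at {hit.position:2d} ({hit.strand}), "
        f"extended 7-mer: {hit.extended_match}, palindrome: {flag}"
        + (f" ({pal})" if flag else "")
    )
# Binding (core present) is lost in the mut/del probes; the palindrome flag
# separates the Igf2-type (repressed) from the Twist2-type (activated) site.
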