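# silencescan

Analysis toolkit for transcription-factor knockdown studies that combine
two-condition RNA-seq, binding-site ChIP-seq and histone-modification
ChIP-seq — the design used to characterise regulators such as ZBED6 in
mouse C2C12 myoblasts: silence the factor with siRNA, sequence silenced and
control transcriptomes at two timepoints, and ask which genes respond,
whether responders carry binding sites near their TSS, whether those sites
are evolutionarily conserved or palindromic, and how active histone marks
shift after silencing.

The package is a library plus an `examples/` directory of narrative
scripts; a fully self-consistent synthetic-study generator with known
ground truth stands in for deposited sequencing data.

## The statistics at the core

**Differential expression (MA-plot random-sampling test).** Each gene's
count in a library of n mapped reads is modelled as C ~ Bin(n, p). With
X = log2 C1 (silenced), Y = log2 C2 (control), M = X − Y and
A = (X + Y)/2, the delta method gives X ≈ N(log2(n1 p), (1−p)/(n1 p ln²2)),
and conditioning the resulting bivariate normal on A yields

    E(M | A = a) = (μX − μY) + 2(σX² − σY²)/(σX² + σY²) · (a − (μX + μY)/2)
    Var(M | A)   = 4 σX² σY² / (σX² + σY²)

with the pooled null estimate p̂ = (C1 + C2)/(n1 + n2). The standardized
z = (M − E(M|A)) / √Var(M|A) is referred to the two-sided normal tail, and
Benjamini–Hochberg adjustment controls the FDR. A gene is called DE when
(i) its day-2 q-value is below 0.001, (ii) its library-size-adjusted fold
change is at least 1.5, and (iii) day 4 shows the same direction of change.

**Binding-site association.** MACS-style peaks (height ≥ 12) are associated
with genes whose TSS lies within 5 kb of the summit; the 2×2 table of
site-presence against DE status is tested by a Pearson chi-square (df = 1),
with Fisher's exact test for small cells. The core recognition site GCTCG
(extended GGCTCGC) is scanned within ±100 bp of each summit on both
strands; a hit is conserved when its mean per-base phastCons score exceeds
0.90, and flagged palindromic when a reverse-complement-equal window of
≥ 6 bp overlaps the core — the feature that separates repressed from
activated targets.

**Histone footprints.** Signal tracks (bedGraph/wiggle, MAPQ > 10 at
import) are averaged in 50-bp bins over 3.5-kb windows around anchor sets,
strand-aware and depth-normalised to reads per 10⁷. Per-gene counts in the
2-kb window downstream of the TSS (for multi-TSS genes, the TSS with the
highest H3K4me3 control count) give silenced/control ratios normalised so
the non-DE gene set is centred at 1; up- vs non-DE ratio shifts are tested
by Mann-Whitney.

## Worked example

```
$ python examples/03_peak_enrichment.py
published: 29.8% of DE vs 24.7% of non-DE genes have a site; chi2=8.47, p=0.004
simulated (odds 3 planted at up-regulated genes): 44.9% vs 26.2%, odds ratio 2.30, p=0.0041
```

The first line recomputes the published contingency analysis from its
printed counts: 29.8% of differentially expressed genes carry a binding
site within 5 kb of the TSS against 24.7% of expressed non-DE genes, an
enrichment with chi-square p = 0.004. The second line runs the same test on
a simulated study in which the association is planted at odds ratio 3 for
up-regulated genes and recovers it.

```
$ python examples/02_motif_scan_probes.py
Igf2_wt      core at 10 (+), extended 7-mer: True, palindrome: True (GCCTAGGC)
Twist2_wt    core at 17 (+), extended 7-mer: True, palindrome: False
Twist2_mut   no core motif
Twist2_pal   core at 17 (+), extended 7-mer: True, palindrome: True (GCCTAGGC)
Twist2_del   no core motif
```

The five printed gel-shift probes behave exactly as designed: the core is
found only in the three probes the factor binds, and the palindrome flag
marks the two repressor-context probes (the natural Igf2 site and the
Twist2 variant engineered to carry the same palindrome).

The other examples cover simulation plus DE calling (`01`), histone
footprints and ratio tests (`04`), and RPKM/qPCR arithmetic (`05`).

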