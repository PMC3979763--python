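# Methods

## The differential-expression model

The test treats each gene's read count as a binomial draw from its library:
C ~ Bin(n, p) with n the total mapped reads and p the gene's true sampling
proportion ("random sampling"). Writing X = log2 C1, Y = log2 C2 for the
silenced and control counts, the delta method gives
X ≈ N(log2(n1 p), (1−p)/(n1 p ln²2)) and likewise for Y. The statistic is
M = X − Y conditioned on A = (X + Y)/2; because (M, A) is a linear map of
(X, Y), the conditional moments are the exact bivariate-normal conditioning
of the delta-method approximation:

    Cov(M, A) = (σX² − σY²)/2,  Var(A) = (σX² + σY²)/4
    E(M | A=a) = (μX − μY) + 2(σX² − σY²)/(σX² + σY²)(a − (μX + μY)/2)
    Var(M | A) = 4 σX² σY² / (σX² + σY²)

These identities were re-derived symbolically before implementation and the
numerical behaviour checked against the exact conditional binomial
(C1 | C1+C2 = s ~ Bin(s, n1/(n1+n2))). The null proportion is estimated
pooled, p̂ = (C1+C2)/(n1+n2); the two-sided p comes from the normal tail
with no continuity correction, matching the conditional-normal model.

Known behaviour of the approximation, measured against the exact
conditional test:

* **Moderate significance** (p ≳ 10⁻³, count ratios ≲ 1.25 at any depth):
  |Δlog10 p| ≲ 0.05–0.15.
* **Far tail**: the log-scale curvature of M makes the normal z overstate
  significance; at counts (200, 100) the normal p is 1.9e-9 against an
  exact 8.0e-9 (Δlog10 ≈ 0.62), growing with |z|. Ranking is essentially
  unaffected; fixed-α decisions at the stringent FDR gate are conservative
  to this direction of error only in the sense that both p-values are far
  below any practical threshold.
* **Discreteness**: at mean count λ the two-sided p-value has an atom at 1
  of mass P(C1 = C2) ≈ (4πλ)^(−1/2) (≈ 0.028 at λ = 100). Type-I error at
  α = 0.05 is calibrated (measured 0.051 at 10⁵ null simulations,
  n = 10⁷, p = 10⁻⁵), but the Kolmogorov–Smirnov distance of the null
  p-value distribution from Uniform(0,1) is bounded below by that atom, so
  it plateaus near 0.028 regardless of simulation size.

**Zero handling.** If both counts are zero the gene is untested; if exactly
one is zero, 0.5 is substituted before the logs and the gene flagged (and
excluded from correlation analyses). This keeps M finite without inventing
precision.

**The composite call.** Up/down status requires (i) day-2 BH q < 0.001,
(ii) |M − log2(n1/n2)| ≥ log2 1.5, (iii) sign agreement with day 4. The
fold-change gate uses the library-size-adjusted M: raw count ratios
conflate sequencing depth with expression, and with equal depths the
adjustment is a no-op. The FDR gate is applied to day 2 only; day 4
contributes the direction, reflecting the design in which the later
timepoint accumulates secondary effects.

## Motif, conservation and palindrome calls

Scanning reports every occurrence of the 5-mer core GCTCG whose start lies
within ±100 bp (inclusive) of the peak summit, on both strands by default
(minus-strand hits are reverse-complement occurrences on the forward
sequence); the extended flag marks hits covered by the 7-mer GGCTCGC. The
core, flank and extended motif are parameters, so the alternative spelling
that appears once in the source literature (GTCTG) can be scanned
explicitly if desired.

Conservation is the arithmetic mean of per-base scores over the five core
bases only; unscored bases count as 0 so that sparse tracks cannot inflate
the mean, and "conserved" requires mean > 0.90 strictly.

A palindrome is a window of ≥ 6 bp, equal to its own reverse complement,
overlapping the matched core by ≥ 1 bp, with the search bounded 20 bp
either side of the core (clamped at sequence ends). The longest such
window is reported, leftmost on ties; odd-length windows can never satisfy
reverse-complement equality and are skipped. The flag is undefined only
when the sequence cannot host any qualifying window — clamping (rather
than refusing) at sequence edges is required for short probe sequences,
and the definition is validated against all five printed gel-shift probes:
core present in exactly {Igf2 wt, Twist2 wt, Twist2 pal}, palindrome in
exactly {Igf2 wt, Twist2 pal} (where the longest palindrome is the 8-mer
GCCTAGGC containing CCTAGG).

## Enrichment statistics

The DE-versus-binding contingency restricts both columns to an explicit
expressed-gene universe (the caller supplies any annotation filtering,
e.g. removal of small non-coding RNAs). Pearson chi-square (df = 1) is
computed without Yates correction by default: on the published table the
corrected and uncorrected p both round to the printed 0.004, and expected
counts there are large. The correction flag exists because at small counts
the discrete permutation null (label shuffling with fixed margins) is
tracked by the Yates-corrected p, not the uncorrected one — the test suite
pins both behaviours. Fisher's two-sided p sums hypergeometric point
probabilities ≤ that of the observed table (a tail-doubling variant is
behind a flag). Mann-Whitney uses exact enumeration when min(n) ≤ 8 with
no ties, otherwise the tie-corrected normal approximation with continuity
correction; the measured worst-case gap between the two on tie-free
samples with n ∈ [3, 8] is ≈ 0.037, so exact enumeration is always
preferred where feasible.

## Histone profiles

Signal is per-base coverage (bedGraph input; read-interval input is
filtered at MAPQ > 10 and summed per base, divided by read length to stay
commensurable with coverage tracks). Footprints use 50-bp bins over
±1750 bp (the 3.5-kb window), strand-aware, dropped near chromosome edges,
scaled to reads per 10⁷. Windowed TSS counts use [TSS, TSS+2000) on the
coding strand; for multi-TSS genes the TSS with the highest H3K4me3
control count downstream is selected (ties to the smallest coordinate).
The silenced/control ratio is normalised by a single global factor,
Σ_nonDE control / Σ_nonDE silenced, so a genome-wide efficiency difference
between libraries cancels; a per-gene median-ratio alternative was
considered and rejected as the default because the global factor is the
direct formalisation of "normalised to counts for all non-DE genes" and is
robust when many genes have low counts.

## The synthetic study generator

The generator emulates the statistical structure the pipeline is designed
to detect, with full determinism under a seed:

* **Annotation**: non-overlapping genes on both strands, 1–3 transcripts
  each (union-exon merging and multi-TSS selection are exercised), 1.5–4 kb
  spans at 12-kb spacing on two chromosomes, plus a 500-kb gene-free tail
  per chromosome that hosts background peaks.
* **Counts**: per sample, gene counts are independent Bin(n_s, p_gs) draws
  — deliberately the same sampling model the DE test assumes, so type-I
  error and recovery are interpretable; overdispersion robustness is a
  documented extension, not a default. Baselines are log-normal
  (log2 mean 8, sd 1.2 — a realistic 2–3 decade dynamic range in which
  ~99% of genes exceed 30 reads at the default depth), scaled so expressed
  genes capture 75% of each 10⁶-read library (the typical exonic fraction
  of such experiments). 10% of genes carry planted effects with
  |log2FC| ~ U(2, 3) in the silenced samples; day-2 and day-4 effects
  share their sign with probability (1+ρ)/2, ρ = 0.95 by default, so the
  cross-day direction gate costs ≈ 2.5% sensitivity. True proportions are
  only rescaled (with a warning) if they would sum above 1.
* **Peaks/motifs**: each up-regulated gene receives a peak within 4.4 kb
  of its TSS at 3× the background odds; other genes at the background rate
  0.246 (the published non-DE with-site fraction). Every gene peak carries
  a planted core insert (GGCTCGC, or CCTAGGCTCGC for the palindromic
  fraction, 50% by default) within ±90 bp of the summit on a random
  strand; 22% (the published conserved-peak fraction) get per-base
  conservation drawn from U(0.93, 1) over the motif against a U(0.05,
  0.55) background, making the planted conserved/non-conserved labels
  deterministic under the 0.90-mean threshold. Background sequence is
  uniform random, so chance core occurrences occur at the expected 4⁻⁵
  rate and are not removed.
* **Histone coverage**: flat baseline 1 read/base plus a Gaussian bump
  (σ = 300 bp) centred 120 bp downstream of each gene's active TSS
  (strand-aware), amplitude 15 reads/base at median expression and
  proportional to expression (capped at 20×); inactive TSS of multi-TSS
  genes get 20% bumps. In silenced tracks the amplitude of DE genes is
  multiplied by 2^(κ·effect) with coupling κ = 0.5 and the day-2 effect
  (the DE calls being compared against are day-2 gated). Per-base Poisson
  noise is applied last.

What the generator does **not** emulate: biological replicate variance
(the study pooled triplicates before sequencing), overdispersion,
GC/mappability bias, correlated gene programs, peak-calling noise
(peaks are consumed as given), alignment artefacts, and realistic genome
composition. Passing recovery tests therefore demonstrates correctness of
the statistical machinery under its own assumptions, not robustness to
real-data violations of them.

## Problem sizes and defaults

The default simulation (2,000 genes, four 10⁶-read libraries, ~12.5-Mb
genome, two marks × two conditions) runs the full pipeline in ~15 s; unit
tests use a 150-gene version of the same conditions. Null calibration uses
10⁵ binomial draws at n = 10⁷, p = 10⁻⁵ (mean count 100). The
TSS-selection heuristic is exact whenever alternative TSS are ≥ 2.5 kb
apart; closer TSS can inherit each other's signal bump through window
overlap, a geometric property of 2-kb windows against σ = 300 bumps rather
than an implementation artefact.

## Known limitations

* The normal conditional p-value diverges from the exact conditional
  binomial in the far tail (see above); downstream gates are rank-driven
  and unaffected, but absolute far-tail p-values should not be quoted.
* The enrichment universe filter ("expressed genes present in the
  annotation, minus small non-coding RNAs") is supplied by the caller;
  no RNA-class annotation ships with the package.
* Numeric RPKM bin edges for "high/medium" expression labels are a user
  choice; none are built in.
* Read-level simulation (FASTQ, alignment) and peak calling are out of
  scope; peaks, counts and tracks are the interchange formats.
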