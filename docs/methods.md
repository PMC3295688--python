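# Methods

This note records the statistical model behind each stage, the parameter
choices and their rationale, what the synthetic generator does and does
not emulate, and the numerical decisions made where the design was open.

## Coordinates and data model

All intervals are 0-based half-open (BED convention); interval length is
`end − start` and adjacent intervals do not overlap. The TSS of a
minus-strand transcript is its last transcribed base, `tx_end − 1`; the
choice matters only for off-by-one placement of flanks and is applied
consistently in annotation, simulation, and distance signs. N bases are
legal in genomes but any motif window containing one is skipped.

## Peak calling

The caller is a deliberately compact re-statement of the classic
model-based procedure for single-end short-read ChIP-seq:

1. **Fragment-shift model.** Sliding windows of 2×bandwidth (default
   600 bp, step bandwidth/3) whose tag count exceeds `mfold` (default 32)
   times the background window rate are merged into model regions. Within
   each region, *d* is the mode of reverse-strand 5' positions minus the
   mode of forward-strand 5' positions, and the model *d* is the median
   over regions. Modes are taken from a boxcar-smoothed (41-bp window)
   position histogram, ties leftmost; regions need ≥ 5 tags per strand
   and a positive mode difference. The background window rate is the
   **median** sliding-window count floored at one tag, not the mean: on a
   megabase-scale genome a realistic site density puts a large fraction
   of the library into sites, so the mean is contaminated by the signal
   itself and an mfold filter against it would reject everything. The
   median is signal-robust and coincides with the mean in the sparse
   (real-genome) limit.
2. **Window scoring.** All tags are shifted *d*/2 toward their 3' ends.
   Each window's treatment count k is scored with the Poisson upper tail
   P(X ≥ k | λ), λ = max(control count × depth ratio, genome-wide
   treatment rate × window span). With no control, the genome-wide rate
   alone is used. There is no multi-scale local lambda and no
   duplicate-tag removal; these are documented simplifications.
3. **Peaks.** Overlapping significant windows merge and the merged extent
   is re-scored as one unit. The summit is the leftmost maximum of the
   pileup of d-length fragments centered on shifted tag positions.
4. **FDR.** Sample swap: peaks are called with treatment and control
   exchanged, and fdr(p) = (# swap peaks at ≤ p) / (# treatment peaks at
   ≤ p). Reported peaks satisfy p ≤ 1e-10 and FDR ≤ 1% (defaults).

Monotonicity (more treatment tags in a window never raise its p-value at
fixed λ) and the null behaviour (uniform treatment vs uniform control of
equal depth yields no peaks at p ≤ 1e-10 on a 1 Mb genome) are enforced
by tests.

## Annotation

Classification is by summit position only — the summit is the best
single-point estimate of the protein–DNA contact — with precedence
promoter > 5'UTR > exon > intron > 3'UTR > downstream > intergenic when
the summit touches features of several genes. Promoter and downstream
are 2 kb strand-aware flanks. UTRs are the exonic portions of
[txStart, cdsStart) and [cdsEnd, txEnd), strand-swapped for minus-strand
genes; "exon" therefore means coding exon. Signed TSS distances are
negative upstream (sign flipped for minus-strand genes); nearest gene by
absolute distance, ties to the lower-coordinate transcript. Random
background peak sets preserve the observed length multiset, draw
chromosomes proportional to length, place starts uniformly, and are
allowed to overlap anything — the null is deliberately unconstrained.

## Motif analysis

Discovery is an exhaustive k-mer ratio scan (default k = 9) rather than
an EM motif finder: every window is counted under reverse-complement
canonicalization (the lexicographically smaller of k-mer/revcomp), and
the winner maximizes observed / expected count, the expectation taken
from background sequences rescaled to the foreground window total plus a
+1 pseudocount in foreground units (so background-absent k-mers cannot
blow up). The pipeline's background is 10 per-sequence letter shuffles of
the peak sequences: composition-matched, signal-free, and enough draws
that the per-k-mer expectation is stable — a single draw lets junction
artifacts (a planted site plus one flanking base) occasionally outscore
the true element.

The PWM uses pseudocount 0.5: p(b) = (count + 0.5)/(n + 2). Windows are
scored s = Σᵢ log₂(pᵢ(bᵢ)/0.25); the uniform 0.25 scoring background is a
fixed convention, absorbed by the baseline standardization. The baseline
is the mean and SD of s over **every** usable genome window on **both**
strands, excluding windows that contain N or intersect CDS intervals
(the synthetic genome has no repeat track; a user-supplied mask BED can
be added to the exclusions). z = (s − μ)/σ with hit cutoff z ≥ 4.29, the
conventional stringent threshold for this statistic; the p-value reported
for a z is the standard-normal upper tail (≈ 9e-6 at 4.29). Overlapping
same-strand hits resolve greedily to the higher z, with score ties broken
toward the motif's own 5' end and z compared at 1e-9 resolution — this
makes the hit set exactly invariant under reverse-complementing the
genome, which a plain "leftmost" rule is not. Summit-to-site distance is
0 when the summit lies inside the site, else the distance to the nearer
edge base; the background comparator is one uniformly placed same-length
site per peak.

## Co-occupancy

A peak co-occupies when its interval, extended by `slop_bp` (default 0),
intersects a partner interval by ≥ 1 bp; half-open adjacency does not
count. Both directions (A-with-B, B-with-A) and the pair count are
reported because "fraction co-occupying" is ambiguous between them.
Significance re-places A's length multiset uniformly (chromosomes by
length, no exclusions) and reports the add-one empirical p
(1 + exceedances)/(resamples + 1), which is never exactly 0. Conditional
co-occupancy by feature class is available by filtering A on its
annotation before testing.

## KS running enrichment

The unweighted running sum walks the ranked list, +1/n_hits on set
members, −1/(N − n_hits) otherwise, so the curve ends exactly at 0. The
reported `es` is the deviation of maximum absolute value with sign
retained (earliest position on ties). The p-value tests the directional
hypothesis that set members concentrate at the **top** of the list — the
biologically meaningful direction for activation-ranked expression — as
the upper-tail exceedance of the maximum positive deviation (`es_max`)
under random hit placement: exact enumeration over all C(N, k)
placements when that count is ≤ 1e5, otherwise add-one Monte-Carlo
permutation. This one-sided-on-a-fixed-statistic form is exactly
calibrated (uniform null p), which a sign-conditioned two-sided variant
is not. Ranking by signed or absolute fold change is supported.

The hypergeometric overlap test takes the universe size as an explicit
required argument — it is never inferred from the inputs, because the
choice of universe dominates the p-value.

## Synthetic worlds

Defaults (the simulated study conditions): two chromosomes totalling
1 Mb at GC 0.42 (mammalian-like), 100 non-overlapping genes (transcripts
2–8 kb with exons, 5'UTR, CDS, 3'UTR), 200 planted copies of
5'-CCAAGGTCA-3' (reverse-complemented on minus placements, never
overlapping, planted by overwriting so gene coordinates stay valid), 24%
of them within 2 kb upstream of a TSS; per-site tag counts
Poisson(80) split evenly between strands, forward 5' ends at
center − d/2 and reverse 5' ends at center + d/2 with discretized normal
jitter of SD d/4 (d = 152), 39-bp reads; uniform background at 0.002
tags/bp on treatment and control alike (the control has no site signal);
expression fold changes standard normal with bound genes (site center
within 2 kb of the TSS) shifted up by 2. Everything is deterministic
under one seed; per-stage seeds derive from the global seed and the
stage name.

Scale rationale: 1 Mb with 200 sites keeps every stage under a few
seconds while giving ~50 promoter-proximal sites and ~140–150 called
peaks — enough for stable medians and fractions. The site density is
~50× that of a mammalian genome, which is exactly why the caller's
background estimate must be signal-robust (above), and why the pipeline's
default peak-to-gene window for the KS hit set is 2 kb rather than the
10 kb API default: at this gene density a 10 kb window assigns a peak to
essentially every gene and the KS statistic degenerates. On real-genome
inputs the 10 kb convention stands.

Not emulated: sequencing error and colour-space encoding, mappability
and repeat structure, duplicate reads, GC bias in fragment recovery,
correlated IgG background structure, and multi-isoform gene models. A
passing suite therefore demonstrates correctness of the statistics and
recovery machinery under idealized noise, not robustness to mapping
artifacts.

## Known limitations

* The peak caller is not output-compatible with production callers; it
  reproduces the procedure's logic at desk scale.
* k-mer discovery returns a single exact-width consensus; degenerate
  motifs (e.g. a GC-box) are only representable by re-running at other k.
* The co-occupancy null ignores genome structure (GC, mappability,
  chromatin state); empirical p-values are floored at 1/(resamples + 1).
* With no control track the FDR is reported as 0 because the sample-swap
  estimate is undefined.
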