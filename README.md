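# cistrokit

Downstream ChIP-seq analysis for monomeric nuclear-receptor cistromes —
the post-alignment half of a transcription-factor binding study, built as
a tested, reusable pipeline. It targets the kind of experiment in which a
liver-enriched receptor such as LRH-1 (NR5A2) is immunoprecipitated from
chromatin, short reads are aligned and exported as BED tags, and the
analyst needs to go from tags to biology: where are the binding peaks,
which genomic features do they occupy, what sequence element do they
contain, do they co-localize with a second factor's cistrome, and are the
bound genes enriched among differentially expressed genes?

## What it computes

* **Model-based peak calling.** The fragment shift *d* is estimated as
  the distance between the forward- and reverse-strand tag modes inside
  strongly enriched (≥ *mfold* × background) windows; tags are shifted by
  *d*/2 toward their 3' ends; sliding 2×bandwidth windows are scored with
  a Poisson upper tail P(X ≥ k | λ), λ the depth-scaled control count
  floored at the genome-wide rate; overlapping significant windows merge
  into peaks whose summit is the maximum of the shifted-tag pileup, and
  the FDR at each p-value is estimated by swapping treatment and control.
  Defaults: mfold 32, bandwidth 300 bp, p ≤ 1e-10, FDR ≤ 1%.
* **Feature annotation.** Each peak summit is classified into
  promoter / 5'UTR / exon / intron / 3'UTR / downstream / intergenic
  (promoter and downstream are 2 kb strand-aware flanks), with signed
  summit-to-nearest-TSS distances and size-matched randomized background
  peak sets for comparison.
* **Motif analysis.** An exhaustive reverse-complement-canonicalized
  k-mer enrichment scan (k = 9) stands in for a motif finder; a PWM built
  from the occurrences scores windows as Σᵢ log₂(pᵢ(bᵢ)/0.25), and scores
  are standardized by the genome-wide mean and SD over all windows
  outside coding regions: z = (s − μ)/σ, hit cutoff z ≥ 4.29. Summit-to-
  best-site distances are compared with an arbitrarily placed same-length
  site per peak.
* **Co-occupancy.** Fraction of A peaks intersecting a second peak set B,
  with an empirical p-value from re-placing A's length multiset uniformly
  at random (add-one rule).
* **KS expression enrichment.** Running-sum statistic over a fold-change-
  ranked gene list (+1/n_hits on ChIP-proximal genes, −1/(N−n_hits)
  otherwise); significance by permutation of hit positions, exact
  enumeration when feasible. A hypergeometric upper-tail test covers
  gene-list overlaps against an explicit universe.
* **Synthetic ground truth.** A generator plants the NR half-site
  5'-CCAAGGTCA-3' in a random genome (24% of sites within 2 kb upstream
  of a TSS), simulates bimodal strand-shifted tags (d = 152 bp, 39-bp
  reads) plus an IgG-like control, and shifts the expression fold change
  of bound genes — so every stage is testable against a known answer.

## Worked example

Run the full pipeline on a synthetic world from one seed:

```
cistrokit run-all --seed 7 --outdir out/
```

or in Python:

```python
from cistrokit.pipeline import run_pipeline
report = run_pipeline({"seed": 7}, "out/")
```

The run report (`out/report.json`) from this exact invocation contains:

```
peaks.fragment_shift_d      153      # planted value: 152 bp
peaks.n_peaks               140
peaks.recovery              {"site_recovery": 0.955, "peak_precision": 1.0}
annotation.fractions        {"promoter": 0.336, ..., "intergenic": 0.214}
motif.consensus             "CCAAGGTCA"
motif.fraction_peaks_with_hit  1.0   # at z >= 4.29
cooccupancy.empirical_p     0.01     # = 1/(99+1), the resampling floor
ks.es                       0.466
ks.p_perm                   0.007
```

Reading it: the strand-shift model recovered the planted 152-bp fragment
shift to within 1 bp; 95.5% of planted half-sites fall inside a called
peak and every called peak contains a planted site; the enriched 9-mer is
exactly the planted NR half-site, present at z ≥ 4.29 in every peak; the
peak set co-localizes with the planted site intervals more than any of 99
size-matched random placements; and the genes near peaks are enriched at
the top of the simulated expression ranking (positive enrichment score,
permutation p = 0.007).

Individual stages are also exposed as subcommands (`simulate`,
`callpeaks`, `annotate`, `motif`, `cooccupy`, `ksenrich`) over BED /
FASTA / TSV files, and as plain library functions.

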