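"""Peak-to-feature annotation, summit-to-TSS distances, and randomized
background peak sets.

A peak is classified by its summit position. When the summit hits features
of multiple genes the precedence is
promoter > 5'UTR > exon > intron > 3'UTR > downstream; anything else is
intergenic. Flanks are strand-aware: the promoter is 5' of the TSS and
"downstream" is 3' of the transcript end. The 5'UTR is the exonic part of
[txStart, cdsStart) on the + strand (strand-swapped for - genes), the
3'UTR likewise; "exon" means the coding exon portion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import GeneModel, GenomeSequence, Peak, intervals_overlap

FEATURE_CLASSES = (
    "promoter", "utr5", "exon", "intron", "utr3", "downstream", "intergenic",
)
_PRECEDENCE = {c: i for i, c in enumerate(FEATURE_CLASSES)}


@dataclass
class AnnotationConfig:
    promoter_bp: int = 2000
    downstream_bp: int = 2000
    gene_window_bp: int = 10_000

    def __post_init__(self):
        if min(self.promoter_bp, self.downstream_bp, self.gene_window_bp) <= 0:
            raise ValueError("annotation window sizes must be > 0")


@dataclass
class AnnotationSummary:
    counts: dict[str, int]
    n_peaks: int

    @property
    def fractions(self) -> dict[str, float]:
        if self.n_peaks == 0:
            return {c: 0.0 for c in FEATURE_CLASSES}
        return {c: self.counts.get(c, 0) / self.n_peaks for c in FEATURE_CLASSES}


@dataclass
class PeakAnnotation:
    peak: Peak
    feature: str
    nearest_gene: str | None
    tss_distance: float  # signed bp; NaN when no same-chromosome gene exists


def _gene_feature_at(gene: GeneModel, pos: int, config: AnnotationConfig) -> str | None:
    """Feature class of ``pos`` relative to one gene, or None."""
    if gene.strand == "+":
        prom = (gene.tx_start - config.promoter_bp, gene.tx_start)
        down = (gene.tx_end, gene.tx_end + config.downstream_bp)
        utr5_span = (gene.tx_start, gene.cds_start)
        utr3_span = (gene.cds_end, gene.tx_end)
    else:
        prom = (gene.tx_end, gene.tx_end + config.promoter_bp)
        down = (gene.tx_start - config.downstream_bp, gene.tx_start)
        utr5_span = (gene.cds_end, gene.tx_end)
        utr3_span = (gene.tx_start, gene.cds_start)

    if prom[0] <= pos < prom[1]:
        return "promoter"
    if gene.tx_start <= pos < gene.tx_end:
        in_exon = any(s <= pos < e for s, e in gene.exon_blocks)
        if not in_exon:
            return "intron"
        if utr5_span[0] <= pos < utr5_span[1]:
            return "utr5"
        if utr3_span[0] <= pos < utr3_span[1]:
            return "utr3"
        return "exon"
    if down[0] <= pos < down[1]:
        return "downstream"
    return None


def classify_peaks(
    peaks: list[Peak],
    gene_models: list[GeneModel],
    config: AnnotationConfig | None = None,
) -> tuple[AnnotationSummary, list[PeakAnnotation]]:
    """Classify each peak summit into exactly one feature class and attach
    the nearest-TSS gene and signed distance."""
    config = config or AnnotationConfig()
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).append(g)

    annotations = []
    counts = {c: 0 for c in FEATURE_CLASSES}
    for peak in peaks:
        best = "intergenic"
        for gene in by_chrom.get(peak.chrom, []):
            feat = _gene_feature_at(gene, peak.summit, config)
            if feat is not None and _PRECEDENCE[feat] < _PRECEDENCE[best]:
                best = feat
        gene_id, dist = _nearest_tss(peak, by_chrom.get(peak.chrom, []))
        counts[best] += 1
        annotations.append(PeakAnnotation(peak, best, gene_id, dist))
    return AnnotationSummary(counts, len(peaks)), annotations


def _nearest_tss(peak: Peak, genes: list[GeneModel]) -> tuple[str | None, float]:
    if not genes:
        return None, float("nan")
    best = min(
        genes, key=lambda g: (abs(peak.summit - g.tss), min(g.tx_start, g.tx_end))
    )
    if best.strand == "+":
        dist = peak.summit - best.tss
    else:
        dist = best.tss - peak.summit  # negative = upstream of a - gene
    return best.gene_id, float(dist)


def summit_to_tss_distances(
    peaks: list[Peak], gene_models: list[GeneModel]
) -> list[float]:
    """Signed summit-to-nearest-TSS distance per peak (negative = upstream).

    Distance is NaN for peaks on chromosomes without any gene model.
    """
    if not gene_models:
        raise ValueError("at least one gene model is required")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).append(g)
    return [
        _nearest_tss(p, by_chrom.get(p.chrom, []))[1] for p in peaks
    ]


def tss_distance_histogram(
    distances: list[float], bin_bp: int = 1000, max_bp: int = 10_000
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of signed TSS distances over [-max_bp, max_bp]."""
    finite = np.array([d for d in distances if np.isfinite(d)])
    edges = np.arange(-max_bp, max_bp + bin_bp, bin_bp)
    hist, _ = np.histogram(finite, bins=edges)
    return hist, edges


def random_background_peaks(
    genome: GenomeSequence,
    size_multiset: list[int],
    n_sets: int,
    seed: int,
) -> list[list[Peak]]:
    """Place peak sets with the given length multiset uniformly at random.

    Chromosomes are chosen proportional to length (restricted to those long
    enough to hold the peak), starts uniform over valid placements, summit
    at the interval midpoint. Placements may overlap one another.
    """
    rng = np.random.default_rng(seed)
    names = genome.chrom_names
    lengths = np.array([len(genome.chroms[c]) for c in names], dtype=float)
    if max(size_multiset, default=0) > lengths.max():
        raise ValueError("a requested size exceeds every chromosome length")
    sizes = np.asarray(size_multiset, dtype=np.int64)
    all_fit = sizes.max(initial=0) <= lengths.min()
    p_all = lengths / lengths.sum()
    sets = []
    for _ in range(n_sets):
        if all_fit:
            # every size fits every chromosome: fully vectorized draw
            ci = rng.choice(len(names), size=sizes.size, p=p_all)
            span = lengths[ci].astype(np.int64) - sizes + 1
            starts = (rng.random(sizes.size) * span).astype(np.int64)
            peaks = [
                Peak(names[c], int(s), int(s) + int(w), int(s) + int(w) // 2)
                for c, s, w in zip(ci, starts, sizes)
            ]
        else:
            peaks = []
            for size in size_multiset:
                ok = lengths >= size
                p = np.where(ok, lengths, 0.0)
                p /= p.sum()
                ci = int(rng.choice(len(names), p=p))
                start = int(rng.integers(0, int(lengths[ci]) - size + 1))
                peaks.append(
                    Peak(names[ci], start, start + size, start + size // 2)
                )
        sets.append(peaks)
    return sets
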