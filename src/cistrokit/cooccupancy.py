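"""Co-occupancy of two peak sets with size-matched resampling significance.

An A peak co-occupies with B when its interval, extended by ``slop_bp``
on each side, intersects some B interval by at least 1 bp (half-open
adjacency does not count). Significance is empirical: the A length
multiset is re-placed uniformly at random ``n_resamples`` times and the
add-one exceedance fraction of the co-occupancy count is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree

from .annotate import random_background_peaks
from .types import GenomeSequence, Peak


@dataclass
class OverlapResult:
    n_A: int
    n_B: int
    n_overlap_pairs: int
    n_A_with_B: int
    n_B_with_A: int
    fraction_A: float
    fraction_B: float
    slop_bp: int = 0
    empirical_p: float | None = None
    n_resamples: int = 0


def _build_trees(peaks: list[Peak]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)
    return trees


def _count_with(peaks: list[Peak], trees: dict[str, IntervalTree], slop: int):
    """(#peaks overlapping >=1 partner, #overlap pairs)."""
    n_with = 0
    n_pairs = 0
    for p in peaks:
        tree = trees.get(p.chrom)
        if tree is None:
            continue
        found = tree.overlap(p.start - slop, p.end + slop)
        if found:
            n_with += 1
            n_pairs += len(found)
    return n_with, n_pairs


def intersect_peaksets(
    set_A: list[Peak], set_B: list[Peak], slop_bp: int = 0
) -> OverlapResult:
    """Count co-occupying peaks and pairs in both directions."""
    if slop_bp < 0:
        raise ValueError("slop_bp must be >= 0")
    trees_B = _build_trees(set_B)
    trees_A = _build_trees(set_A)
    n_a_with, n_pairs = _count_with(set_A, trees_B, slop_bp)
    n_b_with, _ = _count_with(set_B, trees_A, slop_bp)
    return OverlapResult(
        n_A=len(set_A),
        n_B=len(set_B),
        n_overlap_pairs=n_pairs,
        n_A_with_B=n_a_with,
        n_B_with_A=n_b_with,
        fraction_A=n_a_with / len(set_A) if set_A else 0.0,
        fraction_B=n_b_with / len(set_B) if set_B else 0.0,
        slop_bp=slop_bp,
    )


def overlap_significance(
    set_A: list[Peak],
    set_B: list[Peak],
    genome: GenomeSequence,
    n_resamples: int = 999,
    seed: int = 0,
    slop_bp: int = 0,
) -> OverlapResult:
    """Empirical p-value for the observed A-with-B count against random
    placements of A's length multiset (add-one rule, never exactly 0)."""
    if n_resamples < 19:
        raise ValueError("n_resamples must be >= 19")
    result = intersect_peaksets(set_A, set_B, slop_bp)
    trees_B = _build_trees(set_B)
    sizes = [p.length for p in set_A]
    exceed = 0
    resamples = random_background_peaks(genome, sizes, n_resamples, seed)
    for fake_A in resamples:
        n_with, _ = _count_with(fake_A, trees_B, slop_bp)
        if n_with >= result.n_A_with_B:
            exceed += 1
    result.empirical_p = (1 + exceed) / (n_resamples + 1)
    result.n_resamples = n_resamples
    return result
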