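"""Peak-to-gene assignment, KS running-sum expression enrichment, and
hypergeometric gene-list overlap.

The KS statistic walks a rank-ordered gene list, stepping up 1/n_hits on
set members and down 1/(n_total - n_hits) otherwise; the running curve
therefore ends exactly at 0. ``es`` is the deviation of maximum absolute
value (sign retained, earliest position on ties). The p-value tests
enrichment of the set toward the TOP of the list: it is the (add-one)
upper-tail exceedance of the maximum positive deviation under random hit
placement. Exhaustive enumeration over all C(n, k) placements is used
when feasible; otherwise Monte-Carlo permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import hypergeom

from .types import ExpressionRecord, GeneModel, Peak


@dataclass
class KSResult:
    n_total: int
    n_hits: int
    running_curve: np.ndarray
    es: float           # signed extreme deviation
    es_max: float       # maximum positive deviation (tested statistic)
    p_perm: float
    n_permutations: int
    exhaustive: bool = False


@dataclass
class GeneSetOverlap:
    universe_size: int
    set1_size: int
    set2_size: int
    overlap: int
    p_hyper: float


def peaks_to_genes(
    peaks: list[Peak],
    gene_models: list[GeneModel],
    window_bp: int = 10_000,
    nearest_only: bool = False,
) -> set[str]:
    """Genes whose transcript interval extended by ``window_bp`` touches a
    peak. With ``nearest_only`` each peak contributes only its nearest
    gene (distance to the transcript interval, 0 when overlapping; ties
    to the lower-coordinate gene), still subject to the window."""
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).append(g)

    out: set[str] = set()
    if nearest_only:
        for p in peaks:
            best = None
            best_key = None
            for g in by_chrom.get(p.chrom, []):
                dist = max(g.tx_start - p.end + 1, p.start - g.tx_end + 1, 0)
                key = (dist, g.tx_start, g.gene_id)
                if best_key is None or key < best_key:
                    best, best_key = g, key
            if best is not None and best_key[0] <= window_bp:
                out.add(best.gene_id)
    else:
        for g in gene_models:
            lo, hi = g.tx_start - window_bp, g.tx_end + window_bp
            for p in peaks:
                if p.chrom == g.chrom and p.start < hi and lo < p.end:
                    out.add(g.gene_id)
                    break
    return out


def rank_expression(
    records: list[ExpressionRecord], absolute: bool = False
) -> list[ExpressionRecord]:
    """Return records ordered by descending (absolute) fold change with
    fresh 1-based ranks."""
    key = (lambda r: -abs(r.fold_change)) if absolute else (lambda r: -r.fold_change)
    ranked = sorted(records, key=key)
    return [
        ExpressionRecord(r.gene_id, r.fold_change, i)
        for i, r in enumerate(ranked, 1)
    ]


def _curve_stats(indicator: np.ndarray, n_hits: int) -> tuple[np.ndarray, float, float]:
    n = indicator.size
    up = 1.0 / n_hits
    down = 1.0 / (n - n_hits)
    curve = np.cumsum(np.where(indicator, up, -down))
    i_ext = int(np.argmax(np.abs(curve)))
    return curve, float(curve[i_ext]), float(curve.max())


def ks_running_enrichment(
    ranked_expression: list[ExpressionRecord],
    hit_gene_set: set[str],
    n_permutations: int = 999,
    seed: int = 0,
    exhaustive: bool | None = None,
) -> KSResult:
    """Running-sum enrichment of ``hit_gene_set`` in a ranked gene list.

    ``exhaustive=None`` auto-selects exact enumeration when
    C(n_total, n_hits) <= 100000.
    """
    ids = [r.gene_id for r in ranked_expression]
    if len(set(ids)) != len(ids):
        raise ValueError("ranked list contains duplicate gene ids")
    indicator = np.array([g in hit_gene_set for g in ids], dtype=bool)
    n = indicator.size
    k = int(indicator.sum())
    if k == 0 or k == n:
        raise ValueError("hit set must be a proper non-empty subset of the list")

    curve, es, es_max = _curve_stats(indicator, k)

    n_comb = comb(n, k)
    if exhaustive is None:
        exhaustive = n_comb <= 100_000
    if exhaustive:
        exceed = 0
        for positions in combinations(range(n), k):
            ind = np.zeros(n, dtype=bool)
            ind[list(positions)] = True
            _, _, em = _curve_stats(ind, k)
            if em >= es_max - 1e-12:
                exceed += 1
        p = exceed / n_comb
        return KSResult(n, k, curve, es, es_max, p, n_comb, exhaustive=True)

    rng = np.random.default_rng(seed)
    up = 1.0 / k
    down = 1.0 / (n - k)
    # vectorized: each row is one random hit placement
    order = np.argsort(rng.random((n_permutations, n)), axis=1)
    ind = np.zeros((n_permutations, n), dtype=bool)
    np.put_along_axis(ind, order[:, :k], True, axis=1)
    curves = np.cumsum(np.where(ind, up, -down), axis=1)
    es_null = curves.max(axis=1)
    exceed = int(np.sum(es_null >= es_max - 1e-12))
    p = (1 + exceed) / (n_permutations + 1)
    return KSResult(n, k, curve, es, es_max, p, n_permutations, exhaustive=False)


def hypergeometric_overlap(
    universe_size: int, set1, set2
) -> GeneSetOverlap:
    """Upper-tail hypergeometric p for the overlap of two gene sets drawn
    from an explicit universe. ``set1``/``set2`` may be collections of ids
    or integer sizes with the overlap given via collections only."""
    s1 = set(set1)
    s2 = set(set2)
    K, n = len(s1), len(s2)
    ov = len(s1 & s2)
    if K > universe_size or n > universe_size:
        raise ValueError("a set is larger than the universe")
    p = float(hypergeom.sf(ov - 1, universe_size, K, n))
    return GeneSetOverlap(universe_size, K, n, ov, min(p, 1.0))
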