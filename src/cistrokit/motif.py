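"""Motif discovery, PWM construction, genome-baseline z-score scanning,
and summit-to-site distances.

Discovery is an exhaustive k-mer enrichment scan (canonicalized over
reverse complement): the k-mer maximizing observed/expected frequency in
the peak sequences, with the expectation taken from background k-mer
frequencies. A PWM built from the aligned occurrences scores windows as

    score(w) = sum_i log2( p_i(w_i) / 0.25 )

and scores are standardized against the genome-wide mean and SD of the
same score over every usable window (both strands, windows overlapping
excluded regions or containing N are skipped). A window is a motif hit
when its z-score reaches the cutoff (default 4.29); the p-value reported
for a z is the standard-normal upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .types import DNA, GenomeSequence, Peak, revcomp


class DegenerateBaselineError(ValueError):
    """The PWM score has zero variance over the baseline windows."""


@dataclass
class PWM:
    """Position-dependent letter-probability matrix over {A,C,G,T}."""

    probs: np.ndarray  # shape (width, 4), rows sum to 1
    pseudocount: float

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM probs must have shape (width, 4)")
        if np.any(self.probs <= 0):
            raise ValueError("PWM probabilities must be > 0 (use a pseudocount)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(DNA[i] for i in np.argmax(self.probs, axis=1))

    @property
    def log_odds(self) -> np.ndarray:
        """log2(p/0.25) score matrix, shape (width, 4)."""
        return np.log2(self.probs / 0.25)

    def reverse_complement(self) -> "PWM":
        return PWM(self.probs[::-1, ::-1].copy(), self.pseudocount)


@dataclass
class BaselineStats:
    mean_score: float
    sd_score: float
    n_positions: int
    excluded_bp: int = 0

    def __post_init__(self):
        if self.sd_score <= 0:
            raise DegenerateBaselineError("baseline score SD must be > 0")
        if self.n_positions <= 0:
            raise ValueError("baseline must cover at least one window")

    def z(self, score):
        return (score - self.mean_score) / self.sd_score


@dataclass
class MotifHit:
    peak_name: str
    chrom: str
    start: int
    end: int
    strand: str
    score: float
    z: float
    p: float


@dataclass
class ScanConfig:
    z_cutoff: float = 4.29
    both_strands: bool = True

    def __post_init__(self):
        if not np.isfinite(self.z_cutoff):
            raise ValueError("z_cutoff must be finite")


# ---------------------------------------------------------------------------
# k-mer discovery

def _kmer_codes(seq_codes: np.ndarray, k: int) -> np.ndarray:
    """Base-4 integer code of every k-window without N; N windows dropped."""
    n = seq_codes.size - k + 1
    if n <= 0:
        return np.array([], dtype=np.int64)
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    vals = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for i in range(k):
        col = seq_codes[i : i + n].astype(np.int64)
        ok &= col < 4
        vals += np.where(col < 4, col, 0) * weights[i]
    return vals[ok]


def _revcomp_code(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement of base-4 k-mer codes, vectorized."""
    out = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        out = out * 4 + (3 - (tmp % 4))
        tmp //= 4
    return out


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(DNA[code % 4])
        code //= 4
    return "".join(reversed(out))


def _encode_seq(seq: str) -> np.ndarray:
    lut = np.full(128, 4, dtype=np.uint8)
    for i, c in enumerate(DNA):
        lut[ord(c)] = i
    lut[ord("N")] = 4
    return lut[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def _canonical_counts(seqs: list[str], k: int) -> tuple[dict[int, int], int]:
    """Counts of canonical (lexicographically smaller of kmer/revcomp)
    k-mer codes over all sequences, plus total windows counted."""
    total = 0
    counts: dict[int, int] = {}
    for seq in seqs:
        codes = _kmer_codes(_encode_seq(seq), k)
        if codes.size == 0:
            continue
        canon = np.minimum(codes, _revcomp_code(codes, k))
        total += canon.size
        uniq, cnt = np.unique(canon, return_counts=True)
        for u, c in zip(uniq.tolist(), cnt.tolist()):
            counts[u] = counts.get(u, 0) + c
    return counts, total


@dataclass
class KmerResult:
    consensus: str          # canonical form (lexicographically smaller)
    ratio: float            # observed / expected frequency
    n_occurrences: int
    occurrences: list[tuple[int, int, str]] = field(default_factory=list)
    # (sequence index, offset, strand); strand - means the canonical form
    # appears reverse-complemented at that offset


def find_enriched_kmer(
    peak_sequences: list[str],
    k: int,
    background_sequences: list[str],
) -> KmerResult:
    """Exhaustive k-mer enrichment: the canonical k-mer maximizing
    observed/expected frequency, expectation from the background.

    Both strands are counted via reverse-complement canonicalization. The
    expected count is the background frequency rescaled to the foreground
    window total plus a +1 pseudocount (in foreground-count units), so
    k-mers absent from the background cannot produce unbounded ratios.
    Supplying several background draws per peak (e.g. repeated shuffles)
    stabilizes the expectation.
    """
    if k < 4:
        raise ValueError("k must be >= 4")
    if len(peak_sequences) < 10:
        raise ValueError("need at least 10 peak sequences")
    if any(len(s) < k for s in peak_sequences):
        raise ValueError("every peak sequence must be at least k long")
    fg, fg_total = _canonical_counts(peak_sequences, k)
    bg, bg_total = _canonical_counts(background_sequences, k)
    if fg_total == 0 or bg_total == 0:
        raise ValueError("no scorable k-mer windows")

    scale = fg_total / bg_total
    best_code, best_ratio, best_count = -1, -1.0, 0
    for code, count in fg.items():
        expected = bg.get(code, 0) * scale + 1.0
        ratio = count / expected
        if ratio > best_ratio or (ratio == best_ratio and code < best_code):
            best_code, best_ratio, best_count = code, ratio, count

    consensus = _decode(best_code, k)
    rc = revcomp(consensus)
    occurrences = []
    for idx, seq in enumerate(peak_sequences):
        s = seq.upper()
        for off in range(len(s) - k + 1):
            window = s[off : off + k]
            if window == consensus:
                occurrences.append((idx, off, "+"))
            elif window == rc:
                occurrences.append((idx, off, "-"))
    return KmerResult(consensus, best_ratio, best_count, occurrences)


# ---------------------------------------------------------------------------
# PWM construction and scoring

def build_pwm(occurrences: list[str], pseudocount: float = 0.5) -> PWM:
    """PWM from aligned equal-length occurrence strings:
    p[i][b] = (count + pseudocount) / (n + 4*pseudocount)."""
    if not occurrences:
        raise ValueError("occurrence list is empty")
    w = len(occurrences[0])
    if any(len(o) != w for o in occurrences):
        raise ValueError("occurrences must all have the same length")
    counts = np.zeros((w, 4), dtype=float)
    for occ in occurrences:
        for i, base in enumerate(occ.upper()):
            counts[i, DNA.index(base)] += 1
    probs = (counts + pseudocount) / (len(occurrences) + 4 * pseudocount)
    return PWM(probs, pseudocount)


def _score_positions(codes: np.ndarray, log_odds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores of every window start on the given strand matrix; second
    return is the validity mask (windows free of N)."""
    w = log_odds.shape[0]
    n = codes.size - w + 1
    if n <= 0:
        return np.zeros(0), np.zeros(0, dtype=bool)
    scores = np.zeros(n, dtype=float)
    valid = np.ones(n, dtype=bool)
    padded = np.vstack([log_odds.T, np.zeros(w)])  # row 4 = N placeholder
    for i in range(w):
        col = codes[i : i + n].astype(np.int64)
        valid &= col < 4
        scores += padded[np.minimum(col, 4), i]
    return scores, valid


def genome_baseline(
    pwm: PWM,
    genome: GenomeSequence,
    excluded_regions: dict[str, list[tuple[int, int]]] | None = None,
) -> BaselineStats:
    """Mean and SD of the PWM score over every usable genome window.

    Both strands are scored. A window is skipped when it contains N or
    intersects an excluded region (typically CDS intervals). Raises
    :class:`DegenerateBaselineError` when the score variance is zero.
    """
    excluded_regions = excluded_regions or {}
    w = pwm.width
    lo_fwd = pwm.log_odds
    lo_rev = pwm.reverse_complement().log_odds
    n_tot = 0
    s1 = 0.0
    s2 = 0.0
    excluded_bp = 0
    for chrom in genome.chrom_names:
        codes = genome.codes(chrom)
        n = codes.size - w + 1
        if n <= 0:
            continue
        base_excl = np.zeros(codes.size, dtype=bool)
        for s, e in excluded_regions.get(chrom, []):
            base_excl[max(s, 0) : min(e, codes.size)] = True
        excluded_bp += int(base_excl.sum())
        # window usable iff no excluded base inside it
        cum = np.concatenate(([0], np.cumsum(base_excl)))
        win_ok = (cum[w:] - cum[:-w]) == 0
        for lo in (lo_fwd, lo_rev):
            scores, valid = _score_positions(codes, lo)
            use = valid & win_ok
            sel = scores[use]
            n_tot += sel.size
            s1 += float(sel.sum())
            s2 += float((sel * sel).sum())
    if n_tot < 1:
        raise ValueError("everything excluded: no usable baseline windows")
    mean = s1 / n_tot
    var = max(s2 / n_tot - mean * mean, 0.0)
    sd = float(np.sqrt(var))
    if sd == 0.0:
        raise DegenerateBaselineError("uniform PWM: baseline SD is zero")
    return BaselineStats(mean, sd, n_tot, excluded_bp)


@dataclass
class ScanSummary:
    hits: list[MotifHit]
    per_peak_count: dict[str, int]
    best_hit: dict[str, MotifHit]
    fraction_with_hit: float


def scan_peaks(
    peaks: list[Peak],
    genome: GenomeSequence,
    pwm: PWM,
    baseline: BaselineStats,
    scan_config: ScanConfig | None = None,
) -> ScanSummary:
    """Score every window inside each peak on both strands; report hits at
    z >= z_cutoff with overlapping same-strand hits greedily resolved to
    the higher z (ties leftmost)."""
    cfg = scan_config or ScanConfig()
    w = pwm.width
    lo_fwd = pwm.log_odds
    lo_rev = pwm.reverse_complement().log_odds
    hits: list[MotifHit] = []
    per_peak: dict[str, int] = {}
    best: dict[str, MotifHit] = {}
    n_with = 0
    for peak in peaks:
        L = len(genome.chroms[peak.chrom])
        if not (0 <= peak.start and peak.end <= L):
            raise ValueError(f"peak {peak.name} outside genome")
        codes = genome.codes(peak.chrom)[peak.start : peak.end]
        candidates: list[MotifHit] = []
        strand_mats = [("+", lo_fwd)]
        if cfg.both_strands:
            strand_mats.append(("-", lo_rev))
        for strand, lo in strand_mats:
            scores, valid = _score_positions(codes, lo)
            for off in np.flatnonzero(valid):
                z = baseline.z(scores[off])
                if z >= cfg.z_cutoff:
                    candidates.append(
                        MotifHit(
                            peak.name, peak.chrom,
                            peak.start + int(off), peak.start + int(off) + w,
                            strand, float(scores[off]), float(z),
                            float(norm.sf(z)),
                        )
                    )
        kept = _greedy_resolve(candidates)
        per_peak[peak.name] = len(kept)
        if kept:
            n_with += 1
            best[peak.name] = max(kept, key=lambda h: (h.z, -h.start))
        hits.extend(kept)
    frac = n_with / len(peaks) if peaks else 0.0
    return ScanSummary(hits, per_peak, best, frac)


def _greedy_resolve(candidates: list[MotifHit]) -> list[MotifHit]:
    """Keep highest-z hits, dropping lower-z hits that overlap a kept hit
    on the same strand. Score ties are broken toward the motif's 5' end on
    its own strand, so the resolution is invariant under reverse
    complementation of the genome. z is compared at 1e-9 resolution so
    mathematically equal scores tie regardless of summation order."""
    kept: list[MotifHit] = []
    for hit in sorted(
        candidates,
        key=lambda h: (-round(h.z, 9), h.start if h.strand == "+" else -h.start),
    ):
        clash = any(
            k.strand == hit.strand and hit.start < k.end and k.start < hit.end
            for k in kept
        )
        if not clash:
            kept.append(hit)
    kept.sort(key=lambda h: h.start)
    return kept


def summit_site_distances(
    best_hits: dict[str, MotifHit],
    peaks: list[Peak],
    seed: int = 0,
) -> tuple[list[int], list[int]]:
    """Distance from each peak summit to its best motif site, plus a
    background distance to one uniformly placed same-length site per peak.

    Distance is 0 when the summit lies inside the site, else the distance
    to the nearer site edge base.
    """
    rng = np.random.default_rng(seed)
    by_name = {p.name: p for p in peaks}
    real: list[int] = []
    background: list[int] = []
    for name, hit in best_hits.items():
        peak = by_name.get(name)
        if peak is None:
            raise ValueError(f"hit references unknown peak {name}")
        real.append(_site_distance(peak.summit, hit.start, hit.end))
        w = hit.end - hit.start
        hi = peak.end - w
        bg_start = int(rng.integers(peak.start, hi + 1)) if hi >= peak.start else peak.start
        background.append(_site_distance(peak.summit, bg_start, bg_start + w))
    return real, background


def _site_distance(summit: int, start: int, end: int) -> int:
    if start <= summit < end:
        return 0
    return min(abs(summit - start), abs(summit - (end - 1)))


def write_pwm(pwm: PWM, path) -> None:
    """4-column probability matrix text format (one row per position)."""
    with open(path, "w") as fh:
        fh.write("# A\tC\tG\tT\n")
        for row in pwm.probs:
            fh.write("\t".join(f"{p:.6f}" for p in row) + "\n")


def read_pwm(path, pseudocount: float = 0.0) -> PWM:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append([float(x) for x in line.split()])
    return PWM(np.array(rows), pseudocount)
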