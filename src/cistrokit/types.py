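"""Shared genomic data types and coordinate conventions.

All coordinates are 0-based, half-open ``[start, end)`` — the BED convention.
Interval length is always ``end - start``; two intervals overlap iff
``a.start < b.end and b.start < a.end``. Conversion to 1-based coordinates
happens only in human-readable reports, never internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DNA = "ACGT"
_CODE = {c: i for i, c in enumerate(DNA)}
_CODE["N"] = 4
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(COMPLEMENT)[::-1]


class GenomeSequence:
    """An in-memory genome: ordered chromosomes of uppercase A/C/G/T/N.

    Parameters
    ----------
    seqs : dict
        Ordered mapping of chromosome name to sequence string. Lowercase
        input is uppercased; characters outside {A,C,G,T,N} are rejected.
    """

    def __init__(self, seqs: dict[str, str]):
        if not seqs:
            raise ValueError("genome must contain at least one chromosome")
        self.chroms: dict[str, str] = {}
        for name, seq in seqs.items():
            if name in self.chroms:
                raise ValueError(f"duplicate chromosome name: {name}")
            s = seq.upper()
            if not s:
                raise ValueError(f"chromosome {name} is empty")
            bad = set(s) - set("ACGTN")
            if bad:
                raise ValueError(
                    f"illegal character(s) {sorted(bad)} in chromosome {name}"
                )
            self.chroms[name] = s
        self._codes: dict[str, np.ndarray] = {}

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chroms)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chroms.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chroms.values())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.chroms[chrom]
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(f"{chrom}:{start}-{end} outside chromosome bounds")
        return seq[start:end]

    def codes(self, chrom: str) -> np.ndarray:
        """Sequence as uint8 codes A=0 C=1 G=2 T=3 N=4 (cached)."""
        if chrom not in self._codes:
            raw = np.frombuffer(self.chroms[chrom].encode("ascii"), dtype=np.uint8)
            lut = np.full(128, 4, dtype=np.uint8)
            for base, code in _CODE.items():
                lut[ord(base)] = code
            self._codes[chrom] = lut[raw]
        return self._codes[chrom]

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeSequence) and self.chroms == other.chroms


@dataclass(frozen=True)
class Tag:
    """One aligned sequencing read as a strand-oriented genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid tag interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"tag strand must be + or -, got {self.strand!r}")

    @property
    def five_prime(self) -> int:
        """Position of the 5' base: start on +, end-1 on -."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class Peak:
    """An enriched region with a summit and enrichment statistics.

    ``score`` is the -log10 enrichment p-value; ``summit`` is an absolute
    coordinate strictly inside ``[start, end)``.
    """

    chrom: str
    start: int
    end: int
    summit: int
    score: float = 0.0
    fold_enrichment: float = 0.0
    fdr: float = 0.0
    name: str = ""

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid peak interval [{self.start},{self.end})")
        if not self.start <= self.summit < self.end:
            raise ValueError(
                f"summit {self.summit} outside peak [{self.start},{self.end})"
            )
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"fdr must be in [0,1], got {self.fdr}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """A transcript model (refFlat-like): strand, exons, CDS bounds.

    The TSS is the first transcribed base: ``tx_start`` on the + strand and
    ``tx_end - 1`` on the - strand.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exon_blocks: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.gene_id}: tx_start must be < tx_end")
        if not self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end:
            raise ValueError(f"{self.gene_id}: CDS outside transcript bounds")
        prev_end = self.tx_start - 1
        for s, e in self.exon_blocks:
            if s >= e:
                raise ValueError(f"{self.gene_id}: empty exon block [{s},{e})")
            if s < self.tx_start or e > self.tx_end:
                raise ValueError(f"{self.gene_id}: exon outside transcript")
            if s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons unsorted or overlapping")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tes(self) -> int:
        """Transcript end site (last transcribed base)."""
        return self.tx_end - 1 if self.strand == "+" else self.tx_start


@dataclass
class ExpressionRecord:
    """One gene in an expression table with its signed fold change and rank."""

    gene_id: str
    fold_change: float
    rank: int = 0


def validate_expression_ranks(records: list[ExpressionRecord]) -> None:
    """Check that ranks are a permutation of 1..N."""
    ranks = sorted(r.rank for r in records)
    if ranks != list(range(1, len(records) + 1)):
        raise ValueError("expression ranks are not a permutation of 1..N")


def intervals_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Overlap length of two half-open intervals (0 when disjoint/adjacent)."""
    return max(0, min(a_end, b_end) - max(a_start, b_start))
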