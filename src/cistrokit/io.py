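"""Readers and writers for FASTA, BED, bedGraph and the tabular formats.

BED dialects used throughout:

* tags — BED6, strand required: ``chrom start end name score strand``
* peaks — BED6+3: ``chrom start end name score strand summit_offset
  fold_enrichment fdr`` where ``score`` is the -log10 p-value, ``strand``
  is ``.``, and ``summit_offset`` is relative to ``start``
* plain intervals — BED3 (extra columns preserved on read, ignored)

Gene models use a refFlat-like TSV (exonStarts/exonEnds comma-separated);
expression tables are two-column TSV (gene_id, fold_change).
"""

from __future__ import annotations

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import ExpressionRecord, GeneModel, GenomeSequence, Peak, Tag


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> GenomeSequence:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    seqs: dict[str, str] = {}
    for rec in records:
        if rec.id in seqs:
            raise ValueError(f"duplicate chromosome name: {rec.id}")
        seqs[rec.id] = str(rec.seq)
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.chroms.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# BED

def read_bed(path, kind: str = "interval", genome: GenomeSequence | None = None):
    """Read a BED file as tags, peaks, or plain intervals.

    Returns a list of :class:`Tag`, :class:`Peak`, or ``(chrom, start, end)``
    tuples depending on ``kind``. Input order is preserved. When a genome is
    supplied, coordinates past the chromosome end are rejected.
    """
    if kind not in ("tag", "peak", "interval"):
        raise ValueError(f"unknown BED kind: {kind}")
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: empty or inverted interval [{start},{end})"
                )
            if genome is not None:
                if chrom not in genome.chroms:
                    raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom}")
                if end > len(genome.chroms[chrom]):
                    raise ValueError(
                        f"{path}:{lineno}: interval past end of {chrom}"
                    )
            if kind == "tag":
                if len(cols) < 6:
                    raise ValueError(f"{path}:{lineno}: tag BED requires a strand column")
                strand = cols[5]
                if strand not in "+-":
                    raise ValueError(f"{path}:{lineno}: bad tag strand {strand!r}")
                out.append(Tag(chrom, start, end, strand))
            elif kind == "peak":
                name = cols[3] if len(cols) > 3 else f"peak_{lineno}"
                score = float(cols[4]) if len(cols) > 4 else 0.0
                summit = start + int(cols[6]) if len(cols) > 6 else (start + end) // 2
                fold = float(cols[7]) if len(cols) > 7 else 0.0
                fdr = float(cols[8]) if len(cols) > 8 else 0.0
                out.append(
                    Peak(chrom, start, end, summit, score=score,
                         fold_enrichment=fold, fdr=fdr, name=name)
                )
            else:
                out.append((chrom, start, end))
    return out


def write_bed(collection, path) -> None:
    """Write tags, peaks, or (chrom, start, end[, ...]) tuples as BED."""
    with open(path, "w") as fh:
        for item in collection:
            if isinstance(item, Tag):
                fh.write(
                    f"{item.chrom}\t{item.start}\t{item.end}\t.\t0\t{item.strand}\n"
                )
            elif isinstance(item, Peak):
                fh.write(
                    f"{item.chrom}\t{item.start}\t{item.end}\t{item.name or '.'}\t"
                    f"{item.score:.6g}\t.\t{item.summit - item.start}\t"
                    f"{item.fold_enrichment:.6g}\t{item.fdr:.6g}\n"
                )
            else:
                fh.write("\t".join(str(x) for x in item) + "\n")


# ---------------------------------------------------------------------------
# bedGraph

def write_bedgraph(track: dict[str, np.ndarray], path) -> None:
    """Write per-base coverage arrays as 4-column bedGraph.

    Consecutive equal-valued positions are merged into single records and
    zero runs are omitted, so the sum of record value x span equals the
    total coverage mass of the track.
    """
    with open(path, "w") as fh:
        for chrom, values in track.items():
            v = np.asarray(values)
            if v.size == 0:
                continue
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise ValueError(f"{chrom}: coverage values must be finite and >= 0")
            # run-length encode
            change = np.flatnonzero(v[1:] != v[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [v.size]))
            for s, e in zip(starts, ends):
                val = v[s]
                if val == 0:
                    continue
                out = int(val) if float(val).is_integer() else float(val)
                fh.write(f"{chrom}\t{s}\t{e}\t{out}\n")


# ---------------------------------------------------------------------------
# gene models (refFlat-like TSV)

_GENE_HEADER = "gene_id\tchrom\tstrand\ttxStart\ttxEnd\tcdsStart\tcdsEnd\texonStarts\texonEnds"


def write_gene_models(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write(_GENE_HEADER + "\n")
        for g in genes:
            ex_s = ",".join(str(s) for s, _ in g.exon_blocks)
            ex_e = ",".join(str(e) for _, e in g.exon_blocks)
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tx_start}\t{g.tx_end}\t"
                f"{g.cds_start}\t{g.cds_end}\t{ex_s}\t{ex_e}\n"
            )


def read_gene_models(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene_id"):
            raise ValueError(f"{path}: missing gene-model header line")
        for line in fh:
            if not line.strip():
                continue
            (gid, chrom, strand, txs, txe, cdss, cdse, ex_s, ex_e) = \
                line.rstrip("\n").split("\t")
            starts = [int(x) for x in ex_s.split(",") if x]
            ends = [int(x) for x in ex_e.split(",") if x]
            genes.append(
                GeneModel(gid, chrom, strand, int(txs), int(txe), int(cdss),
                          int(cdse), list(zip(starts, ends)))
            )
    return genes


# ---------------------------------------------------------------------------
# expression tables

def write_expression(records: list[ExpressionRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tfold_change\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.fold_change:.6g}\n")


def read_expression(path) -> list[ExpressionRecord]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene_id"):
            raise ValueError(f"{path}: missing expression header line")
        for line in fh:
            if not line.strip():
                continue
            gid, fc = line.split("\t")[:2]
            out.append(ExpressionRecord(gid, float(fc)))
    seen = set()
    for r in out:
        if r.gene_id in seen:
            raise ValueError(f"duplicate gene id in expression table: {r.gene_id}")
        seen.add(r.gene_id)
    return out
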