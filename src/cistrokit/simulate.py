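"""Synthetic ground-truth worlds for end-to-end testing of the pipeline.

The generator emulates the statistical structure of a monomeric
nuclear-receptor ChIP-seq experiment on a desk-scale genome: a random
genome with non-overlapping gene models, planted 9-bp half-site motif
instances biased toward promoters, bimodal strand-shifted treatment tags
around each site (fragment shift d = 152 bp, 39-bp reads), an IgG-like
uniform control, and an expression table in which site-proximal genes
carry an elevated fold change.

Every generator is fully deterministic under ``SimulationConfig.seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .types import DNA, ExpressionRecord, GeneModel, GenomeSequence, Tag, revcomp

#: The nuclear-receptor half-site planted by default.
HALF_SITE = "CCAAGGTCA"


@dataclass
class SimulationConfig:
    """Parameters of the synthetic world.

    Defaults give a 1 Mb two-chromosome genome with 100 genes and 200
    planted half-sites, 24% of which sit within 2 kb upstream of a TSS,
    sequenced with 39-bp reads at a fragment shift of 152 bp.
    """

    seed: int = 0
    chrom_lengths: list[int] = field(default_factory=lambda: [600_000, 400_000])
    gc_content: float = 0.42
    n_genes: int = 100
    n_sites: int = 200
    promoter_site_fraction: float = 0.24
    fragment_shift_d: int = 152
    tags_per_site_mean: float = 80.0
    background_tag_rate: float = 0.002  # tags per bp, per track, both strands
    read_length: int = 39
    expression_effect: float = 2.0
    consensus: str = HALF_SITE

    def __post_init__(self):
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0,1]")
        if not 0.0 <= self.promoter_site_fraction <= 1.0:
            raise ValueError("promoter_site_fraction must be in [0,1]")
        if self.fragment_shift_d <= 0:
            raise ValueError("fragment_shift_d must be > 0")
        if self.background_tag_rate < 0 or self.tags_per_site_mean < 0:
            raise ValueError("rates must be >= 0")
        if min([self.n_genes, self.n_sites, self.read_length], default=0) < 0:
            raise ValueError("counts must be >= 0")
        if set(self.consensus) - set(DNA):
            raise ValueError("consensus must be over {A,C,G,T}")


@dataclass
class SiteLocus:
    """One planted motif instance."""

    chrom: str
    start: int
    end: int
    strand: str
    n_tags: int = 0

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class GroundTruth:
    """Ledger of everything the generator planted, for recovery tests."""

    site_loci: list[SiteLocus] = field(default_factory=list)
    bound_genes: set[str] = field(default_factory=set)


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def generate_genome(config: SimulationConfig) -> GenomeSequence:
    """I.i.d. random genome with P(G)+P(C) = ``gc_content``."""
    if not config.chrom_lengths or min(config.chrom_lengths) <= 0:
        raise ValueError("chrom_lengths must be non-empty and positive")
    rng = _rng(config, 1)
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    seqs = {}
    bases = np.frombuffer(DNA.encode(), dtype=np.uint8)
    for i, length in enumerate(config.chrom_lengths, 1):
        draws = rng.choice(4, size=length, p=probs)
        seqs[f"chr{i}"] = bases[draws].tobytes().decode("ascii")
    return GenomeSequence(seqs)


def generate_gene_models(
    genome: GenomeSequence, config: SimulationConfig
) -> list[GeneModel]:
    """Place non-overlapping transcripts with exons, a 5'UTR, CDS and 3'UTR."""
    rng = _rng(config, 2)
    names = genome.chrom_names
    lengths = np.array([len(genome.chroms[c]) for c in names], dtype=float)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in names}
    genes: list[GeneModel] = []
    max_tries = 200 * max(config.n_genes, 1)
    tries = 0
    while len(genes) < config.n_genes:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {config.n_genes} non-overlapping genes"
            )
        chrom = names[rng.choice(len(names), p=lengths / lengths.sum())]
        L = len(genome.chroms[chrom])
        tx_len = int(rng.integers(2000, 8001))
        if tx_len >= L:
            continue
        tx_start = int(rng.integers(0, L - tx_len))
        tx_end = tx_start + tx_len
        if any(tx_start < e and s < tx_end for s, e in placed[chrom]):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 5))
        # split the transcript into 2*n_exons - 1 alternating blocks,
        # exons first and last, each block >= 100 bp
        n_blocks = 2 * n_exons - 1
        if n_blocks * 100 > tx_len:
            n_exons, n_blocks = 1, 1
        cuts = np.sort(rng.choice(tx_len - n_blocks * 100, size=n_blocks - 1,
                                  replace=False)) if n_blocks > 1 else np.array([], int)
        block_lens = np.diff(np.concatenate(([0], cuts, [tx_len - n_blocks * 100]))) + 100
        exons = []
        pos = tx_start
        for b, blen in enumerate(block_lens):
            if b % 2 == 0:
                exons.append((pos, pos + int(blen)))
            pos += int(blen)
        utr5 = int(rng.integers(100, 301))
        utr3 = int(rng.integers(100, 301))
        cds_start = tx_start + utr5
        cds_end = tx_end - utr3
        if cds_start >= cds_end:
            continue
        gid = f"gene{len(genes) + 1:04d}"
        genes.append(
            GeneModel(gid, chrom, strand, tx_start, tx_end, cds_start, cds_end, exons)
        )
        placed[chrom].append((tx_start, tx_end))
    return genes


def plant_motif_sites(
    genome: GenomeSequence,
    gene_models: list[GeneModel],
    consensus: str | None = None,
    config: SimulationConfig | None = None,
) -> tuple[GenomeSequence, GroundTruth]:
    """Overwrite the genome with motif instances and record their loci.

    A fraction ``promoter_site_fraction`` of sites is placed within 2 kb
    upstream of a TSS; the rest are uniform over the genome. Sites never
    overlap each other. Minus-strand placements write the reverse
    complement. Sites are planted by overwriting (not inserting) so gene
    coordinates stay valid.
    """
    config = config or SimulationConfig()
    consensus = consensus if consensus is not None else config.consensus
    w = len(consensus)
    if w > min(len(s) for s in genome.chroms.values()):
        raise ValueError("consensus longer than smallest chromosome")
    rng = _rng(config, 3)
    truth = GroundTruth()
    seqs = {c: bytearray(s, "ascii") for c, s in genome.chroms.items()}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chroms}

    n_prom = int(round(config.n_sites * config.promoter_site_fraction))
    plans = ["promoter"] * n_prom + ["uniform"] * (config.n_sites - n_prom)
    names = genome.chrom_names
    lengths = np.array([len(genome.chroms[c]) for c in names], dtype=float)
    genes_with_room = [g for g in gene_models] if gene_models else []

    for kind in plans:
        for _ in range(10_000):
            if kind == "promoter" and genes_with_room:
                g = genes_with_room[int(rng.integers(len(genes_with_room)))]
                offset = int(rng.integers(1, 2001 - w))
                if g.strand == "+":
                    start = g.tss - offset - w
                else:
                    start = g.tss + offset
                chrom = g.chrom
            else:
                chrom = names[int(rng.choice(len(names), p=lengths / lengths.sum()))]
                start = int(rng.integers(0, len(genome.chroms[chrom]) - w + 1))
            end = start + w
            if start < 0 or end > len(genome.chroms[chrom]):
                continue
            if any(start < e and s < end for s, e in occupied[chrom]):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            written = consensus if strand == "+" else revcomp(consensus)
            seqs[chrom][start:end] = written.encode("ascii")
            occupied[chrom].append((start, end))
            truth.site_loci.append(SiteLocus(chrom, start, end, strand))
            break
        else:
            raise RuntimeError("could not place all motif sites without overlap")

    new_genome = GenomeSequence({c: s.decode("ascii") for c, s in seqs.items()})
    # bound genes: site center within 2 kb of the TSS
    for g in gene_models:
        for site in truth.site_loci:
            if site.chrom == g.chrom and abs(site.center - g.tss) <= 2000:
                truth.bound_genes.add(g.gene_id)
                break
    return new_genome, truth


def simulate_tags(
    genome: GenomeSequence, truth: GroundTruth, config: SimulationConfig
) -> tuple[list[Tag], list[Tag]]:
    """Draw treatment and IgG-like control tag collections.

    For each planted site, Poisson-distributed forward tags start near
    ``center - d/2`` and reverse tags end near ``center + d/2``; positions
    are jittered with a discretized normal of SD ``d/4``. Both tracks get
    uniform background at ``background_tag_rate``; the control has no
    site signal.
    """
    d = config.fragment_shift_d
    rl = config.read_length
    rng = _rng(config, 4)
    treatment: list[Tag] = []
    control: list[Tag] = []
    lengths = genome.lengths

    def add_tag(coll, chrom, five_prime, strand):
        L = lengths[chrom]
        if strand == "+":
            s = int(np.clip(five_prime, 0, L - rl))
            coll.append(Tag(chrom, s, s + rl, "+"))
        else:
            e = int(np.clip(five_prime, rl - 1, L - 1)) + 1
            coll.append(Tag(chrom, e - rl, e, "-"))

    for site in truth.site_loci:
        n_f = rng.poisson(config.tags_per_site_mean / 2)
        n_r = rng.poisson(config.tags_per_site_mean / 2)
        site.n_tags = int(n_f + n_r)
        jit_f = np.rint(rng.normal(0, d / 4, size=n_f)).astype(int)
        jit_r = np.rint(rng.normal(0, d / 4, size=n_r)).astype(int)
        for j in jit_f:
            add_tag(treatment, site.chrom, site.center - d // 2 + j, "+")
        for j in jit_r:
            add_tag(treatment, site.chrom, site.center + d // 2 + j, "-")

    for coll in (treatment, control):
        for chrom, L in lengths.items():
            n_bg = rng.poisson(config.background_tag_rate * L)
            starts = rng.integers(0, max(L - rl, 1), size=n_bg)
            strands = rng.random(n_bg) < 0.5
            for s, fwd in zip(starts, strands):
                coll.append(Tag(chrom, int(s), int(s) + rl, "+" if fwd else "-"))

    key = lambda t: (t.chrom, t.start, t.end, t.strand)
    return sorted(treatment, key=key), sorted(control, key=key)


def simulate_expression(
    gene_models: list[GeneModel], truth: GroundTruth, config: SimulationConfig
) -> list[ExpressionRecord]:
    """Standard-normal fold changes, with bound genes shifted up by
    ``expression_effect``; ranks assigned by descending fold change."""
    if config.expression_effect < 0:
        raise ValueError("expression_effect must be >= 0")
    rng = _rng(config, 5)
    records = []
    for g in gene_models:
        fc = rng.normal(0.0, 1.0)
        if g.gene_id in truth.bound_genes:
            fc += config.expression_effect
        records.append(ExpressionRecord(g.gene_id, float(fc)))
    order = sorted(range(len(records)), key=lambda i: -records[i].fold_change)
    for rank, i in enumerate(order, 1):
        records[i].rank = rank
    return records


def generate_world(config: SimulationConfig | None = None):
    """Run every generator in order; returns
    ``(genome, genes, truth, treatment, control, expression)``."""
    config = config or SimulationConfig()
    genome = generate_genome(config)
    genes = generate_gene_models(genome, config)
    genome, truth = plant_motif_sites(genome, genes, config.consensus, config)
    treatment, control = simulate_tags(genome, truth, config)
    expression = simulate_expression(genes, truth, config)
    return genome, genes, truth, treatment, control, expression


def write_fixture_set(config: SimulationConfig, outdir) -> dict[str, str]:
    """Write the complete fixture file set for a config; returns the manifest."""
    import json
    from pathlib import Path

    from . import io as ckio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes, truth, treatment, control, expression = generate_world(config)
    paths = {
        "genome": outdir / "genome.fa",
        "genes": outdir / "genes.tsv",
        "truth_sites": outdir / "truth_sites.bed",
        "treatment": outdir / "treatment.bed",
        "control": outdir / "control.bed",
        "expression": outdir / "expression.tsv",
        "config": outdir / "config.json",
    }
    ckio.write_fasta(genome, paths["genome"])
    ckio.write_gene_models(genes, paths["genes"])
    with open(paths["truth_sites"], "w") as fh:
        for s in truth.site_loci:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\tsite\t{s.n_tags}\t{s.strand}\n")
    ckio.write_bed(treatment, paths["treatment"])
    ckio.write_bed(control, paths["control"])
    ckio.write_expression(expression, paths["expression"])
    with open(paths["config"], "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}
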