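"""Synthetic-world generators: determinism, composition, planted structure."""

import numpy as np
import pytest
from scipy.stats import ranksums

from cistrokit.peakcalling import _smoothed_mode
from cistrokit.simulate import (HALF_SITE, SimulationConfig, generate_genome,
                                generate_gene_models, generate_world,
                                plant_motif_sites, simulate_expression,
                                simulate_tags)
from cistrokit.types import revcomp


def small_config(**kw):
    base = dict(seed=11, chrom_lengths=[100_000], n_genes=10, n_sites=20,
                tags_per_site_mean=60.0)
    base.update(kw)
    return SimulationConfig(**base)


class TestGenome:
    def test_degenerate_gc_one(self):
        g = generate_genome(small_config(gc_content=1.0))
        assert set(g.chroms["chr1"]) <= {"G", "C"}

    def test_same_seed_identical(self):
        a = generate_genome(small_config())
        b = generate_genome(small_config())
        assert a.chroms == b.chroms

    def test_gc_fraction_within_3_binomial_sd(self):
        gc = 0.42
        g = generate_genome(small_config(gc_content=gc))
        seq = g.chroms["chr1"]
        n = len(seq)
        obs = (seq.count("G") + seq.count("C")) / n
        sd = np.sqrt(gc * (1 - gc) / n)
        assert abs(obs - gc) < 3 * sd

    def test_bad_gc_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(gc_content=1.5)


class TestGeneModels:
    def test_zero_genes(self):
        g = generate_genome(small_config())
        assert generate_gene_models(g, small_config(n_genes=0)) == []

    def test_nonoverlap_and_validity(self):
        cfg = small_config(chrom_lengths=[1_000_000], n_genes=50)
        g = generate_genome(cfg)
        genes = generate_gene_models(g, cfg)
        assert len(genes) == 50
        by_chrom = {}
        for gene in genes:
            # constructor re-validates invariants; also needs UTRs and exons
            assert gene.exon_blocks
            assert gene.tx_start < gene.cds_start < gene.cds_end < gene.tx_end
            by_chrom.setdefault(gene.chrom, []).append((gene.tx_start, gene.tx_end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2  # disjoint transcripts

    def test_strand_balance_within_3_sd(self):
        cfg = small_config(chrom_lengths=[1_000_000], n_genes=50)
        genes = generate_gene_models(generate_genome(cfg), cfg)
        n_plus = sum(g.strand == "+" for g in genes)
        sd = np.sqrt(50 * 0.25)
        assert abs(n_plus - 25) < 3 * sd


class TestPlanting:
    def test_zero_sites_leaves_genome_unchanged(self):
        cfg = small_config(n_sites=0)
        g = generate_genome(cfg)
        genes = generate_gene_models(g, cfg)
        g2, truth = plant_motif_sites(g, genes, config=cfg)
        assert g2.chroms == g.chroms
        assert truth.site_loci == []

    def test_consensus_written_at_every_locus(self):
        cfg = small_config()
        g = generate_genome(cfg)
        genes = generate_gene_models(g, cfg)
        g2, truth = plant_motif_sites(g, genes, config=cfg)
        assert len(truth.site_loci) == cfg.n_sites
        for s in truth.site_loci:
            seq = g2.fetch(s.chrom, s.start, s.end)
            assert seq == (HALF_SITE if s.strand == "+" else revcomp(HALF_SITE))

    def test_promoter_fraction_within_3_binomial_sd(self):
        cfg = SimulationConfig(seed=5, chrom_lengths=[2_000_000], n_genes=100,
                               n_sites=200, promoter_site_fraction=0.24)
        g = generate_genome(cfg)
        genes = generate_gene_models(g, cfg)
        _, truth = plant_motif_sites(g, genes, config=cfg)
        n_prom = 0
        for s in truth.site_loci:
            for gene in genes:
                if gene.chrom != s.chrom:
                    continue
                if gene.strand == "+" and gene.tss - 2000 <= s.start and s.end <= gene.tss:
                    n_prom += 1
                    break
                if gene.strand == "-" and gene.tss < s.start and s.end <= gene.tss + 2001:
                    n_prom += 1
                    break
        frac = n_prom / len(truth.site_loci)
        sd = np.sqrt(0.24 * 0.76 / 200)
        assert abs(frac - 0.24) < 3 * sd


class TestTags:
    def test_no_background_no_sites_gives_zero_tags(self):
        cfg = small_config(n_sites=0, background_tag_rate=0.0)
        g = generate_genome(cfg)
        genes = generate_gene_models(g, cfg)
        g2, truth = plant_motif_sites(g, genes, config=cfg)
        treatment, control = simulate_tags(g2, truth, cfg)
        assert treatment == [] and control == []

    def test_strand_mode_separation_recovers_d(self):
        # one site, many tags: distance between smoothed 5' modes ~ d
        cfg = SimulationConfig(seed=42, chrom_lengths=[50_000], n_genes=0,
                               n_sites=1, promoter_site_fraction=0.0,
                               tags_per_site_mean=500.0, background_tag_rate=0.0)
        g = generate_genome(cfg)
        g2, truth = plant_motif_sites(g, [], config=cfg)
        treatment, _ = simulate_tags(g2, truth, cfg)
        plus = np.sort([t.five_prime for t in treatment if t.strand == "+"])
        minus = np.sort([t.five_prime for t in treatment if t.strand == "-"])
        m_plus = _smoothed_mode(plus, 0, 50_000)
        m_minus = _smoothed_mode(minus, 0, 50_000)
        assert abs((m_minus - m_plus) - cfg.fragment_shift_d) <= 10

    def test_total_tag_count_within_3_sd_of_poisson_total(self):
        cfg = small_config()
        g = generate_genome(cfg)
        genes = generate_gene_models(g, cfg)
        g2, truth = plant_motif_sites(g, genes, config=cfg)
        treatment, _ = simulate_tags(g2, truth, cfg)
        expected = cfg.n_sites * cfg.tags_per_site_mean + \
            cfg.background_tag_rate * sum(cfg.chrom_lengths)
        sd = np.sqrt(expected)
        assert abs(len(treatment) - expected) < 3 * sd

    def test_control_lacks_site_signal(self, default_world):
        control = default_world["control"]
        truth = default_world["truth"]
        cfg = default_world["config"]
        # control density near sites should match background, not signal
        n_near = sum(
            1 for t in control for s in truth.site_loci[:20]
            if t.chrom == s.chrom and abs(t.five_prime - s.center) < 300
        )
        expected = cfg.background_tag_rate * 600 * 20
        assert n_near < expected + 4 * np.sqrt(expected) + 5


class TestExpression:
    def _world(self, effect, seed=9):
        cfg = SimulationConfig(seed=seed, chrom_lengths=[500_000], n_genes=60,
                               n_sites=40, expression_effect=effect)
        g = generate_genome(cfg)
        genes = generate_gene_models(g, cfg)
        g2, truth = plant_motif_sites(g, genes, config=cfg)
        return genes, truth, simulate_expression(genes, truth, cfg)

    def test_null_effect_gives_uniform_bound_ranks(self):
        pvals = []
        for seed in range(5):
            genes, truth, recs = self._world(0.0, seed=seed)
            bound = [r.rank for r in recs if r.gene_id in truth.bound_genes]
            rest = [r.rank for r in recs if r.gene_id not in truth.bound_genes]
            if bound and rest:
                pvals.append(ranksums(bound, rest).pvalue)
        assert min(pvals) > 0.01 / len(pvals)  # no seed significant at 0.01

    def test_positive_effect_shifts_bound_genes_up(self):
        genes, truth, recs = self._world(2.0)
        bound = [r.rank for r in recs if r.gene_id in truth.bound_genes]
        rest = [r.rank for r in recs if r.gene_id not in truth.bound_genes]
        assert np.mean(bound) < np.mean(rest)

    def test_same_seed_identical_table(self):
        _, _, a = self._world(2.0)
        _, _, b = self._world(2.0)
        assert a == b


def test_world_determinism_and_truth_readback():
    cfg = small_config()
    w1 = generate_world(cfg)
    w2 = generate_world(cfg)
    assert w1[0].chroms == w2[0].chroms
    assert w1[3] == w2[3]  # treatment tags
    genome, _, truth = w1[0], w1[1], w1[2]
    for s in truth.site_loci:
        if s.strand == "+":
            assert genome.fetch(s.chrom, s.start, s.end) == HALF_SITE
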