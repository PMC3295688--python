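"""Motif discovery, PWM scoring, genome baselines, and summit distances."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from cistrokit.motif import (PWM, BaselineStats, DegenerateBaselineError,
                             ScanConfig, build_pwm, find_enriched_kmer,
                             genome_baseline, scan_peaks,
                             summit_site_distances, write_pwm, read_pwm)
from cistrokit.pipeline import _background_sequences
from cistrokit.simulate import HALF_SITE
from cistrokit.types import GenomeSequence, Peak, revcomp


def random_seqs(rng, n, length):
    return ["".join(rng.choice(list("ACGT"), size=length)) for _ in range(n)]


def brute_force_scores(pwm, seq):
    """All window scores on both strands by direct per-letter lookup."""
    w = pwm.width
    out = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for off in range(len(s) - w + 1):
            window = s[off : off + w]
            if "N" in window:
                continue
            score = sum(
                np.log2(pwm.probs[i, "ACGT".index(b)] / 0.25)
                for i, b in enumerate(window)
            )
            start = off if strand == "+" else len(seq) - off - w
            out.append((start, strand, score))
    return out


class TestKmerDiscovery:
    def test_recovers_planted_consensus(self, rng):
        seqs = []
        for s in random_seqs(rng, 30, 120):
            pos = int(rng.integers(0, 120 - 9))
            seqs.append(s[:pos] + HALF_SITE + s[pos + 9:])
        bg = _background_sequences(seqs, rng, 10)
        result = find_enriched_kmer(seqs, 9, bg)
        assert result.consensus == HALF_SITE
        assert result.n_occurrences >= 30

    def test_minus_strand_planting_gives_same_canonical(self, rng):
        rc = revcomp(HALF_SITE)
        seqs = []
        for s in random_seqs(rng, 30, 120):
            pos = int(rng.integers(0, 120 - 9))
            seqs.append(s[:pos] + rc + s[pos + 9:])
        bg = _background_sequences(seqs, rng, 10)
        result = find_enriched_kmer(seqs, 9, bg)
        assert result.consensus == HALF_SITE  # canonical, lexicographically smaller
        assert all(strand == "-" for _, _, strand in result.occurrences)

    def test_random_sequences_ratio_within_resampled_null(self, rng):
        """On pure noise the top ratio must look like a null draw: it may
        not exceed the 99th percentile of ratios from fresh noise sets."""
        def top_ratio(seed):
            r = np.random.default_rng(seed)
            seqs = random_seqs(r, 40, 200)
            return find_enriched_kmer(seqs, 9, _background_sequences(seqs, r, 10)).ratio

        observed = top_ratio(0)
        null = np.array([top_ratio(1 + i) for i in range(30)])
        assert observed <= np.quantile(null, 0.99) * 1.0 + 1e-9

    def test_too_few_sequences_rejected(self, rng):
        with pytest.raises(ValueError):
            find_enriched_kmer(random_seqs(rng, 5, 50), 9, random_seqs(rng, 5, 50))

    def test_sequence_shorter_than_k_rejected(self, rng):
        seqs = random_seqs(rng, 10, 50)
        seqs[0] = "ACGT"
        with pytest.raises(ValueError):
            find_enriched_kmer(seqs, 9, seqs)


class TestBuildPwm:
    def test_identical_sites_probability(self):
        pwm = build_pwm([HALF_SITE] * 10, pseudocount=0.5)
        # consensus letter probability = 10.5 / 12
        assert pwm.probs[0, 1] == pytest.approx(10.5 / 12)  # C at position 0
        assert pwm.consensus == HALF_SITE

    def test_rows_sum_to_one(self):
        pwm = build_pwm(["ACGT", "AAAA", "TTTT"], pseudocount=0.25)
        assert np.allclose(pwm.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_and_ragged_rejected(self):
        with pytest.raises(ValueError):
            build_pwm([])
        with pytest.raises(ValueError):
            build_pwm(["ACGT", "ACG"])

    def test_round_trip_text_format(self, tmp_path):
        pwm = build_pwm([HALF_SITE] * 7)
        path = tmp_path / "m.pwm"
        write_pwm(pwm, path)
        back = read_pwm(path)
        assert np.allclose(back.probs, pwm.probs, atol=1e-6)


class TestGenomeBaseline:
    def test_uniform_pwm_degenerate(self):
        genome = GenomeSequence({"chr1": "ACGT" * 2500})
        pwm = PWM(np.full((6, 4), 0.25), 0.0)
        with pytest.raises(DegenerateBaselineError):
            genome_baseline(pwm, genome)

    def test_matches_exhaustive_rescan(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        genome = GenomeSequence({"chr1": seq})
        pwm = build_pwm([HALF_SITE] * 20)
        base = genome_baseline(pwm, genome)
        scores = [s for _, _, s in brute_force_scores(pwm, seq)]
        assert base.n_positions == len(scores)
        assert base.mean_score == pytest.approx(np.mean(scores), abs=1e-9)
        assert base.sd_score == pytest.approx(np.std(scores), abs=1e-9)

    def test_exclusion_bookkeeping(self):
        # all but 500 window starts excluded -> 500 windows x 2 strands
        genome = GenomeSequence({"chr1": "ACGT" * 500})  # 2000 bp
        pwm = build_pwm([HALF_SITE] * 5)
        w = pwm.width
        keep = 500
        excl = {"chr1": [(keep + w - 1, 2000)]}
        base = genome_baseline(pwm, genome, excl)
        assert base.n_positions == keep * 2
        assert base.excluded_bp == 2000 - keep - w + 1

    def test_n_windows_skipped(self):
        genome = GenomeSequence({"chr1": "ACGTACGTAC" + "N" + "ACGTACGTAC"})
        pwm = build_pwm(["ACGTA"] * 3)
        base = genome_baseline(pwm, genome)
        # windows touching the N are dropped on both strands
        assert base.n_positions == 2 * (6 + 6)


@pytest.fixture(scope="module")
def scan_world():
    rng = np.random.default_rng(77)
    seq = "".join(rng.choice(list("ACGT"), size=60_000))
    genome = GenomeSequence({"chr1": seq})
    pwm = build_pwm([HALF_SITE] * 50)
    baseline = genome_baseline(pwm, genome)
    return genome, pwm, baseline


class TestScanPeaks:
    def test_score_at_mean_gives_z0_p_half(self, scan_world):
        _, _, baseline = scan_world
        assert baseline.z(baseline.mean_score) == pytest.approx(0.0)
        assert norm.sf(0.0) == pytest.approx(0.5)

    def test_z_429_normal_tail(self):
        assert norm.sf(4.29) == pytest.approx(8.95e-6, rel=0.01)

    def test_hits_match_brute_force(self, scan_world):
        genome, pwm, baseline = scan_world
        rng = np.random.default_rng(3)
        peaks = []
        for i in range(25):
            start = int(rng.integers(0, 58_000))
            length = int(rng.integers(60, 2_000))
            end = min(start + length, 60_000)
            peaks.append(Peak("chr1", start, end, (start + end) // 2,
                              name=f"p{i}"))
        cfg = ScanConfig(z_cutoff=2.0)  # low cutoff so hits actually occur
        scan = scan_peaks(peaks, genome, pwm, baseline, cfg)
        for p in peaks:
            seq = genome.fetch(p.chrom, p.start, p.end)
            expected = {
                (p.start + s, strand)
                for s, strand, score in brute_force_scores(pwm, seq)
                if baseline.z(score) >= cfg.z_cutoff
            }
            got_all = {(h.start, h.strand) for h in scan.hits
                       if h.peak_name == p.name}
            # greedy resolution only removes overlapping same-strand hits;
            # every kept hit must be in the brute-force set and every
            # brute-force hit must overlap a kept hit on its strand
            assert got_all <= expected
            for s, strand in expected:
                assert any(
                    h.strand == strand and abs(h.start - s) < pwm.width
                    for h in scan.hits if h.peak_name == p.name
                )

    def test_exact_scores_match_brute_force(self, scan_world):
        genome, pwm, baseline = scan_world
        peak = Peak("chr1", 1_000, 3_000, 2_000, name="px")
        scan = scan_peaks([peak], genome, pwm, baseline, ScanConfig(z_cutoff=-50))
        brute = {(1_000 + s, strand): score
                 for s, strand, score in
                 brute_force_scores(pwm, genome.fetch("chr1", 1_000, 3_000))}
        for h in scan.hits:
            assert h.score == pytest.approx(brute[(h.start, h.strand)], abs=1e-9)

    def test_p_strictly_decreasing_in_z(self):
        zs = np.linspace(-3, 6, 50)
        ps = norm.sf(zs)
        assert np.all(np.diff(ps) < 0)

    def test_z_affine_invariance(self):
        base = BaselineStats(10.0, 2.0, 100)
        scores = np.array([8.0, 10.0, 14.0])
        z0 = base.z(scores)
        # affine transform applied to both scores and baseline
        a, b = 3.0, -7.0
        base2 = BaselineStats(a * 10.0 + b, a * 2.0, 100)
        assert np.allclose(base2.z(a * scores + b), z0)

    def test_revcomp_genome_mirror_invariance(self):
        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list("ACGT"), size=5_000))
        g_fwd = GenomeSequence({"chr1": seq})
        g_rev = GenomeSequence({"chr1": revcomp(seq)})
        pwm = build_pwm([HALF_SITE] * 20)
        b_fwd = genome_baseline(pwm, g_fwd)
        b_rev = genome_baseline(pwm, g_rev)
        assert b_fwd.mean_score == pytest.approx(b_rev.mean_score, abs=1e-9)
        assert b_fwd.sd_score == pytest.approx(b_rev.sd_score, abs=1e-9)
        peak = Peak("chr1", 0, 5_000, 2_500, name="p")
        cfg = ScanConfig(z_cutoff=2.5)
        h_fwd = scan_peaks([peak], g_fwd, pwm, b_fwd, cfg).hits
        h_rev = scan_peaks([peak], g_rev, pwm, b_rev, cfg).hits
        mirrored = {(5_000 - h.end, {"+": "-", "-": "+"}[h.strand]) for h in h_rev}
        assert {(h.start, h.strand) for h in h_fwd} == mirrored

    def test_site_vs_nonsite_peak_hit_fractions(self, rng):
        """400-bp peaks centered on planted sites virtually always contain a
        z>=4.29 hit; matched peaks without sites rarely do."""
        L = 400_000
        seq = list("".join(rng.choice(list("ACGT"), size=L)))
        n_sites = 150
        centers = np.arange(1_000, 1_000 + n_sites * 2_000, 2_000)
        for c in centers:
            seq[c - 4 : c + 5] = list(HALF_SITE)
        genome = GenomeSequence({"chr1": "".join(seq)})
        pwm = build_pwm([HALF_SITE] * 150)
        baseline = genome_baseline(pwm, genome)
        site_peaks = [Peak("chr1", c - 200, c + 200, c, name=f"s{i}")
                      for i, c in enumerate(centers)]
        nosite_peaks = [Peak("chr1", c + 800, c + 1_200, c + 1_000, name=f"n{i}")
                        for i, c in enumerate(centers)]
        scan_s = scan_peaks(site_peaks, genome, pwm, baseline)
        scan_n = scan_peaks(nosite_peaks, genome, pwm, baseline)
        assert scan_s.fraction_with_hit >= 0.95
        assert scan_n.fraction_with_hit < 0.10


class TestSummitSiteDistances:
    def test_overlap_rule_zero(self):
        from cistrokit.motif import _site_distance
        assert _site_distance(105, 100, 109) == 0
        assert _site_distance(120, 100, 109) == 12
        assert _site_distance(95, 100, 109) == 5

    def test_real_sites_closer_than_background(self, default_world, called_peaks):
        """Median best-site distance beats an arbitrarily placed same-length
        site in >= 95% of placement seeds."""
        genome = default_world["genome"]
        genes = default_world["genes"]
        peaks = called_peaks["peaks"]
        pwm = build_pwm([HALF_SITE] * 100)
        cds = {}
        for g in genes:
            cds.setdefault(g.chrom, []).append((g.cds_start, g.cds_end))
        baseline = genome_baseline(pwm, genome, cds)
        scan = scan_peaks(peaks, genome, pwm, baseline)
        wins = 0
        n_seeds = 40
        for seed in range(n_seeds):
            real, bg = summit_site_distances(scan.best_hit, peaks, seed=seed)
            if np.median(real) < np.median(bg):
                wins += 1
        assert wins >= 0.95 * n_seeds


def test_scan_config_validation():
    with pytest.raises(ValueError):
        ScanConfig(z_cutoff=float("nan"))
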