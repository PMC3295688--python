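"""End-to-end pipeline: simulate -> call peaks -> annotate -> motif ->
co-occupancy -> KS enrichment, driven by one configuration and one seed.

Per-stage seeds are derived deterministically from the global seed and
the stage name, so an identical config + seed yields a byte-identical
JSON report and each stage is reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np

from . import io as ckio
from .annotate import AnnotationConfig, classify_peaks, summit_to_tss_distances
from .cooccupancy import overlap_significance
from .enrichment import ks_running_enrichment, peaks_to_genes, rank_expression
from .motif import (ScanConfig, build_pwm, find_enriched_kmer, genome_baseline,
                    scan_peaks, summit_site_distances, write_pwm)
from .peakcalling import (NoModelError, PeakCallingConfig, PeakModel,
                          call_peaks, estimate_fragment_shift, pileup_track)
from .simulate import SimulationConfig, write_fixture_set
from .types import Peak

log = logging.getLogger("cistrokit")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {},            # SimulationConfig overrides
    "peaks": {},               # PeakCallingConfig overrides
    "annotation": {},          # AnnotationConfig overrides
    "motif": {"k": 9, "z_cutoff": 4.29, "n_background_draws": 10},
    "cooccupancy": {"n_resamples": 99, "slop_bp": 0},
    "ks": {"gene_window_bp": 2000, "n_permutations": 999, "rank_absolute": False},
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def _merge(defaults: dict, overrides: dict) -> dict:
    out = dict(defaults)
    for key, val in (overrides or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    import yaml

    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def run_pipeline(config: dict, outdir) -> dict:
    """Run every stage on a synthetic world; write stage outputs and return
    the JSON-serializable run report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = _merge(DEFAULT_CONFIG, config)
    seed = int(cfg["seed"])
    report: dict = {"parameters": _jsonable(cfg)}
    timings: dict[str, float] = {}

    # --- simulate ---------------------------------------------------------
    t0 = time.perf_counter()
    sim_cfg = SimulationConfig(**{"seed": stage_seed(seed, "simulate"),
                                  **cfg["simulate"]})
    manifest = write_fixture_set(sim_cfg, outdir / "fixtures")
    genome = ckio.read_fasta(manifest["genome"])
    genes = ckio.read_gene_models(manifest["genes"])
    truth_sites = ckio.read_bed(manifest["truth_sites"], kind="interval")
    treatment = ckio.read_bed(manifest["treatment"], kind="tag")
    control = ckio.read_bed(manifest["control"], kind="tag")
    expression = ckio.read_expression(manifest["expression"])
    bound_genes = _bound_genes(genes, truth_sites)
    report["simulate"] = {
        "n_genes": len(genes),
        "n_sites": len(truth_sites),
        "n_bound_genes": len(bound_genes),
        "n_treatment_tags": len(treatment),
        "n_control_tags": len(control),
    }
    timings["simulate"] = time.perf_counter() - t0
    log.info("simulate: %d sites, %d tags", len(truth_sites), len(treatment))

    # --- peak calling -----------------------------------------------------
    t0 = time.perf_counter()
    pk_cfg = PeakCallingConfig(**cfg["peaks"])
    try:
        model = estimate_fragment_shift(treatment, genome, pk_cfg)
        peaks = call_peaks(treatment, control, model, pk_cfg, genome)
    except NoModelError:
        model, peaks = None, []
        log.warning("callpeaks: no peak model (data too sparse); "
                    "downstream stages skipped")
    ckio.write_bed(peaks, outdir / "peaks.bed")
    if model is not None:
        ckio.write_bedgraph(pileup_track(treatment, model, genome),
                            outdir / "treatment_pileup.bedGraph")
    report["peaks"] = {
        "fragment_shift_d": model.fragment_shift_d if model else None,
        "n_model_regions": model.n_model_regions if model else 0,
        "n_peaks": len(peaks),
        "recovery": _recovery(peaks, truth_sites),
    }
    timings["callpeaks"] = time.perf_counter() - t0

    # --- annotation -------------------------------------------------------
    t0 = time.perf_counter()
    ann_cfg = AnnotationConfig(**cfg["annotation"])
    summary, annotations = classify_peaks(peaks, genes, ann_cfg)
    dists = summit_to_tss_distances(peaks, genes) if peaks else []
    with open(outdir / "annotation.tsv", "w") as fh:
        fh.write("peak\tfeature\tnearest_gene\ttss_distance\n")
        for a in annotations:
            fh.write(f"{a.peak.name}\t{a.feature}\t{a.nearest_gene}\t"
                     f"{a.tss_distance:.0f}\n")
    finite = [d for d in dists if np.isfinite(d)]
    report["annotation"] = {
        "fractions": {k: round(v, 6) for k, v in summary.fractions.items()},
        "median_abs_tss_distance": float(np.median(np.abs(finite))) if finite else None,
    }
    timings["annotate"] = time.perf_counter() - t0

    # --- motif ------------------------------------------------------------
    t0 = time.perf_counter()
    if len(peaks) < 10:
        report["motif"] = None
        report["cooccupancy"] = None
        report["ks"] = None
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return report
    m_cfg = cfg["motif"]
    rng = np.random.default_rng(stage_seed(seed, "motif"))
    peak_seqs = [genome.fetch(p.chrom, p.start, p.end) for p in peaks]
    bg_seqs = _background_sequences(peak_seqs, rng,
                                    int(m_cfg["n_background_draws"]))
    kmer = find_enriched_kmer(peak_seqs, int(m_cfg["k"]), bg_seqs)
    pwm = build_pwm([kmer.consensus] * max(kmer.n_occurrences, 1))
    cds = {g.chrom: [] for g in genes}
    for g in genes:
        cds[g.chrom].append((g.cds_start, g.cds_end))
    baseline = genome_baseline(pwm, genome, cds)
    scan = scan_peaks(peaks, genome, pwm, baseline,
                      ScanConfig(z_cutoff=float(m_cfg["z_cutoff"])))
    real_d, bg_d = summit_site_distances(scan.best_hit, peaks,
                                         seed=stage_seed(seed, "motif_bg"))
    write_pwm(pwm, outdir / "motif_pwm.txt")
    with open(outdir / "motif_hits.bed", "w") as fh:
        for h in scan.hits:
            fh.write(f"{h.chrom}\t{h.start}\t{h.end}\t{h.peak_name}\t"
                     f"{h.z:.3f}\t{h.strand}\n")
    report["motif"] = {
        "consensus": kmer.consensus,
        "enrichment_ratio": round(kmer.ratio, 3),
        "n_occurrences": kmer.n_occurrences,
        "baseline_mean": round(baseline.mean_score, 6),
        "baseline_sd": round(baseline.sd_score, 6),
        "fraction_peaks_with_hit": round(scan.fraction_with_hit, 6),
        "median_summit_site_distance": float(np.median(real_d)) if real_d else None,
        "median_background_distance": float(np.median(bg_d)) if bg_d else None,
    }
    timings["motif"] = time.perf_counter() - t0
    log.info("motif: %s, hit fraction %.2f", kmer.consensus, scan.fraction_with_hit)

    # --- co-occupancy (called peaks vs planted site intervals) ------------
    t0 = time.perf_counter()
    co_cfg = cfg["cooccupancy"]
    site_peaks = [
        Peak(c, s, e, (s + e) // 2, name=f"site_{i}")
        for i, (c, s, e) in enumerate(truth_sites)
    ]
    if site_peaks and peaks:
        overlap = overlap_significance(
            peaks, site_peaks, genome,
            n_resamples=int(co_cfg["n_resamples"]),
            seed=stage_seed(seed, "cooccupancy"),
            slop_bp=int(co_cfg["slop_bp"]),
        )
        report["cooccupancy"] = {
            "fraction_A_with_B": round(overlap.fraction_A, 6),
            "n_overlap_pairs": overlap.n_overlap_pairs,
            "empirical_p": overlap.empirical_p,
            "n_resamples": overlap.n_resamples,
        }
    else:
        report["cooccupancy"] = None
    timings["cooccupy"] = time.perf_counter() - t0

    # --- KS enrichment ----------------------------------------------------
    t0 = time.perf_counter()
    ks_cfg = cfg["ks"]
    hit_genes = peaks_to_genes(peaks, genes, int(ks_cfg["gene_window_bp"]))
    ranked = rank_expression(expression, absolute=bool(ks_cfg["rank_absolute"]))
    if 0 < len(hit_genes & {r.gene_id for r in ranked}) < len(ranked):
        ks = ks_running_enrichment(
            ranked, hit_genes,
            n_permutations=int(ks_cfg["n_permutations"]),
            seed=stage_seed(seed, "ks"),
            exhaustive=False,
        )
        with open(outdir / "ks_curve.tsv", "w") as fh:
            fh.write("rank\trunning_sum\n")
            for i, v in enumerate(ks.running_curve, 1):
                fh.write(f"{i}\t{v:.6f}\n")
        report["ks"] = {
            "n_total": ks.n_total,
            "n_hits": ks.n_hits,
            "es": round(ks.es, 6),
            "es_max": round(ks.es_max, 6),
            "p_perm": ks.p_perm,
            "n_permutations": ks.n_permutations,
        }
    else:
        report["ks"] = None
    timings["ksenrich"] = time.perf_counter() - t0

    for stage, dt in timings.items():
        log.info("stage %-10s %.2fs", stage, dt)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _bound_genes(genes, truth_sites) -> set[str]:
    out = set()
    for g in genes:
        for c, s, e in truth_sites:
            if c == g.chrom and abs((s + e) // 2 - g.tss) <= 2000:
                out.add(g.gene_id)
                break
    return out


def _recovery(peaks: list[Peak], truth_sites) -> dict:
    """Fraction of planted sites inside a called peak and of called peaks
    containing a planted site."""
    if not truth_sites or not peaks:
        return {"site_recovery": 0.0, "peak_precision": 0.0}
    n_sites_in = 0
    for c, s, e in truth_sites:
        if any(p.chrom == c and p.start < e and s < p.end for p in peaks):
            n_sites_in += 1
    n_peaks_with = 0
    for p in peaks:
        if any(p.chrom == c and p.start < e and s < p.end for c, s, e in truth_sites):
            n_peaks_with += 1
    return {
        "site_recovery": round(n_sites_in / len(truth_sites), 6),
        "peak_precision": round(n_peaks_with / len(peaks), 6),
    }


def _background_sequences(peak_seqs: list[str], rng, n_draws: int = 10) -> list[str]:
    """Motif-discovery background: per-sequence letter shuffles of the peak
    sequences, repeated ``n_draws`` times. Composition-matched but
    signal-free, so the expected k-mer frequency reflects base content
    alone; several draws keep the per-k-mer expectation stable."""
    out = []
    for _ in range(max(n_draws, 1)):
        for seq in peak_seqs:
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
            rng.shuffle(arr)
            out.append(arr.tobytes().decode("ascii"))
    return out


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
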