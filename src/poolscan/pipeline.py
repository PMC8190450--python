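"""End-to-end orchestration: simulate -> call -> scan -> diversity -> fst
-> ld -> integrate, with per-stage seeding, on-disk outputs and a summary.

Each stage writes its result tables into the run directory and is skipped
on rerun when its outputs already exist (resume semantics); a single global
seed deterministically derives one sub-seed per stage from the stage name,
so stages can be rerun independently yet reproducibly.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calling, diversity, expression, fst, ld, scan, simulate
from .io import (
    read_gene_table,
    read_sample_sheet,
    read_sync,
    write_gene_table,
    write_sample_sheet,
    write_sync,
    write_table,
)

log = logging.getLogger("poolscan")

X_CHROMS_DEFAULT = {"XL", "XR"}


@dataclass
class RunConfig:
    outdir: str = "poolscan_run"
    seed: int = 0
    sync_path: str | None = None  # when set, the simulate stage is skipped
    sheet_path: str | None = None
    genes_path: str | None = None
    x_chroms: set = field(default_factory=lambda: set(X_CHROMS_DEFAULT))
    sim: simulate.SimulationConfig = field(default_factory=simulate.divergent_scenario)
    filters: calling.SiteFilterConfig = field(default_factory=calling.SiteFilterConfig)
    q_threshold: float = 0.05
    link_bp: int = 50_000
    peak_min_snps: int = 10
    window_size: int = 50_000
    window_step: int = 40_000
    min_snps_tajd: int = 10
    z_values: tuple = (1.0, 6.0)
    n_boot: int = 1000
    n_genes: int = 1000
    de_enrichment: float = 6.0
    overlap_flank_bp: int = 10_000
    n_resample: int = 1000
    ld_n_pairs: int = 20_000
    ld_bin_width: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        filt_raw = raw.pop("filters", {})
        plan = sim_raw.pop("chrom_plan", None)
        regions = sim_raw.pop("hap_regions", None)
        sim_cfg = simulate.SimulationConfig(**sim_raw)
        if plan is not None:
            sim_cfg.chrom_plan = [simulate.ChromPlan(**c) for c in plan]
        if regions is not None:
            sim_cfg.hap_regions = [simulate.HapRegionPlan(**r) for r in regions]
        cfg = cls(sim=sim_cfg, filters=calling.SiteFilterConfig(**filt_raw), **raw)
        cfg.x_chroms = set(cfg.x_chroms)
        cfg.z_values = tuple(cfg.z_values)
        return cfg

    def validate(self) -> None:
        for p in (self.sync_path, self.sheet_path, self.genes_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input path does not exist: {p}")


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage sub-seed: global seed mixed with a stage-name hash."""
    return (global_seed * 100_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def chrom_lengths_from_config(cfg: RunConfig) -> dict[str, int]:
    return {c.name: c.length for c in cfg.sim.chrom_plan}


def run_pipeline(cfg: RunConfig, force: bool = False) -> dict:
    """Execute all stages in dependency order; returns the summary dict."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed}

    # ---- simulate ------------------------------------------------------
    sync_p = out / "pools.sync"
    sheet_p = out / "sample_sheet.tsv"
    genes_p = out / "genes.tsv"
    truth_p = out / "truth.tsv"
    truth = None
    if cfg.sync_path is not None:
        log.info("stage=simulate skipped (external sync input %s)", cfg.sync_path)
        sheet = read_sample_sheet(cfg.sheet_path, paired=True)
        sites = read_sync(cfg.sync_path, sheet)
        genes = read_gene_table(cfg.genes_path) if cfg.genes_path else []
    else:
        s = stage_seed(cfg.seed, "simulate")
        log.info("stage=simulate seed=%d n_loci_plan=%s", s, [c.n_loci for c in cfg.sim.chrom_plan])
        truth = simulate.simulate_wright_fisher(cfg.sim, seed=s)
        sites = simulate.sample_pool_counts(truth, cfg.sim, seed=stage_seed(cfg.seed, "pool-sample"))
        sheet = cfg.sim.sample_sheet()
        genes = simulate.generate_gene_annotation_and_de(
            truth, cfg.n_genes, cfg.de_enrichment, seed=stage_seed(cfg.seed, "genes")
        )
        if force or not sync_p.exists():
            write_sync(sites, sync_p)
            write_sample_sheet(sheet, sheet_p)
            write_gene_table(genes, genes_p)
            tdf = truth.loci.copy()
            for j, lid in enumerate(truth.line_ids):
                tdf[f"freq_{lid}"] = truth.freqs[:, j]
            write_table(tdf, truth_p)
    summary["n_sites"] = len(sites)

    # ---- call ----------------------------------------------------------
    log.info("stage=call filters=%s", cfg.filters)
    result = calling.call_snps(sites, cfg.filters)
    snps = result.snps
    summary["n_snps_called"] = len(snps)
    summary["n_multiallelic_dropped"] = result.n_multiallelic
    chroms, positions, major, minor = calling.snps_to_arrays(snps)
    snp_df = pd.DataFrame({"chrom": chroms, "pos": positions})
    for j, pid in enumerate(sheet.pool_ids):
        snp_df[f"maj_{pid}"] = major[:, j]
        snp_df[f"min_{pid}"] = minor[:, j]
    write_table(snp_df, out / "snps.tsv")

    # ---- scan ----------------------------------------------------------
    log.info("stage=scan q_threshold=%g", cfg.q_threshold)
    scan_df = scan.scan_snps(snps, sheet, q_threshold=cfg.q_threshold)
    top = scan_df[scan_df["is_top"]]
    peaks = scan.cluster_top_snps(top["chrom"].to_numpy(), top["pos"].to_numpy(), cfg.link_bp)
    peak_df = pd.DataFrame(
        [{"chrom": p.chrom, "start": p.start, "end": p.end, "n_snps": p.n_snps} for p in peaks]
    )
    # annotate membership
    peak_id = np.full(len(scan_df), -1)
    for i, p in enumerate(peaks):
        sel = (scan_df["chrom"] == p.chrom) & scan_df["pos"].isin(p.members) & scan_df["is_top"]
        peak_id[sel.to_numpy()] = i
    scan_df["peak_id"] = peak_id
    write_table(scan_df, out / "scan.tsv")
    write_table(peak_df, out / "peaks.tsv")
    if len(peak_df):
        bed = peak_df.copy()
        bed["start"] = bed["start"] - 1  # BED is 0-based half-open
        bed[["chrom", "start", "end", "n_snps"]].to_csv(
            out / "peaks.bed", sep="\t", index=False, header=False
        )
    summary["n_top_snps"] = int(len(top))
    summary["n_clusters"] = len(peaks)
    summary["n_peaks_gt10"] = len(scan.major_peaks(peaks, cfg.peak_min_snps))
    if len(top):
        bg = scan_df[~scan_df["is_top"]]
        excess = scan.chromosome_excess_test(
            top.groupby("chrom").size().to_dict(), bg.groupby("chrom").size().to_dict()
        )
        write_table(excess, out / "chromosome_excess.tsv")
        summary["chromosome_excess_p"] = dict(zip(excess["chrom"], excess["p_bonferroni"]))
        fixed = scan.fixed_difference_flags(snps, sheet)
        summary["fixed_difference_fraction_of_top"] = float(
            fixed[scan_df["is_top"].to_numpy()].mean()
        )
        if peaks:
            covchk = scan.peak_coverage_check(
                peaks, sites, n_random=100, seed=stage_seed(cfg.seed, "coverage-check")
            )
            summary["peak_coverage_p"] = covchk["p_value"]

    # ---- diversity -----------------------------------------------------
    log.info("stage=diversity window=%d step=%d", cfg.window_size, cfg.window_step)
    lengths = chrom_lengths_from_config(cfg) if cfg.sync_path is None else {
        c: int(m) for c, m in snp_df.groupby("chrom")["pos"].max().items()
    }
    windows = diversity.make_windows(lengths, cfg.window_size, cfg.window_step)
    div_df = diversity.pooled_window_diversity(
        chroms, positions, major, minor, sheet, windows, cfg.min_snps_tajd
    )
    write_table(div_df, out / "windows_diversity.tsv")
    for treat in ("E", "M"):
        sub = div_df[div_df["treatment"] == treat]
        summary[f"pi_mean_{treat}"] = float(sub["pi"].mean())
        summary[f"tajimas_d_mean_{treat}"] = float(sub["tajimas_d"].mean())

    # ---- fst -----------------------------------------------------------
    log.info("stage=fst z_values=%s n_boot=%d", cfg.z_values, cfg.n_boot)
    fst_tab = fst.pairwise_fst_table(chroms, positions, major, minor, sheet)
    wfst = fst.window_fst(fst_tab, windows)
    write_table(wfst, out / "windows_fst.tsv")
    wfst_mean = (
        wfst.groupby(["chrom", "start", "end"], as_index=False)["fst"].mean()
    )
    fx_rows = []
    for rep, g in wfst.groupby("replicate"):
        for z in cfg.z_values:
            fx_r = fst.bootstrap_fx(
                g, cfg.x_chroms, z, cfg.n_boot, seed=stage_seed(cfg.seed, f"fx-{rep}-{z}")
            )
            fx_rows.append(
                {
                    "replicate": rep,
                    "z": z,
                    "f_a": fx_r.f_a,
                    "f_x_observed": fx_r.f_x_observed,
                    "f_x_expected": fx_r.f_x,
                    "ci_low": fx_r.ci_low,
                    "ci_high": fx_r.ci_high,
                }
            )
    fx_df = pd.DataFrame(fx_rows)
    write_table(fx_df, out / "fx_expectation.tsv")
    summary["fst_autosome_mean"] = float(
        wfst_mean.loc[~wfst_mean["chrom"].astype(str).isin(cfg.x_chroms), "fst"].mean()
    )
    summary["fst_x_mean"] = float(
        wfst_mean.loc[wfst_mean["chrom"].astype(str).isin(cfg.x_chroms), "fst"].mean()
    )
    try:
        xa = fst.xa_ratio(
            wfst_mean, cfg.x_chroms, "fst", cfg.n_boot, seed=stage_seed(cfg.seed, "xa-fst")
        )
        summary["xa_fst_ratio"] = xa["ratio"]
        summary["xa_fst_ci"] = [xa["ci_low"], xa["ci_high"]]
    except ValueError:
        summary["xa_fst_ratio"] = None
    if peaks:
        in_peak = diversity.label_windows_in_peaks(wfst_mean, peaks)
        if in_peak.any() and (~in_peak).any():
            summary["fst_in_peaks"] = float(wfst_mean.loc[in_peak, "fst"].mean())
            summary["fst_outside_peaks"] = float(wfst_mean.loc[~in_peak, "fst"].mean())

    # ---- ld ------------------------------------------------------------
    ld_rows = []
    if truth is not None and truth.haplotypes:
        log.info("stage=ld n_pairs=%d", cfg.ld_n_pairs)
        for reg_id in truth.haplotypes:
            for lid in truth.line_ids:
                rp = simulate.generate_read_pairs(
                    truth,
                    reg_id,
                    lid,
                    cfg.ld_n_pairs,
                    seed=stage_seed(cfg.seed, f"ld-{reg_id}-{lid}"),
                )
                pairs = ld.compute_pair_ld(rp)
                table = ld.bin_by_distance(pairs, bin_width=cfg.ld_bin_width)
                if len(table) >= 2:
                    f = ld.fit_decay(table, region_id=f"{reg_id}:{lid}")
                    ld_rows.append(
                        {
                            "region": reg_id,
                            "line": lid,
                            "treatment": lid[0],
                            "intercept": f.intercept,
                            "decay_slope": f.decay_slope,
                            "slope_se": f.slope_se,
                            "n_classes": f.n_classes,
                        }
                    )
    ld_df = pd.DataFrame(ld_rows)
    write_table(ld_df, out / "ld_decay.tsv")
    if len(ld_df):
        summary["ld_slope_mean_E"] = float(
            ld_df.loc[ld_df["treatment"] == "E", "decay_slope"].mean()
        )
        summary["ld_slope_mean_M"] = float(
            ld_df.loc[ld_df["treatment"] == "M", "decay_slope"].mean()
        )

    # ---- integrate -----------------------------------------------------
    if genes and len(top):
        log.info("stage=integrate flank=%d", cfg.overlap_flank_bp)
        near = expression.genes_near_snps(
            top["chrom"].to_numpy(), top["pos"].to_numpy(), genes, cfg.overlap_flank_bp
        )
        de_set = {g.gene_id for g in genes if g.is_de}
        if near:
            ov = expression.overlap_resampling_test(
                near,
                de_set,
                [g.gene_id for g in genes],
                cfg.n_resample,
                seed=stage_seed(cfg.seed, "overlap"),
            )
            summary["overlap_n_query"] = ov.n_query
            summary["overlap_observed_prop"] = ov.observed_overlap_prop
            summary["overlap_resample_q95"] = ov.resample_q95
            summary["overlap_empirical_p"] = ov.empirical_p
            summary["overlap_significant"] = ov.significant

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    log.info("pipeline complete: %s", out / "summary.json")
    return summary
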