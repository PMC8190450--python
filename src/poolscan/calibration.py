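"""Self-calibration experiments for the scan pipeline.

These routines run the package end to end on simulated designs whose truth
is known, and report how the statistics behave: type-I error of the GLM
scan on fully neutral data, recovery of divergently selected loci, and the
qualitative genome-scan signatures (X:A differentiation ratio, elevated
FST inside divergence peaks, depressed Tajima's D in swept regions).

They are ordinary library functions — the test suite asserts on their
output and the reproduction script reports it.
"""

from __future__ import annotations

import numpy as np

from . import calling, diversity, fst, scan, simulate

X_CHROMS = {"XL", "XR"}


def _sub_seed(seed: int, salt: int) -> int:
    return (seed * 9973 + salt) % (2**31 - 1)


def neutral_scan(seed: int, coverage: float = 50.0) -> dict:
    """Scan fully neutral data (8 pools of 40, ~5000 SNPs): the fraction of
    nominally significant GLM p-values and the number of q < 0.05 calls."""
    cfg = simulate.SimulationConfig(
        chrom_plan=[
            simulate.ChromPlan("2", 2_000_000, 3350, False),
            simulate.ChromPlan("XL", 2_000_000, 3350, True),
        ],
        selected_fraction=0.0,
        mean_coverage=coverage,
        seed=seed,
    )
    truth = simulate.simulate_wright_fisher(cfg, seed=_sub_seed(seed, 1))
    sites = simulate.sample_pool_counts(truth, cfg, seed=_sub_seed(seed, 2))
    snps = calling.call_snps(sites).snps
    df = scan.scan_snps(snps, cfg.sample_sheet())
    return {
        "n_snps": len(df),
        "frac_p_below_05": float((df["p_value"] < 0.05).mean()),
        "n_top": int(df["is_top"].sum()),
    }


def selected_recovery(
    seed: int,
    n_loci: int = 2000,
    n_selected: int = 50,
    sel_coeff: float = 0.05,
    coverage: float = 50.0,
) -> dict:
    """Recovery of divergently selected loci by the q < 0.05 top-SNP rule.

    ``n_selected`` loci carry antagonistic selection (+s in E lines, -s in
    M lines, additive) among ``n_loci`` total; reports the fraction of
    selected loci called top and the fraction of top SNPs that are
    unselected.
    """
    per_chrom = n_loci // 4
    cfg = simulate.SimulationConfig(
        chrom_plan=[
            simulate.ChromPlan("2", 400_000, per_chrom, False),
            simulate.ChromPlan("3", 400_000, per_chrom, False),
            simulate.ChromPlan("XL", 300_000, per_chrom, True),
            simulate.ChromPlan("XR", 300_000, per_chrom, True),
        ],
        selected_fraction=n_selected / n_loci,
        sel_coeff_e=sel_coeff,
        sel_coeff_m=-sel_coeff,
        mean_coverage=coverage,
        seed=seed,
    )
    truth = simulate.simulate_wright_fisher(cfg, seed=_sub_seed(seed, 3))
    sites = simulate.sample_pool_counts(truth, cfg, seed=_sub_seed(seed, 4))
    snps = calling.call_snps(sites).snps
    df = scan.scan_snps(snps, cfg.sample_sheet())
    m = df.merge(truth.loci[["chrom", "pos", "selected"]], on=["chrom", "pos"], how="left")
    m["selected"] = m["selected"].fillna(False)
    n_sel_called = int(m["selected"].sum())
    top = m[m["is_top"]]
    recovery = float(m.loc[m["selected"], "is_top"].mean()) if n_sel_called else np.nan
    false_frac = float((~top["selected"].astype(bool)).mean()) if len(top) else 0.0
    return {
        "n_snps": len(df),
        "n_selected_called": n_sel_called,
        "n_top": int(len(top)),
        "recovery": recovery,
        "false_top_fraction": false_frac,
    }


def headline_metrics(seed: int, sim_cfg: simulate.SimulationConfig | None = None) -> dict:
    """The genome-scan headlines on one divergent-selection replicate.

    Returns the X:A window-FST ratio, mean window FST inside vs outside
    top-SNP peaks, and mean per-pool Tajima's D in completed-sweep regions
    vs windows outside all linked regions (E lines in which the swept
    allele reached fixation; NaN when no sweep completed).
    """
    cfg = sim_cfg or simulate.divergent_scenario()
    truth = simulate.simulate_wright_fisher(cfg, seed=_sub_seed(seed, 5))
    sites = simulate.sample_pool_counts(truth, cfg, seed=_sub_seed(seed, 6))
    sheet = cfg.sample_sheet()
    snps = calling.call_snps(sites).snps
    df = scan.scan_snps(snps, sheet)
    top = df[df["is_top"]]
    peaks = scan.cluster_top_snps(top["chrom"].to_numpy(), top["pos"].to_numpy())

    chroms, pos, major, minor = calling.snps_to_arrays(snps)
    lengths = {c.name: c.length for c in cfg.chrom_plan}
    windows = diversity.make_windows(lengths)

    fst_tab = fst.pairwise_fst_table(chroms, pos, major, minor, sheet)
    wfst = fst.window_fst(fst_tab, windows)
    wfst_mean = wfst.groupby(["chrom", "start", "end"], as_index=False)["fst"].mean()
    xa = fst.xa_ratio(wfst_mean, X_CHROMS, "fst", n_boot=100, seed=_sub_seed(seed, 7))

    in_peak = diversity.label_windows_in_peaks(wfst_mean, peaks)
    fst_in = float(wfst_mean.loc[in_peak, "fst"].mean()) if in_peak.any() else np.nan
    fst_out = float(wfst_mean.loc[~in_peak, "fst"].mean()) if (~in_peak).any() else np.nan

    # Tajima's D: completed-sweep regions vs windows outside linked regions
    region_spans = {r.region_id: (r.chrom, r.start, r.end) for r in cfg.hap_regions if r.selected}
    sel_loci = truth.loci[truth.loci["selected"] & truth.loci["region"].notna()]
    d_sweep, d_unlinked = [], []
    e_indices = [j for j, lid in enumerate(truth.line_ids) if lid.startswith("E")]
    for reg_id, (rchrom, rstart, rend) in region_spans.items():
        sel_idx = sel_loci.index[sel_loci["region"] == reg_id]
        if len(sel_idx) == 0:
            continue
        sel_row = int(sel_idx[0])
        for j in e_indices:
            if truth.freqs[sel_row, j] < 0.95:
                continue  # sweep incomplete in this line
            wd = diversity.window_diversity(
                chroms, pos, major[:, j], minor[:, j], cfg.pool_size, windows, min_snps=5
            )
            in_reg = (
                (wd["chrom"] == rchrom) & (wd["start"] <= rend) & (wd["end"] >= rstart)
            ).to_numpy()
            in_any = np.zeros(len(wd), dtype=bool)
            for r in cfg.hap_regions:
                in_any |= (
                    (wd["chrom"] == r.chrom) & (wd["start"] <= r.end) & (wd["end"] >= r.start)
                ).to_numpy()
            d_sweep.append(np.nanmean(wd["tajimas_d"].to_numpy()[in_reg]))
            d_unlinked.append(np.nanmean(wd["tajimas_d"].to_numpy()[~in_any]))
    return {
        "n_top": int(len(top)),
        "n_clusters": len(peaks),
        "xa_fst_ratio": float(xa["ratio"]),
        "fst_in_peaks": fst_in,
        "fst_outside_peaks": fst_out,
        "n_completed_sweeps": len(d_sweep),
        "d_sweep": float(np.nanmean(d_sweep)) if d_sweep else np.nan,
        "d_unlinked": float(np.nanmean(d_unlinked)) if d_unlinked else np.nan,
    }
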