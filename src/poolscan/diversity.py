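"""Pool-corrected nucleotide diversity and Tajima's D in sliding windows.

Pool-seq allele frequencies carry two layers of sampling noise: reads are
drawn (with replacement) from the pooled chromosomes, and the pool itself
is a finite sample of the population.  The per-site diversity estimator
corrects both:

    pi_site = C/(C-1) * 2*p*(1-p) * 2n/(2n-1)

with read coverage ``C = major + minor``, read frequency ``p``, and ``n``
diploid individuals in the pool (2n chromosomes).  Watterson's theta uses
the harmonic-number correction with sample size 2n, and Tajima's D applies
the classical variance formula at that sample size.  Windows are 50 kb
with a 10-kb overlap (step 40 kb) by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneInterval

WINDOW_SIZE = 50_000
WINDOW_STEP = 40_000


def tajima_constants(n_chrom: int) -> dict[str, float]:
    """Classical Tajima variance constants for ``n_chrom`` sequences."""
    n = n_chrom
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "e1": e1, "e2": e2}


def site_pi(major: np.ndarray, minor: np.ndarray, pool_size: int) -> np.ndarray:
    """Per-site heterozygosity with read- and pool-sampling corrections.

    Sites with coverage < 2 yield NaN (skipped upstream)."""
    major = np.asarray(major, dtype=np.float64)
    minor = np.asarray(minor, dtype=np.float64)
    cov = major + minor
    n2 = 2 * pool_size
    with np.errstate(invalid="ignore", divide="ignore"):
        p = major / cov
        pi = cov / (cov - 1.0) * 2.0 * p * (1.0 - p) * n2 / (n2 - 1.0)
    return np.where(cov >= 2, pi, np.nan)


def make_windows(
    chrom_lengths: dict[str, int], size: int = WINDOW_SIZE, step: int = WINDOW_STEP
) -> pd.DataFrame:
    """Overlapping window plan; a trailing partial window is kept and
    flagged.  Coordinates are 1-based inclusive."""
    rows = []
    for chrom, length in chrom_lengths.items():
        start = 1
        while start <= length:
            end = min(start + size - 1, length)
            rows.append((chrom, start, end, end - start + 1 < size))
            if end == length:
                break
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "partial"])


def window_diversity(
    chroms: np.ndarray,
    positions: np.ndarray,
    major: np.ndarray,
    minor: np.ndarray,
    pool_size: int,
    windows: pd.DataFrame,
    min_snps: int = 10,
    site_mask_denominator: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-window pi, Watterson's theta and Tajima's D for one pool.

    ``major``/``minor`` are that pool's read counts at each SNP.  ``pi`` is
    the summed site diversity divided by the window length (or by the
    number of adequately covered sites when a per-window site count is
    supplied via ``site_mask_denominator``, aligned with ``windows``).
    Tajima's D is reported only when at least ``min_snps`` segregating
    sites fall in the window.
    """
    cov = np.asarray(major) + np.asarray(minor)
    pi_sites = site_pi(major, minor, pool_size)
    seg = (np.asarray(major) > 0) & (np.asarray(minor) > 0) & (cov >= 2)
    n_chrom = 2 * pool_size
    const = tajima_constants(n_chrom)

    pos_by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    df = pd.DataFrame({"chrom": chroms, "pos": positions, "pi": pi_sites, "seg": seg})
    for chrom, g in df.groupby("chrom"):
        order = np.argsort(g["pos"].to_numpy())
        pos_by_chrom[str(chrom)] = (
            g["pos"].to_numpy()[order],
            g["pi"].to_numpy()[order],
            g["seg"].to_numpy()[order],
        )

    rows = []
    for wi, w in enumerate(windows.itertuples()):
        entry = pos_by_chrom.get(str(w.chrom))
        if entry is None:
            pi_sum, S = 0.0, 0
        else:
            pos, pis, segs = entry
            lo, hi = np.searchsorted(pos, [w.start, w.end + 1])
            pi_sum = float(np.nansum(pis[lo:hi]))
            S = int(segs[lo:hi].sum())
        if site_mask_denominator is not None:
            denom = max(float(site_mask_denominator[wi]), 1.0)
        else:
            denom = float(w.end - w.start + 1)
        theta_w = S / const["a1"]
        if S >= min_snps and S > 0:
            var = const["e1"] * S + const["e2"] * S * (S - 1)
            tajd = (pi_sum - theta_w) / np.sqrt(var) if var > 0 else np.nan
        else:
            tajd = np.nan
        rows.append(
            {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "n_snps": S,
                "pi": pi_sum / denom,
                "theta_w": theta_w,
                "tajimas_d": tajd,
            }
        )
    return pd.DataFrame(rows)


def pooled_window_diversity(
    chroms: np.ndarray,
    positions: np.ndarray,
    major: np.ndarray,
    minor: np.ndarray,
    sheet,
    windows: pd.DataFrame,
    min_snps: int = 10,
) -> pd.DataFrame:
    """Window statistics for every pool in a sample sheet, stacked long."""
    out = []
    for j, pool in enumerate(sheet.pools):
        wd = window_diversity(
            chroms, positions, major[:, j], minor[:, j], pool.pool_size, windows, min_snps
        )
        wd.insert(3, "pool_id", pool.pool_id)
        wd.insert(4, "treatment", pool.treatment)
        wd.insert(5, "replicate", pool.replicate)
        out.append(wd)
    return pd.concat(out, ignore_index=True)


def gene_mean_stat(
    windows: pd.DataFrame, genes: Sequence[GeneInterval], value_col: str
) -> pd.DataFrame:
    """Unweighted mean of a window statistic over every window whose span
    intersects the gene span (>= 1 bp overlap).  Genes with no overlapping
    window get NaN."""
    rows = []
    by_chrom = {str(c): g for c, g in windows.groupby("chrom")}
    for gene in genes:
        g = by_chrom.get(gene.chrom)
        if g is None:
            rows.append({"gene_id": gene.gene_id, value_col: np.nan, "n_windows": 0})
            continue
        hit = g[(g["start"] <= gene.end) & (g["end"] >= gene.start)]
        vals = hit[value_col].dropna()
        rows.append(
            {
                "gene_id": gene.gene_id,
                value_col: float(vals.mean()) if len(vals) else np.nan,
                "n_windows": int(len(hit)),
            }
        )
    return pd.DataFrame(rows)


def label_windows_in_peaks(windows: pd.DataFrame, peaks: Sequence) -> np.ndarray:
    """Boolean mask: window intersects any peak span."""
    mask = np.zeros(len(windows), dtype=bool)
    for i, w in enumerate(windows.itertuples()):
        for p in peaks:
            if p.chrom == str(w.chrom) and p.start <= w.end and p.end >= w.start:
                mask[i] = True
                break
    return mask


def region_contrast(
    values: np.ndarray,
    in_region: np.ndarray,
    paired_values: tuple[np.ndarray, np.ndarray] | None = None,
) -> dict:
    """Rank test of a window statistic inside versus outside peak regions.

    Default: two-sample Mann-Whitney on in/out windows.  When
    ``paired_values`` supplies matched (in, out) values per unit (e.g. one
    pair per replicate line), a Wilcoxon signed-rank test is used and the
    signed-rank statistic is reported as ``V``.
    """
    if paired_values is not None:
        v_in, v_out = paired_values
        diff = np.asarray(v_in, dtype=float) - np.asarray(v_out, dtype=float)
        diff = diff[diff != 0]
        if len(diff) < 1:
            raise ValueError("no non-zero paired differences")
        ranks = stats.rankdata(np.abs(diff))
        v_stat = float(ranks[diff > 0].sum())
        res = stats.wilcoxon(diff, alternative="two-sided", method="auto")
        return {"test": "wilcoxon-signed-rank", "V": v_stat, "p_value": float(res.pvalue)}
    values = np.asarray(values, dtype=float)
    in_region = np.asarray(in_region, dtype=bool)
    a = values[in_region & ~np.isnan(values)]
    b = values[~in_region & ~np.isnan(values)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 windows in each stratum")
    stat, pv = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {"test": "mann-whitney", "V": float(stat), "p_value": float(pv)}
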