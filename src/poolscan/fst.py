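"""Pairwise pool-seq FST and the neutral faster-X expectation.

Per-SNP FST between two pools uses an analysis-of-variance estimator in the
identity-probability formulation: unbiased estimates of the probability of
identity of two distinct chromosomes within a pool (Q1, corrected for reads
resampling the same chromosome and for finite pool size) and between pools
(Q2), combined as FST = (Q1 - Q2) / (1 - Q2).  Values may be negative;
window averages keep them unclamped.

Under pure drift the X chromosome (effective size 3/4 of autosomes at even
sex ratio) is expected to differentiate faster.  Given the observed
autosomal FST ``F_A`` and the breeding-sex ratio ``z`` (males : females),
the neutral X expectation is

    F_X = 1 - 9 (z + 1) (1 - F_A) / (8 (2z + 1) - (1 - F_A)(7z - 1))

which is 0 at F_A = 0 and 1 at F_A = 1.  Bootstrap confidence bands come
from resampling windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class FxExpectation:
    f_a: float  # observed autosomal mean window FST
    f_x_observed: float  # observed X mean window FST
    z: float
    f_x: float  # neutral expectation from f_a
    ci_low: float
    ci_high: float


def _q1_single_pool(maj: np.ndarray, mnr: np.ndarray, n_chrom: int) -> np.ndarray:
    """Unbiased within-pool identity from read counts.

    A random pair of distinct reads is identical with probability
    1/n + (1 - 1/n) Q1 (same chromosome sampled twice, or two distinct
    chromosomes); solving for Q1 de-biases the read-pair identity."""
    r = maj + mnr
    with np.errstate(invalid="ignore", divide="ignore"):
        read_pair = (maj * (maj - 1.0) + mnr * (mnr - 1.0)) / (r * (r - 1.0))
    q1 = (n_chrom * read_pair - 1.0) / (n_chrom - 1.0)
    return np.where(r >= 2, q1, np.nan)


def snp_fst(
    maj1: np.ndarray,
    mnr1: np.ndarray,
    maj2: np.ndarray,
    mnr2: np.ndarray,
    pool_size1: int,
    pool_size2: int,
    estimator: str = "anova",
) -> np.ndarray:
    """Per-SNP pairwise FST between two pools from read counts.

    ``anova`` (default) is the identity-probability estimator described in
    the module docstring; ``karlsson`` is a simpler count-based alternative
    without the pool-size correction, kept for sensitivity analysis.
    Returns NaN where undefined (coverage < 2, or both pools fixed for the
    same allele).
    """
    maj1 = np.asarray(maj1, dtype=np.float64)
    mnr1 = np.asarray(mnr1, dtype=np.float64)
    maj2 = np.asarray(maj2, dtype=np.float64)
    mnr2 = np.asarray(mnr2, dtype=np.float64)
    r1 = maj1 + mnr1
    r2 = maj2 + mnr2
    with np.errstate(invalid="ignore", divide="ignore"):
        q2 = (maj1 * maj2 + mnr1 * mnr2) / (r1 * r2)
    if estimator == "anova":
        q1a = _q1_single_pool(maj1, mnr1, 2 * pool_size1)
        q1b = _q1_single_pool(maj2, mnr2, 2 * pool_size2)
        q1 = (q1a + q1b) / 2.0
    elif estimator == "karlsson":
        with np.errstate(invalid="ignore", divide="ignore"):
            h1 = (maj1 * (maj1 - 1.0) + mnr1 * (mnr1 - 1.0)) / (r1 * (r1 - 1.0))
            h2 = (maj2 * (maj2 - 1.0) + mnr2 * (mnr2 - 1.0)) / (r2 * (r2 - 1.0))
        q1 = (h1 + h2) / 2.0
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = (q1 - q2) / (1.0 - q2)
    bad = (r1 < 2) | (r2 < 2) | np.isclose(q2, 1.0)
    return np.where(bad, np.nan, fst)


def pairwise_fst_table(
    chroms: np.ndarray,
    positions: np.ndarray,
    major: np.ndarray,
    minor: np.ndarray,
    sheet,
    estimator: str = "anova",
) -> pd.DataFrame:
    """Per-SNP E-vs-M FST for every replicate pair in the sheet (long)."""
    out = []
    for e_idx, m_idx in sheet.replicate_pairs():
        fst = snp_fst(
            major[:, e_idx],
            minor[:, e_idx],
            major[:, m_idx],
            minor[:, m_idx],
            sheet.pools[e_idx].pool_size,
            sheet.pools[m_idx].pool_size,
            estimator,
        )
        out.append(
            pd.DataFrame(
                {
                    "chrom": chroms,
                    "pos": positions,
                    "replicate": sheet.pools[e_idx].replicate,
                    "fst": fst,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def window_fst(fst_table: pd.DataFrame, windows: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of per-SNP FST inside each window (average of
    ratios), per replicate; windows without SNPs are missing."""
    out = []
    for rep, g in fst_table.groupby("replicate"):
        by_chrom = {str(c): gg for c, gg in g.groupby("chrom")}
        for w in windows.itertuples():
            gg = by_chrom.get(str(w.chrom))
            if gg is None:
                vals = pd.Series(dtype=float)
            else:
                sel = gg[(gg["pos"] >= w.start) & (gg["pos"] <= w.end)]
                vals = sel["fst"].dropna()
            out.append(
                {
                    "chrom": w.chrom,
                    "start": w.start,
                    "end": w.end,
                    "replicate": rep,
                    "n_snps": int(len(vals)),
                    "fst": float(vals.mean()) if len(vals) else np.nan,
                }
            )
    return pd.DataFrame(out)


def fx_expected(f_a: float | np.ndarray, z: float) -> float | np.ndarray:
    """Neutral X-chromosome FST expected from autosomal FST and breeding
    sex ratio z (males : females)."""
    if z <= 0:
        raise ValueError("z must be > 0")
    f_a = np.asarray(f_a, dtype=np.float64)
    if np.any((f_a < 0) | (f_a > 1)):
        raise ValueError("f_a must lie in [0, 1]")
    denom = 8.0 * (2.0 * z + 1.0) - (1.0 - f_a) * (7.0 * z - 1.0)
    if np.any(denom <= 0):
        raise ValueError("F_X denominator non-positive")
    out = 1.0 - 9.0 * (z + 1.0) * (1.0 - f_a) / denom
    return float(out) if out.ndim == 0 else out


def bootstrap_fx(
    window_fst_values: pd.DataFrame,
    x_chroms: set[str] | frozenset[str],
    z: float,
    n_boot: int = 1000,
    seed: int = 0,
    autosome_only_pool: bool = False,
) -> FxExpectation:
    """Bootstrap band for the neutral X expectation, one replicate pair.

    Each iteration draws (with replacement) as many windows as there are
    autosomal windows — from the set of all windows by default — averages
    their FST and converts via ``fx_expected``; the 2.5/97.5 percentiles of
    the resulting distribution form the confidence band.
    """
    df = window_fst_values.dropna(subset=["fst"])
    is_x = df["chrom"].astype(str).isin(x_chroms).to_numpy()
    fst = df["fst"].to_numpy()
    n_auto = int((~is_x).sum())
    if n_auto == 0:
        raise ValueError("no autosomal windows")
    f_a = float(fst[~is_x].mean())
    f_x_obs = float(fst[is_x].mean()) if is_x.any() else np.nan
    pool = fst[~is_x] if autosome_only_pool else fst
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(pool), size=(n_boot, n_auto))
    boot_fa = np.clip(pool[idx].mean(axis=1), 0.0, 1.0)
    boot_fx = fx_expected(boot_fa, z)
    lo, hi = np.percentile(boot_fx, [2.5, 97.5])
    return FxExpectation(f_a, f_x_obs, z, fx_expected(np.clip(f_a, 0, 1), z), float(lo), float(hi))


def xa_ratio(
    windows: pd.DataFrame,
    x_chroms: set[str] | frozenset[str],
    value_col: str,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Ratio of the X-chromosome mean to the autosome mean of a window
    statistic, with a bootstrap 95% CI (windows resampled within strata)."""
    df = windows.dropna(subset=[value_col])
    is_x = df["chrom"].astype(str).isin(x_chroms).to_numpy()
    vals = df[value_col].to_numpy(dtype=float)
    x_vals, a_vals = vals[is_x], vals[~is_x]
    if len(x_vals) == 0 or len(a_vals) == 0:
        raise ValueError("both X and autosome strata must be non-empty")
    a_mean = a_vals.mean()
    if a_mean == 0:
        raise ValueError("autosome mean is zero; ratio undefined")
    rng = np.random.default_rng(seed)
    bx = x_vals[rng.integers(0, len(x_vals), size=(n_boot, len(x_vals)))].mean(axis=1)
    ba = a_vals[rng.integers(0, len(a_vals), size=(n_boot, len(a_vals)))].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = bx / ba
    lo, hi = np.nanpercentile(ratios, [2.5, 97.5])
    return {
        "ratio": float(x_vals.mean() / a_mean),
        "x_mean": float(x_vals.mean()),
        "autosome_mean": float(a_mean),
        "ci_low": float(lo),
        "ci_high": float(hi),
    }
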