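"""Linking the genomic scan to gene-expression inputs.

Genes within a flanking distance of top SNPs are collected and their
overlap with differential-expression (DE) gene sets is compared to the
overlap of equally sized random gene sets drawn from the annotation.
Gene-level diversity and differentiation statistics are contrasted between
DE and non-DE genes, and the change in sex-biased expression between
treatments (delta_SB = log2FC_E - log2FC_M, per tissue) is modelled on
Tajima's D per treatment with chromosome-type interactions (ANCOVA).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneInterval


@dataclass
class OverlapTestResult:
    n_query: int
    observed_overlap_prop: float
    resample_mean: float
    resample_q95: float
    empirical_p: float
    significant: bool


def genes_near_snps(
    top_chroms: np.ndarray,
    top_positions: np.ndarray,
    genes: Sequence[GeneInterval],
    flank_bp: int = 10_000,
) -> set[str]:
    """Genes with any top SNP within [start - flank, end + flank]
    (inclusive); all ties are kept."""
    by_chrom: dict[str, np.ndarray] = {}
    df = pd.DataFrame({"chrom": top_chroms, "pos": top_positions})
    for chrom, g in df.groupby("chrom"):
        by_chrom[str(chrom)] = np.sort(g["pos"].to_numpy())
    hits = set()
    for gene in genes:
        pos = by_chrom.get(gene.chrom)
        if pos is None:
            continue
        lo = np.searchsorted(pos, gene.start - flank_bp, side="left")
        hi = np.searchsorted(pos, gene.end + flank_bp, side="right")
        if hi > lo:
            hits.add(gene.gene_id)
    return hits


def overlap_resampling_test(
    query: set[str],
    de: set[str],
    universe: Sequence[str],
    n_resample: int = 1000,
    seed: int = 0,
) -> OverlapTestResult:
    """Is the DE overlap of the query gene set larger than chance?

    Each resample draws ``len(query)`` genes without replacement from the
    universe and records its DE overlap proportion.  The significance call
    uses the 95th-percentile rule; ``empirical_p`` additionally reports the
    add-one-corrected tail fraction (never exactly zero).
    """
    universe = list(universe)
    n_q = len(query)
    if n_q < 1:
        raise ValueError("query set is empty")
    if n_q > len(universe):
        raise ValueError("query larger than universe")
    de_arr = np.array([g in de for g in universe])
    observed = len(query & de) / n_q
    rng = np.random.default_rng(seed)
    props = np.empty(n_resample)
    for i in range(n_resample):
        idx = rng.choice(len(universe), size=n_q, replace=False)
        props[i] = de_arr[idx].mean()
    q95 = float(np.quantile(props, 0.95))
    emp_p = (1 + int((props >= observed).sum())) / (n_resample + 1)
    return OverlapTestResult(
        n_query=n_q,
        observed_overlap_prop=float(observed),
        resample_mean=float(props.mean()),
        resample_q95=q95,
        empirical_p=float(emp_p),
        significant=bool(observed >= q95),
    )


def de_contrast(
    gene_stats: pd.DataFrame,
    stat_col: str,
    de_col: str = "is_de",
    strata_cols: Sequence[str] = ("chrom_type",),
    mode: str = "one-sample",
) -> pd.DataFrame:
    """DE vs non-DE contrast of a gene-level statistic, per stratum.

    Default mode tests DE-gene values against the single constant equal to
    the non-DE mean with a one-sample Wilcoxon signed-rank test (reported
    as ``V``), which keeps the huge non-DE sample from dominating the
    significance; ``two-sample`` switches to a Mann-Whitney rank-sum test.
    """
    rows = []
    for keys, g in gene_stats.groupby(list(strata_cols)):
        if not isinstance(keys, tuple):
            keys = (keys,)
        de_vals = g.loc[g[de_col].astype(bool), stat_col].dropna().to_numpy()
        non_vals = g.loc[~g[de_col].astype(bool), stat_col].dropna().to_numpy()
        row = dict(zip(strata_cols, keys))
        row.update({"n_de": len(de_vals), "n_non_de": len(non_vals)})
        if len(de_vals) == 0 or len(non_vals) == 0:
            row.update({"V": np.nan, "p_value": np.nan})
            rows.append(row)
            continue
        row["de_mean"] = float(de_vals.mean())
        row["non_de_mean"] = float(non_vals.mean())
        if mode == "one-sample":
            diff = de_vals - non_vals.mean()
            nz = diff[diff != 0]
            if len(nz) == 0:
                row.update({"V": 0.0, "p_value": 1.0})
            else:
                ranks = stats.rankdata(np.abs(nz))
                v = float(ranks[nz > 0].sum())
                p = float(stats.wilcoxon(nz, alternative="two-sided").pvalue)
                row.update({"V": v, "p_value": p})
        elif mode == "two-sample":
            u, p = stats.mannwhitneyu(de_vals, non_vals, alternative="two-sided")
            row.update({"V": float(u), "p_value": float(p)})
        else:
            raise ValueError(f"unknown mode {mode!r}")
        rows.append(row)
    return pd.DataFrame(rows)


def _chrom_dummies(chrom_type: pd.Series) -> tuple[pd.DataFrame, list[str]]:
    levels = sorted(chrom_type.unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 chromosome types for the ANCOVA")
    cols = {}
    for lev in levels[1:]:
        cols[f"chrom[{lev}]"] = (chrom_type == lev).astype(float).to_numpy()
    return pd.DataFrame(cols), levels


def ancova_delta_sb(records: pd.DataFrame) -> dict:
    """OLS of delta_sb on chromosome type, Tajima's D per treatment, and
    their interactions, with sequential (type-I) F tests per term.

    ``records`` needs columns delta_sb, tajd_e, tajd_m, chrom_type; rows
    with missing covariates are dropped.
    """
    import statsmodels.api as sm

    df = records.dropna(subset=["delta_sb", "tajd_e", "tajd_m", "chrom_type"]).copy()
    counts = df["chrom_type"].value_counts()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError(
            "each chromosome type needs >= 2 records for a full-rank ANCOVA; "
            f"got {counts.to_dict()}"
        )
    dummies, levels = _chrom_dummies(df["chrom_type"])
    y = df["delta_sb"].to_numpy()
    n = len(df)
    blocks: list[tuple[str, np.ndarray]] = [("chromosome", dummies.to_numpy())]
    blocks.append(("tajd_e", df["tajd_e"].to_numpy()[:, None]))
    blocks.append(("tajd_m", df["tajd_m"].to_numpy()[:, None]))
    blocks.append(("tajd_e:chromosome", dummies.to_numpy() * df["tajd_e"].to_numpy()[:, None]))
    blocks.append(("tajd_m:chromosome", dummies.to_numpy() * df["tajd_m"].to_numpy()[:, None]))

    X_full = np.column_stack([np.ones(n)] + [b for _, b in blocks])
    full = sm.OLS(y, X_full).fit()

    # sequential F tests: add one term block at a time
    seq_rows = []
    rss_prev = float(((y - y.mean()) ** 2).sum())
    cols_so_far = [np.ones(n)]
    df_resid_full = full.df_resid
    sigma2_full = full.ssr / df_resid_full
    for name, block in blocks:
        cols_so_far.append(block)
        fit = sm.OLS(y, np.column_stack(cols_so_far)).fit()
        df_term = block.shape[1]
        f_stat = (rss_prev - fit.ssr) / df_term / sigma2_full
        p = float(stats.f.sf(f_stat, df_term, df_resid_full))
        seq_rows.append({"term": name, "df": df_term, "F": float(f_stat), "p_value": p})
        rss_prev = fit.ssr

    coef_names = ["intercept"]
    for name, block in blocks:
        if block.shape[1] == 1:
            coef_names.append(name)
        else:
            coef_names.extend(f"{name}[{lev}]" for lev in levels[1:])
    coef_table = pd.DataFrame(
        {
            "term": coef_names,
            "estimate": full.params,
            "se": full.bse,
            "t": full.tvalues,
            "p_value": full.pvalues,
        }
    )
    return {"coefficients": coef_table, "anova": pd.DataFrame(seq_rows), "model": full}
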