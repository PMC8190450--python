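"""Short-range linkage disequilibrium from read-pair co-observations.

Pool-seq loses haplotype phase beyond the read-pair scale, but two SNPs
covered by the same sequenced fragment are phased by construction.  For
each qualifying SNP pair, two-locus haplotype counts are tallied over read
pairs covering both sites and

    r2 = D^2 / (p1 q1 p2 q2),   D = f(AB) - f(A) f(B)

is computed directly (no EM).  Mean r2 per exact base-pair distance class,
classes with too few pairs dropped, and an OLS fit of mean r2 on
log(distance) give the decay slope; steeper (more negative) slopes mean
faster LD decay, i.e. more effective recombination.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .simulate import ReadPairObs


@dataclass
class PairLd:
    chrom: str
    pos1: int
    pos2: int
    distance_bp: int
    n_joint: int
    r2: float


@dataclass
class LdFilterConfig:
    min_maf: float = 0.1
    min_cov: int = 10
    max_cov: int = 400
    min_qual: int = 20  # bases with Phred > min_qual are used


@dataclass
class DecayFit:
    region_id: str
    intercept: float
    decay_slope: float
    slope_se: float
    n_classes: int


def read_pair_table(path: str | Path) -> list[ReadPairObs]:
    """Read the two-site read-pair TSV back into observation records."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "allele1": str, "allele2": str})
    out: dict[int, ReadPairObs] = {}
    for r in df.itertuples():
        rp = out.setdefault(int(r.pair_id), ReadPairObs(int(r.pair_id), str(r.chrom), []))
        for pos, allele, qual in ((r.pos1, r.allele1, r.qual1), (r.pos2, r.allele2, r.qual2)):
            key = (int(pos), str(allele), int(qual))
            if key not in rp.sites:
                rp.sites.append(key)
    for rp in out.values():
        rp.sites.sort()
    return list(out.values())


def pair_r2_from_haplotype_counts(counts: dict[tuple[str, str], int]) -> float | None:
    """r2 from two-locus haplotype counts; None when a margin is fixed."""
    n = sum(counts.values())
    if n == 0:
        return None
    a_counts: Counter = Counter()
    b_counts: Counter = Counter()
    for (a, b), c in counts.items():
        a_counts[a] += c
        b_counts[b] += c
    if len(a_counts) < 2 or len(b_counts) < 2:
        return None
    a_ref = sorted(a_counts)[0]
    b_ref = sorted(b_counts)[0]
    p1 = a_counts[a_ref] / n
    p2 = b_counts[b_ref] / n
    f_ab = sum(c for (a, b), c in counts.items() if a == a_ref and b == b_ref) / n
    d = f_ab - p1 * p2
    denom = p1 * (1 - p1) * p2 * (1 - p2)
    if denom == 0:
        return None
    return float(d * d / denom)


def compute_pair_ld(
    observations: Iterable[ReadPairObs], filters: LdFilterConfig | None = None
) -> list[PairLd]:
    """Tally joint haplotype observations and compute r2 per SNP pair.

    Site-level filters (minor-allele frequency, coverage window) are
    evaluated on the read observations themselves after dropping bases at
    or below the quality cut-off.
    """
    filters = filters or LdFilterConfig()
    site_alleles: dict[tuple[str, int], Counter] = defaultdict(Counter)
    joint: dict[tuple[str, int, int], Counter] = defaultdict(Counter)
    for rp in observations:
        kept = [(pos, al) for pos, al, q in rp.sites if q > filters.min_qual]
        seen = {}
        for pos, al in kept:
            if pos not in seen:  # overlapping mates: count a site once per pair
                seen[pos] = al
                site_alleles[(rp.chrom, pos)][al] += 1
        pos_sorted = sorted(seen)
        for i in range(len(pos_sorted)):
            for j in range(i + 1, len(pos_sorted)):
                pa, pb = pos_sorted[i], pos_sorted[j]
                joint[(rp.chrom, pa, pb)][(seen[pa], seen[pb])] += 1

    def site_ok(chrom: str, pos: int) -> bool:
        c = site_alleles[(chrom, pos)]
        cov = sum(c.values())
        if not filters.min_cov <= cov <= filters.max_cov:
            return False
        if len(c) < 2:
            return False
        maf = min(c.values()) / cov if len(c) == 2 else sorted(c.values())[-2] / cov
        return maf > filters.min_maf

    out: list[PairLd] = []
    for (chrom, p1, p2), counts in sorted(joint.items()):
        if not (site_ok(chrom, p1) and site_ok(chrom, p2)):
            continue
        r2 = pair_r2_from_haplotype_counts(dict(counts))
        if r2 is None:
            continue
        n_joint = sum(counts.values())
        out.append(PairLd(chrom, p1, p2, p2 - p1, n_joint, r2))
    return out


def bin_by_distance(
    pairs: Sequence[PairLd], min_pairs_per_class: int = 5, bin_width: int = 1
) -> pd.DataFrame:
    """Mean r2 per distance class; classes with fewer than
    ``min_pairs_per_class`` SNP pairs are dropped.

    Classes are exact bp distances by default (``bin_width=1``); coarser
    bins pool neighbouring distances and report the mean distance of their
    members — useful when the SNP-pair count per exact distance is small.
    """
    if not pairs:
        return pd.DataFrame(columns=["distance_bp", "mean_r2", "n"])
    d = np.array([p.distance_bp for p in pairs])
    df = pd.DataFrame({"bin": (d - 1) // bin_width, "d": d, "r2": [p.r2 for p in pairs]})
    g = df.groupby("bin").agg(distance_bp=("d", "mean"), mean_r2=("r2", "mean"), n=("r2", "count"))
    g = g[g["n"] >= min_pairs_per_class].reset_index(drop=True)
    return g.sort_values("distance_bp").reset_index(drop=True)


def fit_decay(class_table: pd.DataFrame, region_id: str = "") -> DecayFit:
    """OLS of mean r2 on the natural log of distance."""
    if len(class_table) < 2:
        raise ValueError("need at least 2 distance classes for a decay fit")
    x = np.log(class_table["distance_bp"].to_numpy(dtype=float))
    y = class_table["mean_r2"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    coef, res_ss, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    dof = len(y) - 2
    sigma2 = float(((y - fitted) ** 2).sum() / dof) if dof > 0 else np.nan
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return DecayFit(
        region_id=region_id,
        intercept=float(coef[0]),
        decay_slope=float(coef[1]),
        slope_se=float(np.sqrt(cov[1, 1])) if dof > 0 else np.nan,
        n_classes=len(y),
    )


def compare_decay(class_tables: dict[tuple[str, str], pd.DataFrame]) -> dict:
    """Region/treatment contrasts of the decay slope.

    ``class_tables`` maps (region_id, treatment) to a distance-class table.
    Fits each group and, on the stacked class-level data, a linear model
    with log-distance, region and treatment main effects plus their
    interactions with log-distance; interaction p-values test slope
    differences.
    """
    import statsmodels.api as sm

    fits = {}
    rows = []
    for (region, treatment), table in class_tables.items():
        if len(table) >= 2:
            fits[(region, treatment)] = fit_decay(table, region_id=region)
        for r in table.itertuples():
            rows.append(
                {
                    "region": region,
                    "treatment": treatment,
                    "log_d": np.log(r.distance_bp),
                    "r2": r.mean_r2,
                }
            )
    df = pd.DataFrame(rows)
    result = {"fits": fits, "interaction_p": {}}
    if df.empty or len(fits) < 2:
        return result
    regions = sorted(df["region"].unique())
    treatments = sorted(df["treatment"].unique())
    X_cols = {"const": np.ones(len(df)), "log_d": df["log_d"].to_numpy()}
    for r in regions[1:]:
        ind = (df["region"] == r).to_numpy(dtype=float)
        X_cols[f"region[{r}]"] = ind
        X_cols[f"region[{r}]:log_d"] = ind * df["log_d"].to_numpy()
    for t in treatments[1:]:
        ind = (df["treatment"] == t).to_numpy(dtype=float)
        X_cols[f"treatment[{t}]"] = ind
        X_cols[f"treatment[{t}]:log_d"] = ind * df["log_d"].to_numpy()
    X = pd.DataFrame(X_cols)
    model = sm.OLS(df["r2"].to_numpy(), X).fit()
    for name in X.columns:
        if name.endswith(":log_d"):
            result["interaction_p"][name] = float(model.pvalues[name])
    result["model"] = model
    return result
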