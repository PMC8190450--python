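"""Consistent allele-frequency-change scan across replicated treatment pools.

Each biallelic SNP is tested with a quasibinomial GLM of the major-allele
read counts on treatment (logit link).  Because treatment is the only, and
binary, predictor, the maximum-likelihood fit has a closed form: the fitted
frequency in each treatment group is the coverage-weighted pooled
frequency, and the treatment coefficient is the difference of group
log-odds.  The dispersion is the Pearson chi-square divided by its degrees
of freedom (n_pools - 2) and is not floored at 1; inference uses a t
statistic with n_pools - 2 degrees of freedom and dispersion-scaled
variance — standard quasi-likelihood practice.  This closed form is exactly
the IRLS solution, and the test suite checks it against an independently
fitted GLM.

P-values are converted to Storey q-values; SNPs with q below a threshold
(default 0.05) are "top SNPs".  Top SNPs within 50 kb of each other chain
into clusters ("peaks"); auxiliary checks cover treatment-label
permutations, per-chromosome excess, coverage inside peaks, and fixed
differences between treatments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import SnpRecord, snps_to_arrays
from .io import SampleSheet, SyncSite  # noqa: F401  (SyncSite used in signatures)


@dataclass
class GlmScanResult:
    chrom: str
    pos: int
    beta_treatment: float
    dispersion_phi: float
    p_value: float
    q_value: float | None = None
    is_top: bool = False


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    n_snps: int
    members: np.ndarray  # positions of member top SNPs


# ---------------------------------------------------------------------------
# quasibinomial GLM


def apply_pseudocount(
    major: np.ndarray, minor: np.ndarray, scope: Literal["all-pools", "per-pool"] = "all-pools"
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-count correction: if any major or minor count of a SNP is zero,
    add 1.  ``all-pools`` (default) adds 1 to every count of the affected
    SNP; ``per-pool`` adds 1 only to both counts of pools holding a zero."""
    major = np.asarray(major, dtype=np.float64)
    minor = np.asarray(minor, dtype=np.float64)
    has_zero = ((major == 0) | (minor == 0))
    if scope == "all-pools":
        bump = np.any(has_zero, axis=-1, keepdims=True)
        return major + bump, minor + bump
    elif scope == "per-pool":
        return major + has_zero, minor + has_zero
    raise ValueError(f"unknown pseudocount scope {scope!r}")


def glm_scan_arrays(
    major: np.ndarray,
    minor: np.ndarray,
    e_mask: np.ndarray,
    pseudocount: Literal["all-pools", "per-pool"] = "all-pools",
    weights: Literal["none", "counts"] = "none",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised quasibinomial GLM for every SNP row.

    The response is the per-pool major-allele frequency; by default each
    pool is one unweighted observation (the conventional quasibinomial fit
    of a proportion response), so the dispersion absorbs between-pool
    variance — drift as well as read noise — on the frequency scale.
    ``weights='counts'`` instead weights each pool by its read depth
    (a binomial fit of the (major, minor) counts).

    Returns (beta, phi, p): the treatment (E vs M) log-odds effect on the
    major-allele frequency, the Pearson dispersion, and the two-sided
    p-value from a t test with n_pools - 2 df.
    """
    major = np.atleast_2d(np.asarray(major, dtype=np.float64))
    minor = np.atleast_2d(np.asarray(minor, dtype=np.float64))
    n_snps, k = major.shape
    if k < 3:
        raise ValueError("need at least 3 pools for a dispersion estimate")
    e_mask = np.asarray(e_mask, dtype=bool)
    m_mask = ~e_mask
    if e_mask.sum() < 2 or m_mask.sum() < 2:
        raise ValueError("need at least 2 pools per treatment")

    major, minor = apply_pseudocount(major, minor, pseudocount)
    total = major + minor
    if weights == "none":
        y = major / total
        w = np.ones_like(total)
    elif weights == "counts":
        y = major / total
        w = total
    else:
        raise ValueError(f"unknown weights {weights!r}")

    # group MLE: the prior-weighted mean frequency per treatment
    mu_e = (w * y)[:, e_mask].sum(axis=1) / w[:, e_mask].sum(axis=1)
    mu_m = (w * y)[:, m_mask].sum(axis=1) / w[:, m_mask].sum(axis=1)

    with np.errstate(divide="ignore"):
        beta = np.log(mu_e / (1 - mu_e)) - np.log(mu_m / (1 - mu_m))

    mu = np.where(e_mask[None, :], mu_e[:, None], mu_m[:, None])
    with np.errstate(invalid="ignore", divide="ignore"):
        pearson = w * (y - mu) ** 2 / (mu * (1 - mu))
    pearson = np.where(np.isfinite(pearson), pearson, 0.0)
    df = k - 2
    phi = pearson.sum(axis=1) / df

    w_e = (w[:, e_mask] * (mu_e * (1 - mu_e))[:, None]).sum(axis=1)
    w_m = (w[:, m_mask] * (mu_m * (1 - mu_m))[:, None]).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(phi * (1.0 / w_e + 1.0 / w_m))
        t = beta / se
    # exact balance (beta == 0) is a definite null even when phi == 0
    t = np.where(beta == 0.0, 0.0, t)
    p = np.where(np.isfinite(t), 2.0 * stats.t.sf(np.abs(np.where(np.isfinite(t), t, 0.0)), df), 0.0)
    return beta, phi, p


def fit_snp_glm(
    snp: SnpRecord,
    sheet: SampleSheet,
    pseudocount: Literal["all-pools", "per-pool"] = "all-pools",
    weights: Literal["none", "counts"] = "none",
) -> GlmScanResult:
    beta, phi, p = glm_scan_arrays(
        snp.major[None, :], snp.minor[None, :], sheet.e_mask, pseudocount, weights
    )
    return GlmScanResult(snp.chrom, snp.pos, float(beta[0]), float(phi[0]), float(p[0]))


def scan_snps(
    snps: Sequence[SnpRecord],
    sheet: SampleSheet,
    q_threshold: float = 0.05,
    pseudocount: Literal["all-pools", "per-pool"] = "all-pools",
    weights: Literal["none", "counts"] = "none",
) -> pd.DataFrame:
    """Full scan: GLM per SNP, Storey q-values, top-SNP flags."""
    chroms, pos, major, minor = snps_to_arrays(snps)
    beta, phi, p = glm_scan_arrays(major, minor, sheet.e_mask, pseudocount, weights)
    q = storey_qvalues(p)
    return pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "beta_treatment": beta,
            "dispersion_phi": phi,
            "p_value": p,
            "q_value": q,
            "is_top": q < q_threshold,
        }
    )


# ---------------------------------------------------------------------------
# Storey q-values


def _natural_cubic_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline regression basis (truncated-power form).

    With K knots the basis spans K functions including the constant; the
    fit is linear beyond the boundary knots.
    """
    K = len(knots)

    def d(j: int, xs: np.ndarray) -> np.ndarray:
        num = np.clip(xs - knots[j], 0, None) ** 3 - np.clip(xs - knots[K - 1], 0, None) ** 3
        return num / (knots[K - 1] - knots[j])

    cols = [np.ones_like(x), x]
    for j in range(K - 2):
        cols.append(d(j, x) - d(K - 2, x))
    return np.column_stack(cols)


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's null-proportion estimate, spline-smoothed over a lambda grid
    and evaluated at the grid maximum, clipped to (0, 1]."""
    p = np.asarray(p, dtype=np.float64)
    if lambdas is None:
        lambdas = np.arange(0.0, 0.9001, 0.05)
    m = len(p)
    pi0_raw = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    # natural cubic spline with df = 3: knots at the grid range thirds
    knots = np.quantile(lambdas, [0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0])
    X = _natural_cubic_basis(lambdas, knots)
    coef, *_ = np.linalg.lstsq(X, pi0_raw, rcond=None)
    x_eval = np.array([lambdas[-1]])
    pi0 = float((_natural_cubic_basis(x_eval, knots) @ coef)[0])
    return float(min(max(pi0, 1.0 / m), 1.0))


def storey_qvalues(p: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """Storey–Tibshirani q-values.

    q_(i) = min_{j >= i} pi0 * m * p_(j) / j on the sorted p-values,
    mapped back to input order.
    """
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if pi0 is None:
        pi0 = estimate_pi0(p) if m > 1 else 1.0
    order = np.argsort(p, kind="mergesort")
    p_sorted = p[order]
    ranks = np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate((pi0 * m * p_sorted / ranks)[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# treatment-label permutations


def enumerate_label_permutations(sheet: SampleSheet) -> list[np.ndarray]:
    """All reassignments of the E labels among the pools, excluding the
    observed assignment and its exact complement, in lexicographic order.

    For a balanced k-vs-k design this yields C(2k, k) - 2 assignments
    (68 for 4 vs 4); each is returned as a boolean E mask."""
    e_mask = sheet.e_mask
    k = int(e_mask.sum())
    n = sheet.n_pools
    if n - k != k:
        raise ValueError("label permutation scheme requires a balanced design")
    observed = frozenset(np.flatnonzero(e_mask).tolist())
    complement = frozenset(np.flatnonzero(~e_mask).tolist())
    out = []
    for comb in itertools.combinations(range(n), k):
        s = frozenset(comb)
        if s == observed or s == complement:
            continue
        mask = np.zeros(n, dtype=bool)
        mask[list(comb)] = True
        out.append(mask)
    return out


def permutation_scan(
    snps: Sequence[SnpRecord] | tuple[np.ndarray, np.ndarray],
    sheet: SampleSheet,
    mode: Literal["whole-genome", "per-snp"] = "whole-genome",
    n_perm: int | None = None,
    seed: int | None = None,
    alpha: float = 0.05,
    q_threshold: float | None = None,
    pseudocount: Literal["all-pools", "per-pool"] = "all-pools",
) -> pd.DataFrame:
    """Count of nominally significant SNPs under permuted treatment labels.

    ``whole-genome`` applies one shared relabelling to every SNP per
    permutation (preserving cross-SNP allele-frequency correlation);
    ``per-snp`` draws an independent relabelling per SNP.  Returns one row
    per permutation with ``n_p_below`` (SNPs with p < alpha) and, when
    ``q_threshold`` is given, ``n_top`` at that q cut-off.
    """
    if isinstance(snps, tuple):
        major, minor = snps
    else:
        _, _, major, minor = snps_to_arrays(snps)
    perms = enumerate_label_permutations(sheet)
    if mode == "whole-genome":
        if n_perm is None:
            n_perm = len(perms)
        if n_perm > len(perms):
            raise ValueError(f"only {len(perms)} unique assignments available")
        rows = []
        for i, mask in enumerate(perms[:n_perm]):
            _, _, p = glm_scan_arrays(major, minor, mask, pseudocount)
            row = {"perm": i, "n_p_below": int((p < alpha).sum())}
            if q_threshold is not None:
                row["n_top"] = int((storey_qvalues(p) < q_threshold).sum())
            rows.append(row)
        return pd.DataFrame(rows, columns=["perm", "n_p_below"] + (["n_top"] if q_threshold is not None else []))
    elif mode == "per-snp":
        if seed is None:
            raise ValueError("per-snp mode requires a seed")
        if n_perm is None:
            raise ValueError("per-snp mode requires n_perm")
        rng = np.random.default_rng(seed)
        n_snps = major.shape[0]
        rows = []
        for i in range(n_perm):
            idx = rng.integers(0, len(perms), size=n_snps)
            p = np.empty(n_snps)
            for u in np.unique(idx):
                sel = idx == u
                _, _, p[sel] = glm_scan_arrays(major[sel], minor[sel], perms[u], pseudocount)
            row = {"perm": i, "n_p_below": int((p < alpha).sum())}
            if q_threshold is not None:
                row["n_top"] = int((storey_qvalues(p) < q_threshold).sum())
            rows.append(row)
        return pd.DataFrame(rows, columns=["perm", "n_p_below"] + (["n_top"] if q_threshold is not None else []))
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# clustering and sanity checks


def cluster_top_snps(
    chroms: np.ndarray, positions: np.ndarray, link_bp: int = 50_000
) -> list[Peak]:
    """Single-linkage chaining of top SNPs: consecutive SNPs on the same
    chromosome join one peak iff their gap is <= ``link_bp`` (inclusive)."""
    df = pd.DataFrame({"chrom": chroms, "pos": positions})
    peaks: list[Peak] = []
    for chrom, g in df.groupby("chrom", sort=False):
        pos = np.sort(g["pos"].to_numpy())
        if len(pos) == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > link_bp)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for a, b in zip(starts, ends):
            members = pos[a : b + 1]
            peaks.append(Peak(str(chrom), int(members[0]), int(members[-1]), len(members), members))
    return peaks


def major_peaks(peaks: Sequence[Peak], min_snps: int = 10) -> list[Peak]:
    """Clusters with more than ``min_snps`` member SNPs."""
    return [p for p in peaks if p.n_snps > min_snps]


def chromosome_excess_test(
    top_counts: dict[str, int], background_counts: dict[str, int]
) -> pd.DataFrame:
    """Exact binomial test of each chromosome's share of top SNPs against
    its share of background SNPs; Bonferroni-adjusted two-sided p."""
    chroms = sorted(background_counts)
    n_top = sum(top_counts.get(c, 0) for c in chroms)
    n_bg = sum(background_counts.values())
    if n_bg <= 0:
        raise ValueError("background counts must be positive")
    rows = []
    for c in chroms:
        expect = background_counts[c] / n_bg
        k = top_counts.get(c, 0)
        pv = stats.binomtest(k, n_top, expect, alternative="two-sided").pvalue if n_top else np.nan
        rows.append({"chrom": c, "n_top": k, "expected": n_top * expect, "p": pv})
    df = pd.DataFrame(rows)
    df["p_bonferroni"] = np.minimum(df["p"] * len(df), 1.0)
    return df


def peak_coverage_check(
    peaks: Sequence[Peak],
    sites: Sequence[SyncSite],
    n_random: int = 100,
    seed: int = 0,
) -> dict:
    """Compare read coverage inside peaks against random non-peak regions.

    Random regions reuse lengths resampled from the peak length
    distribution and are placed uniformly on non-peak sequence; coverage
    per region is the mean across-pool summed coverage of its sites.  A
    Mann-Whitney rank test compares the two sets of region means.
    """
    if not peaks:
        raise ValueError("no peaks supplied")
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    rng = np.random.default_rng(seed)
    pos_by_chrom: dict[str, np.ndarray] = {}
    cov_by_chrom: dict[str, np.ndarray] = {}
    df_rows = [(s.chrom, s.pos, int(s.counts[:, :4].sum())) for s in sites]
    site_df = pd.DataFrame(df_rows, columns=["chrom", "pos", "cov"])
    for chrom, g in site_df.groupby("chrom"):
        order = np.argsort(g["pos"].to_numpy())
        pos_by_chrom[str(chrom)] = g["pos"].to_numpy()[order]
        cov_by_chrom[str(chrom)] = g["cov"].to_numpy()[order]

    def region_mean(chrom: str, start: int, end: int) -> float:
        pos = pos_by_chrom.get(chrom)
        if pos is None:
            return np.nan
        lo, hi = np.searchsorted(pos, [start, end + 1])
        if hi <= lo:
            return np.nan
        return float(cov_by_chrom[chrom][lo:hi].mean())

    peak_means = np.array([region_mean(p.chrom, p.start, p.end) for p in peaks])
    lengths = np.array([max(1, p.end - p.start + 1) for p in peaks])
    chrom_span = {c: (int(v.min()), int(v.max())) for c, v in pos_by_chrom.items()}
    peak_ivals = {c: [(p.start, p.end) for p in peaks if p.chrom == c] for c in chrom_span}

    rand_means = []
    attempts = 0
    while len(rand_means) < n_random:
        attempts += 1
        if attempts > 100 * n_random:
            raise ValueError("genome too small to place random non-peak regions")
        length = int(rng.choice(lengths))
        chrom = rng.choice(list(chrom_span))
        lo, hi = chrom_span[chrom]
        if hi - lo + 1 <= length:
            continue
        start = int(rng.integers(lo, hi - length + 1))
        end = start + length - 1
        if any(start <= pe and ps <= end for ps, pe in peak_ivals[chrom]):
            continue
        m = region_mean(chrom, start, end)
        if np.isnan(m):
            continue
        rand_means.append(m)

    rand_means = np.array(rand_means)
    ok = ~np.isnan(peak_means)
    stat, pv = stats.mannwhitneyu(peak_means[ok], rand_means, alternative="two-sided")
    return {
        "peak_mean_coverage": float(np.nanmean(peak_means)),
        "random_mean_coverage": float(rand_means.mean()),
        "u_statistic": float(stat),
        "p_value": float(pv),
        "peak_region_means": peak_means,
        "random_region_means": rand_means,
    }


def fixed_difference_flags(snps: Sequence[SnpRecord], sheet: SampleSheet) -> np.ndarray:
    """True where the SNP is a fixed E/M difference in every replicate pair:
    observed major-allele frequency 1 in all pools of one treatment and 0
    in all pools of the other (pre-pseudocount counts; direction may differ
    between replicates)."""
    pairs = sheet.replicate_pairs()
    _, _, major, minor = snps_to_arrays(snps)
    total = major + minor
    with np.errstate(invalid="ignore"):
        freq = np.where(total > 0, major / np.maximum(total, 1), np.nan)
    flags = np.ones(len(snps), dtype=bool)
    for e_idx, m_idx in pairs:
        fe, fm = freq[:, e_idx], freq[:, m_idx]
        fixed_pair = ((fe == 1.0) & (fm == 0.0)) | ((fe == 0.0) & (fm == 1.0))
        flags &= fixed_pair
    return flags
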