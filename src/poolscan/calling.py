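"""Heuristic pool-SNP calling with coverage and pooled-allele-count filters.

A site is considered only if its A/T/C/G coverage summed across pools is at
least ``min_total_cov`` (default 18, i.e. "more than 17") and strictly below
the per-chromosome coverage ceiling (default the 95th percentile of summed
coverage on that chromosome).  An allele is called when its count summed
across pools reaches ``min_allele_count`` (default 17, ">16") and its
pooled frequency exceeds ``min_allele_freq`` (default 0.001).  Sites with
exactly two called alleles become biallelic SNP records; sites with more
are dropped and tallied.  N and deletion counts are carried in the sync
input but never contribute to coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import NUCLEOTIDES, SyncSite, sync_to_arrays


@dataclass
class SiteFilterConfig:
    min_total_cov: int = 18
    max_cov_quantile: float = 0.95
    min_allele_count: int = 17
    min_allele_freq: float = 0.001
    #: apply the coverage rules per pool instead of on the pooled sum
    per_pool_coverage: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.max_cov_quantile <= 1.0:
            raise ValueError("max_cov_quantile must be in (0, 1]")
        if self.min_total_cov < 1:
            raise ValueError("min_total_cov must be >= 1")


@dataclass
class SnpRecord:
    chrom: str
    pos: int
    major_allele: str
    minor_allele: str
    major: np.ndarray  # per-pool major-allele read counts
    minor: np.ndarray

    @property
    def total_cov(self) -> np.ndarray:
        return self.major + self.minor


@dataclass
class CallResult:
    snps: list[SnpRecord]
    n_sites_seen: int
    n_coverage_filtered: int
    n_monomorphic: int
    n_multiallelic: int
    thresholds: dict[str, float]


def max_cov_thresholds(sites: Sequence[SyncSite], q: float) -> dict[str, float]:
    """Per-chromosome coverage ceiling: empirical q-quantile (linear
    interpolation) of the across-pool summed A/T/C/G coverage."""
    totals: dict[str, list[int]] = {}
    for s in sites:
        totals.setdefault(s.chrom, []).append(int(s.counts[:, :4].sum()))
    return {c: float(np.quantile(np.asarray(v), q)) for c, v in totals.items()}


def call_snps(sites: Sequence[SyncSite], cfg: SiteFilterConfig | None = None) -> CallResult:
    """Apply the three filter rules and emit biallelic SNP records.

    The major allele is the one with the higher count summed across pools;
    input order is preserved.
    """
    cfg = cfg or SiteFilterConfig()
    ceilings = max_cov_thresholds(sites, cfg.max_cov_quantile)
    chroms, positions, _refs, counts = sync_to_arrays(sites)
    n = len(sites)
    snps: list[SnpRecord] = []
    n_cov = n_mono = n_multi = 0
    if n == 0:
        return CallResult([], 0, 0, 0, 0, ceilings)

    nuc_counts = counts[:, :, :4]  # (n, pools, 4)
    pooled = nuc_counts.sum(axis=1)  # (n, 4)
    total = pooled.sum(axis=1)

    for i in range(n):
        ceiling = ceilings[str(chroms[i])]
        if cfg.per_pool_coverage:
            per_pool = nuc_counts[i].sum(axis=1)
            cov_ok = bool(np.all(per_pool >= cfg.min_total_cov) and np.all(per_pool < ceiling))
        else:
            cov_ok = cfg.min_total_cov <= total[i] < ceiling
        if not cov_ok:
            n_cov += 1
            continue
        tot = total[i]
        freq = pooled[i] / tot if tot > 0 else np.zeros(4)
        called = (pooled[i] >= cfg.min_allele_count) & (freq > cfg.min_allele_freq)
        k = int(called.sum())
        if k < 2:
            n_mono += 1
            continue
        if k > 2:
            n_multi += 1
            continue
        a, b = np.flatnonzero(called)
        if pooled[i][a] >= pooled[i][b]:
            maj, mnr = a, b
        else:
            maj, mnr = b, a
        snps.append(
            SnpRecord(
                chrom=str(chroms[i]),
                pos=int(positions[i]),
                major_allele=NUCLEOTIDES[maj],
                minor_allele=NUCLEOTIDES[mnr],
                major=nuc_counts[i, :, maj].copy(),
                minor=nuc_counts[i, :, mnr].copy(),
            )
        )
    return CallResult(snps, n, n_cov, n_mono, n_multi, ceilings)


def snps_to_arrays(snps: Sequence[SnpRecord]) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack SNP records into (chroms, positions, major[n, pools], minor)."""
    chroms = np.array([s.chrom for s in snps], dtype=object)
    pos = np.array([s.pos for s in snps], dtype=np.int64)
    if snps:
        major = np.stack([s.major for s in snps]).astype(np.int64)
        minor = np.stack([s.minor for s in snps]).astype(np.int64)
    else:
        major = np.zeros((0, 0), dtype=np.int64)
        minor = np.zeros((0, 0), dtype=np.int64)
    return chroms, pos, major, minor
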