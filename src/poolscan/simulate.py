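"""Forward simulator for a replicated monogamy/polyandry pool-seq experiment.

The generator emulates the study design end to end: ``n_replicates``
independent pairs of lines (one elevated-polyandry ``E`` and one enforced
monogamy ``M`` line per replicate) evolve from a shared ancestral
population for ``generations`` generations of Wright–Fisher drift at
effective size ``n_e`` per line.  A configurable subset of loci is under
divergent viability selection (coefficient ``sel_coeff_e`` in E lines,
``sel_coeff_m`` in M lines, dominance ``h``).  X-linked loci drift with
``round(1.5 * n_e)`` gene copies (``N_eX = 3/4 N_eA``); autosomal loci with
``2 * n_e``.  Sequencing is emulated by two-stage sampling: a pool of
``pool_size`` diploid females is drawn from each line, then reads are drawn
binomially at Poisson-distributed depth.

Most loci are simulated as freely recombining (independent) sites, which is
sufficient for the allele-frequency statistics.  Linkage — needed for LD
decay and for hitchhiking/sweep signatures in diversity statistics — is
simulated explicitly, but only inside declared *haplotype regions*, where a
full haplotype population is tracked with recombination and (optionally)
selection at the central locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GeneInterval, PoolInfo, SampleSheet, SyncSite

DEFAULT_X_CHROMS = frozenset({"XL", "XR"})


@dataclass(frozen=True)
class ChromPlan:
    name: str
    length: int
    n_loci: int
    x_linked: bool = False


@dataclass(frozen=True)
class HapRegionPlan:
    """A genomic interval simulated with explicit linked haplotypes.

    ``selected`` puts the region's central locus under the configured
    treatment-specific selection, so that linked neutral diversity is
    dragged along (hitchhiking) — the mechanism behind sweep signatures.
    """

    region_id: str
    chrom: str
    start: int
    end: int
    n_loci: int
    recomb_rate: float = 2e-8  # per bp per generation
    selected: bool = False
    #: starting frequency of the selected central locus (None = drawn like
    #: any other locus); a hard sweep starts from a rare variant
    sel_p0: float | None = None
    #: per-locus, per-copy, per-generation mutation (allele flip) rate;
    #: supplies the young low-frequency variants that post-sweep diversity
    #: statistics depend on
    mut_rate: float = 0.0
    #: number of distinct founder haplotypes in the shared ancestral pool;
    #: None starts at linkage equilibrium.  A finite founder count creates
    #: the ancestral LD that lets a sweep drag linked variants to high
    #: frequency consistently across replicate lines
    n_founders: int | None = None


def divergent_scenario(
    seed: int = 0, mean_coverage: float = 50.0, sel_coeff: float = 0.1
) -> SimulationConfig:
    """The canonical divergent-selection scenario used end to end.

    Mirrors the study's qualitative structure at desk scale: divergently
    selected loci scattered over five chromosome arms (three autosomal, two
    X-linked), plus three large linked sweep regions — one on chromosome 3
    (the study's dominant cluster) and one on each X arm — where a rare
    favoured variant (starting frequency 0.1) sweeps in E lines and is
    purged in M lines, with recombination and mutation supplying the
    post-sweep rare variants that diversity statistics respond to.  Sweep
    regions start from a small shared founder-haplotype pool: the
    resulting ancestral LD is what turns a sweep into a cluster of many
    consistently diverged SNPs, the architecture the genome scan reports
    (most top SNPs concentrated in a few large peaks).
    """
    plan = default_chrom_plan()
    regions = [
        HapRegionPlan("sweep-3", "3", 200_001, 350_000, 300, 5e-8, True, 0.1, 2e-4, 6),
        HapRegionPlan("sweep-XL", "XL", 150_001, 300_000, 300, 5e-8, True, 0.1, 2e-4, 6),
        HapRegionPlan("sweep-XR", "XR", 150_001, 300_000, 300, 5e-8, True, 0.1, 2e-4, 6),
        # small neutral regions at realistic SNP spacing (~100 bp) so that
        # read pairs co-observe enough SNP pairs for the LD-decay fit
        HapRegionPlan("ld-2", "2", 400_001, 420_000, 200, 5e-8, False, None, 2e-4, 6),
        HapRegionPlan("ld-XL", "XL", 350_001, 370_000, 200, 5e-8, False, None, 2e-4, 6),
    ]
    return SimulationConfig(
        chrom_plan=plan,
        hap_regions=regions,
        selected_fraction=0.01,
        sel_coeff_e=sel_coeff,
        sel_coeff_m=-sel_coeff,
        mean_coverage=mean_coverage,
        seed=seed,
    )


def default_chrom_plan() -> list[ChromPlan]:
    return [
        ChromPlan("2", 600_000, 1200, False),
        ChromPlan("3", 600_000, 1200, False),
        ChromPlan("4", 600_000, 1200, False),
        ChromPlan("XL", 450_000, 900, True),
        ChromPlan("XR", 450_000, 900, True),
    ]


@dataclass
class SimulationConfig:
    n_replicates: int = 4
    n_e: int = 120
    generations: int = 160
    chrom_plan: list[ChromPlan] = field(default_factory=default_chrom_plan)
    hap_regions: list[HapRegionPlan] = field(default_factory=list)
    selected_fraction: float = 0.01
    sel_coeff_e: float = 0.05
    sel_coeff_m: float = -0.05
    dominance: float = 0.5
    pool_size: int = 40
    mean_coverage: float = 50.0
    overdispersion: float | None = None  # gamma shape for NB depth; None = Poisson
    p0_low: float = 0.05
    p0_high: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_e < 2:
            raise ValueError("n_e must be >= 2")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if not 0.0 <= self.selected_fraction <= 1.0:
            raise ValueError("selected_fraction must be in [0, 1]")
        if self.mean_coverage < 0:
            raise ValueError("mean_coverage must be >= 0")
        if not 0.0 <= self.dominance <= 1.0:
            raise ValueError("dominance must be in [0, 1]")

    def line_ids(self) -> list[str]:
        reps = range(1, self.n_replicates + 1)
        return [f"E{r}" for r in reps] + [f"M{r}" for r in reps]

    def sample_sheet(self) -> SampleSheet:
        pools = []
        for lid in self.line_ids():
            pools.append(PoolInfo(lid, lid[0], int(lid[1:]), self.pool_size))
        return SampleSheet(pools)


@dataclass
class TruthSet:
    """Ground truth of a simulation run.

    ``loci`` has one row per simulated locus (chrom, pos, x_linked,
    selected, s_e, s_m, p0, region); ``freqs[i, j]`` is the final true
    frequency of the tracked (derived) allele at locus ``i`` in line ``j``,
    with line order ``line_ids``.
    """

    loci: pd.DataFrame
    freqs: np.ndarray
    line_ids: list[str]
    config: SimulationConfig
    haplotypes: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    region_loci: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def line_index(self, line_id: str) -> int:
        return self.line_ids.index(line_id)


@dataclass
class ReadPairObs:
    """Alleles observed by one read pair at the region loci it covers."""

    pair_id: int
    chrom: str
    sites: list[tuple[int, str, int]]  # (pos, allele nucleotide, phred quality)


# ---------------------------------------------------------------------------
# core Wright–Fisher machinery


def _selection_update(p: np.ndarray, s: np.ndarray, h: float) -> np.ndarray:
    """Expected next-generation frequency under viability selection.

    Genotype fitnesses 1, 1-h*s, 1-s for AA, Aa, aa where A is the tracked
    (favoured when s > 0) allele at frequency ``p``.
    """
    q = 1.0 - p
    w_aa = 1.0 - s
    w_het = 1.0 - h * s
    w_bar = p * p + 2.0 * p * q * w_het + q * q * w_aa
    with np.errstate(invalid="ignore", divide="ignore"):
        p_new = (p * p + p * q * w_het) / w_bar
    return np.where(w_bar > 0, p_new, p)


def _copies_per_locus(x_linked: np.ndarray, n_e: int) -> np.ndarray:
    n_auto = 2 * n_e
    n_x = int(round(1.5 * n_e))
    return np.where(x_linked, n_x, n_auto)


def _evolve_independent(
    p0: np.ndarray,
    s: np.ndarray,
    x_linked: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One line: evolve all freely recombining loci for cfg.generations."""
    n_copies = _copies_per_locus(x_linked, cfg.n_e)
    p = p0.copy()
    h = cfg.dominance
    any_sel = np.any(s != 0.0)
    for _ in range(cfg.generations):
        if any_sel:
            p = _selection_update(p, s, h)
        p = rng.binomial(n_copies, p) / n_copies
    return p


def _recombine(
    parents_a: np.ndarray, parents_b: np.ndarray, r_adj: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised gamete formation for a batch of offspring.

    ``parents_a/b`` are (n, L) haplotypes; crossover occurs between adjacent
    loci with per-interval probability ``r_adj`` (length L-1).
    """
    n, L = parents_a.shape
    start = rng.integers(0, 2, size=(n, 1))
    if L > 1:
        flips = rng.random((n, L - 1)) < r_adj[None, :]
        track = np.concatenate([start, flips], axis=1)
        which = np.cumsum(track, axis=1) % 2
    else:
        which = start
    return np.where(which == 0, parents_a, parents_b)


def _evolve_haplotype_region(
    h0: np.ndarray,
    positions: np.ndarray,
    sel_idx: int | None,
    s_line: float,
    cfg: SimulationConfig,
    recomb_rate: float,
    n_copies: int,
    rng: np.random.Generator,
    mut_rate: float = 0.0,
) -> np.ndarray:
    """One line, one linked region: WF with recombination and hitchhiking.

    Selection inside linked regions acts genically on gene copies with
    coefficient ``h * s`` per copy (the additive approximation of the
    diploid viability scheme used for independent loci).
    """
    H = h0.copy()
    r_adj = np.clip(recomb_rate * np.diff(positions), 0.0, 0.5)
    s_copy = cfg.dominance * s_line
    for _ in range(cfg.generations):
        probs = None
        if sel_idx is not None and s_copy != 0.0:
            col = H[:, sel_idx]
            if 0 < col.sum() < len(col):  # uniform weights once (un)fixed
                w = 1.0 + s_copy * col
                probs = w / w.sum()
        if probs is None:
            pa = rng.integers(0, H.shape[0], size=n_copies)
            pb = rng.integers(0, H.shape[0], size=n_copies)
        else:
            pa = rng.choice(H.shape[0], size=n_copies, p=probs)
            pb = rng.choice(H.shape[0], size=n_copies, p=probs)
        H = _recombine(H[pa], H[pb], r_adj, rng)
        if mut_rate > 0.0:
            flips = rng.random(H.shape) < mut_rate
            H = np.where(flips, 1 - H, H)
    return H


def simulate_wright_fisher(cfg: SimulationConfig, seed: int | None = None) -> TruthSet:
    """Run the full replicated experiment; return the ground-truth record."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    chrom_order = {c.name: i for i, c in enumerate(cfg.chrom_plan)}
    x_by_chrom = {c.name: c.x_linked for c in cfg.chrom_plan}

    rows = []
    for c in cfg.chrom_plan:
        if c.n_loci > c.length:
            raise ValueError(f"chromosome {c.name}: more loci than positions")
        pos = np.sort(rng.choice(c.length, size=c.n_loci, replace=False)) + 1
        # positions inside a declared haplotype region belong to that
        # region's linked simulation, never to the independent-locus set
        for reg in cfg.hap_regions:
            if reg.chrom == c.name:
                pos = pos[(pos < reg.start) | (pos > reg.end)]
        for p in pos:
            rows.append((c.name, int(p), c.x_linked, None))
    for reg in cfg.hap_regions:
        if reg.chrom not in chrom_order:
            raise ValueError(f"haplotype region on unknown chromosome {reg.chrom}")
        span = reg.end - reg.start + 1
        if reg.n_loci < 2 or span < reg.n_loci:
            raise ValueError(f"region {reg.region_id}: need >= 2 loci within the span")
        pos = np.sort(rng.choice(span, size=reg.n_loci, replace=False)) + reg.start
        for p in pos:
            rows.append((reg.chrom, int(p), x_by_chrom[reg.chrom], reg.region_id))

    loci = pd.DataFrame(rows, columns=["chrom", "pos", "x_linked", "region"])
    loci = loci.sort_values(
        by=["chrom", "pos"], key=lambda s: s.map(chrom_order) if s.name == "chrom" else s
    ).reset_index(drop=True)

    n = len(loci)
    loci["p0"] = rng.uniform(cfg.p0_low, cfg.p0_high, size=n)
    selected = np.zeros(n, dtype=bool)
    indep_mask = loci["region"].isna().to_numpy()
    n_sel = int(round(cfg.selected_fraction * indep_mask.sum()))
    if n_sel > 0:
        sel_idx = rng.choice(np.flatnonzero(indep_mask), size=n_sel, replace=False)
        selected[sel_idx] = True
    for reg in cfg.hap_regions:
        if reg.selected:
            ridx = np.flatnonzero((loci["region"] == reg.region_id).to_numpy())
            mid = ridx[len(ridx) // 2]
            selected[mid] = True
            if reg.sel_p0 is not None:
                loci.loc[mid, "p0"] = reg.sel_p0
    loci["selected"] = selected
    loci["s_e"] = np.where(selected, cfg.sel_coeff_e, 0.0)
    loci["s_m"] = np.where(selected, cfg.sel_coeff_m, 0.0)

    line_ids = cfg.line_ids()
    freqs = np.empty((n, len(line_ids)))
    x_linked = loci["x_linked"].to_numpy()
    p0 = loci["p0"].to_numpy()
    s_e = loci["s_e"].to_numpy()
    s_m = loci["s_m"].to_numpy()

    indep = np.flatnonzero(indep_mask)
    for j, lid in enumerate(line_ids):
        s = s_e if lid.startswith("E") else s_m
        freqs[indep, j] = _evolve_independent(
            p0[indep], s[indep], x_linked[indep], cfg, rng
        )

    haplotypes: dict[str, dict[str, np.ndarray]] = {}
    region_loci: dict[str, np.ndarray] = {}
    for reg in cfg.hap_regions:
        ridx = np.flatnonzero((loci["region"] == reg.region_id).to_numpy())
        region_loci[reg.region_id] = ridx
        positions = loci["pos"].to_numpy()[ridx]
        n_copies = int(_copies_per_locus(np.array([x_by_chrom[reg.chrom]]), cfg.n_e)[0])
        sel_local = None
        if reg.selected:
            sel_pos = np.flatnonzero(selected[ridx])
            sel_local = int(sel_pos[0]) if len(sel_pos) else None
        # shared ancestral haplotype pool: either linkage equilibrium at the
        # nominal p0, or copies of a finite set of founder haplotypes
        if reg.n_founders is None:
            h0 = (rng.random((n_copies, len(ridx))) < p0[ridx][None, :]).astype(np.uint8)
        else:
            founders = (rng.random((reg.n_founders, len(ridx))) < p0[ridx][None, :]).astype(np.uint8)
            if sel_local is not None and reg.sel_p0 is not None:
                k = max(1, int(round(reg.sel_p0 * reg.n_founders)))
                col = np.zeros(reg.n_founders, dtype=np.uint8)
                col[rng.choice(reg.n_founders, size=k, replace=False)] = 1
                founders[:, sel_local] = col
            h0 = founders[rng.integers(0, reg.n_founders, size=n_copies)]
        haplotypes[reg.region_id] = {}
        for j, lid in enumerate(line_ids):
            s_line = cfg.sel_coeff_e if lid.startswith("E") else cfg.sel_coeff_m
            H = _evolve_haplotype_region(
                h0, positions, sel_local, s_line, cfg, reg.recomb_rate, n_copies, rng,
                reg.mut_rate,
            )
            haplotypes[reg.region_id][lid] = H
            freqs[ridx, j] = H.mean(axis=0)

    return TruthSet(
        loci=loci,
        freqs=freqs,
        line_ids=line_ids,
        config=cfg,
        haplotypes=haplotypes,
        region_loci=region_loci,
    )


# ---------------------------------------------------------------------------
# pool-seq sampling


def _draw_depths(n: int, cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.mean_coverage == 0:
        return np.zeros(n, dtype=np.int64)
    if cfg.overdispersion is None:
        return rng.poisson(cfg.mean_coverage, size=n)
    shape = cfg.overdispersion
    lam = rng.gamma(shape, cfg.mean_coverage / shape, size=n)
    return rng.poisson(lam)


def sample_pool_counts(
    truth: TruthSet, cfg: SimulationConfig | None = None, seed: int | None = None
) -> list[SyncSite]:
    """Two-stage pool-seq sampling: individuals into the pool, reads from it.

    Stage 1 draws ``2 * pool_size`` allele copies per pool (all pools are
    females, so X-linked loci also contribute two copies per individual);
    inside haplotype regions whole haplotypes are drawn without replacement
    so that linkage survives into the pool.  Stage 2 draws read depth from
    Poisson(``mean_coverage``) (optionally overdispersed) and allele reads
    binomially from the pool allele fraction.
    """
    cfg = cfg or truth.config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    n, n_lines = truth.freqs.shape
    n_hap = 2 * cfg.pool_size

    pool_freq = np.empty_like(truth.freqs)
    in_region = np.zeros(n, dtype=bool)
    for reg_id, ridx in truth.region_loci.items():
        in_region[ridx] = True
        for j, lid in enumerate(truth.line_ids):
            H = truth.haplotypes[reg_id][lid]
            take = rng.choice(H.shape[0], size=min(n_hap, H.shape[0]), replace=False)
            pool_freq[ridx, j] = H[take].mean(axis=0)
    indep = ~in_region
    pool_freq[indep] = rng.binomial(n_hap, truth.freqs[indep]) / n_hap

    # derived/ancestral nucleotides per site
    nuc = np.array(list("ATCG"))
    ref_idx = rng.integers(0, 4, size=n)
    alt_off = rng.integers(1, 4, size=n)
    alt_idx = (ref_idx + alt_off) % 4

    sites: list[SyncSite] = []
    chroms = truth.loci["chrom"].to_numpy()
    positions = truth.loci["pos"].to_numpy()
    depth = np.empty((n, n_lines), dtype=np.int64)
    alt_reads = np.empty((n, n_lines), dtype=np.int64)
    for j in range(n_lines):
        depth[:, j] = _draw_depths(n, cfg, rng)
        alt_reads[:, j] = rng.binomial(depth[:, j], pool_freq[:, j])

    for i in range(n):
        counts = np.zeros((n_lines, 6), dtype=np.int64)
        counts[:, ref_idx[i]] = depth[i] - alt_reads[i]
        counts[:, alt_idx[i]] = alt_reads[i]
        sites.append(SyncSite(str(chroms[i]), int(positions[i]), str(nuc[ref_idx[i]]), counts))
    return sites


# ---------------------------------------------------------------------------
# read pairs for LD


def generate_read_pairs(
    truth: TruthSet,
    region_id: str,
    line_id: str,
    n_pairs: int,
    read_len: int = 100,
    insert_mean: int = 340,
    insert_sd: float = 30.0,
    seed: int = 0,
) -> list[ReadPairObs]:
    """Sample paired-end fragments from a line's haplotype region.

    Each fragment comes from one haplotype copy; the pair reports the
    alleles at every region locus its two reads cover, with Phred-like
    per-base quality labels.  ``insert_mean``/``insert_sd`` describe the
    full fragment length.
    """
    if region_id not in truth.haplotypes:
        return []
    H = truth.haplotypes[region_id][line_id]
    ridx = truth.region_loci[region_id]
    positions = truth.loci["pos"].to_numpy()[ridx]
    chrom = str(truth.loci["chrom"].to_numpy()[ridx][0])
    # per-site nucleotide labels consistent with sample_pool_counts' scheme
    rng = np.random.default_rng(seed)
    nuc = np.array(list("ATCG"))
    anc_idx = rng.integers(0, 4, size=len(ridx))
    der_idx = (anc_idx + rng.integers(1, 4, size=len(ridx))) % 4

    lo, hi = int(positions.min()), int(positions.max())
    frag = np.maximum(
        2 * read_len, np.round(rng.normal(insert_mean, insert_sd, size=n_pairs)).astype(int)
    )
    start = rng.integers(lo, np.maximum(lo + 1, hi - frag + 2))
    hap_idx = rng.integers(0, H.shape[0], size=n_pairs)

    pair_obs: list[list[tuple[int, str, int]]] = [[] for _ in range(n_pairs)]
    r2_start = start + frag - read_len
    for k, pos in enumerate(positions):
        covered = ((start <= pos) & (pos <= start + read_len - 1)) | (
            (r2_start <= pos) & (pos <= start + frag - 1)
        )
        hit = np.flatnonzero(covered)
        if len(hit) == 0:
            continue
        alleles = np.where(H[hap_idx[hit], k] == 1, nuc[der_idx[k]], nuc[anc_idx[k]])
        quals = np.clip(np.round(rng.normal(35, 6, size=len(hit))), 2, 41).astype(int)
        for pid, al, q in zip(hit, alleles, quals):
            pair_obs[pid].append((int(pos), str(al), int(q)))
    return [ReadPairObs(pid, chrom, obs) for pid, obs in enumerate(pair_obs)]


def write_read_pairs(pairs: Sequence[ReadPairObs], path: str | Path) -> None:
    """Two-site rows: chrom pos1 allele1 qual1 pos2 allele2 qual2 pair_id."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos1\tallele1\tqual1\tpos2\tallele2\tqual2\tpair_id\n")
        for rp in pairs:
            for a in range(len(rp.sites)):
                for b in range(a + 1, len(rp.sites)):
                    p1, al1, q1 = rp.sites[a]
                    p2, al2, q2 = rp.sites[b]
                    fh.write(
                        f"{rp.chrom}\t{p1}\t{al1}\t{q1}\t{p2}\t{al2}\t{q2}\t{rp.pair_id}\n"
                    )


# ---------------------------------------------------------------------------
# gene annotation and synthetic DE sets


def generate_gene_annotation_and_de(
    truth: TruthSet,
    n_genes: int,
    de_enrichment_near_selected: float = 1.0,
    base_de_rate: float = 0.15,
    proximity_bp: int = 10_000,
    gene_length: int = 2_000,
    fc_sd: float = 1.0,
    fc_corr: float = 0.7,
    seed: int = 0,
) -> list[GeneInterval]:
    """Tile non-overlapping genes and draw synthetic DE labels.

    A gene's DE probability starts at ``base_de_rate``; when a selected
    locus lies within ``proximity_bp`` of the gene span the odds are
    multiplied by ``de_enrichment_near_selected``.  Sex-bias fold changes
    (log2 male/female, per treatment) are drawn from a bivariate normal
    with standard deviation ``fc_sd`` and correlation ``fc_corr``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    plan = truth.config.chrom_plan
    total_len = sum(c.length for c in plan)
    counts = np.maximum(1, np.round([n_genes * c.length / total_len for c in plan])).astype(int)
    # adjust rounding drift
    while counts.sum() > n_genes:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < n_genes:
        counts[np.argmin(counts)] += 1

    sel = truth.loci[truth.loci["selected"]]
    sel_by_chrom = {c: g["pos"].to_numpy() for c, g in sel.groupby("chrom")}

    genes: list[GeneInterval] = []
    gi = 0
    cov = np.array([[fc_sd**2, fc_corr * fc_sd**2], [fc_corr * fc_sd**2, fc_sd**2]])
    for c, k in zip(plan, counts):
        if k == 0:
            continue
        stride = c.length // k
        glen = min(gene_length, max(1, stride - 1))
        for m in range(k):
            start = m * stride + 1
            end = start + glen - 1
            near = False
            pos = sel_by_chrom.get(c.name)
            if pos is not None and len(pos):
                near = bool(
                    np.any((pos >= start - proximity_bp) & (pos <= end + proximity_bp))
                )
            p = base_de_rate
            if near and de_enrichment_near_selected != 1.0:
                odds = p / (1.0 - p) * de_enrichment_near_selected
                p = odds / (1.0 + odds)
            is_de = bool(rng.random() < p)
            fc = rng.multivariate_normal([0.0, 0.0], cov)
            genes.append(
                GeneInterval(
                    gene_id=f"g{gi:05d}",
                    chrom=c.name,
                    start=start,
                    end=end,
                    is_de=is_de,
                    log2fc_e=float(fc[0]),
                    log2fc_m=float(fc[1]),
                )
            )
            gi += 1
    return genes
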