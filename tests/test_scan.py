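import numpy as np
import pytest
from scipy import stats

from poolscan import scan
from poolscan.calling import SnpRecord
from poolscan.io import PoolInfo, SampleSheet, SyncSite
from poolscan.scan import (
    Peak,
    apply_pseudocount,
    chromosome_excess_test,
    cluster_top_snps,
    enumerate_label_permutations,
    estimate_pi0,
    fixed_difference_flags,
    fit_snp_glm,
    glm_scan_arrays,
    major_peaks,
    peak_coverage_check,
    permutation_scan,
    storey_qvalues,
)


def make_snp(major, minor, chrom="2", pos=1):
    return SnpRecord(chrom, pos, "A", "T", np.asarray(major), np.asarray(minor))


class TestGlm:
    def test_exact_balance_gives_null(self, paired_sheet):
        snp = make_snp([50] * 8, [50] * 8)
        r = fit_snp_glm(snp, paired_sheet)
        assert r.beta_treatment == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_pseudocount_applied_to_all_pools(self):
        major = np.array([[30, 30, 30, 30, 0, 0, 0, 0]])
        minor = np.array([[0, 0, 0, 0, 30, 30, 30, 30]])
        maj2, min2 = apply_pseudocount(major, minor, "all-pools")
        assert maj2.tolist() == [[31, 31, 31, 31, 1, 1, 1, 1]]
        assert min2.tolist() == [[1, 1, 1, 1, 31, 31, 31, 31]]

    def test_maximal_consistent_divergence_is_significant(self, paired_sheet):
        snp = make_snp([30, 30, 30, 30, 0, 0, 0, 0], [0, 0, 0, 0, 30, 30, 30, 30])
        r = fit_snp_glm(snp, paired_sheet)
        assert r.p_value < 1e-4

    def test_too_few_pools_rejected(self):
        sheet = SampleSheet([PoolInfo("E1", "E", 1, 40), PoolInfo("M1", "M", 1, 40)])
        with pytest.raises(ValueError):
            glm_scan_arrays(np.array([[5, 5]]), np.array([[5, 5]]), sheet.e_mask)

    @pytest.mark.parametrize("weights", ["none", "counts"])
    def test_matches_reference_glm_fit(self, paired_sheet, rng, weights):
        """200 random SNPs against an independently fitted quasibinomial GLM
        (statsmodels IRLS with Pearson-chi-square scale)."""
        import statsmodels.api as sm

        e = paired_sheet.e_mask
        X = np.column_stack([np.ones(8), e.astype(float)])
        for _ in range(200):
            major = rng.integers(1, 80, size=8)
            minor = rng.integers(1, 80, size=8)
            beta, phi, p = glm_scan_arrays(major[None], minor[None], e, weights=weights)
            y = major / (major + minor)
            kwargs = {"var_weights": (major + minor).astype(float)} if weights == "counts" else {}
            fit = sm.GLM(y, X, family=sm.families.Binomial(), **kwargs).fit(scale="X2")
            assert beta[0] == pytest.approx(fit.params[1], rel=1e-6, abs=1e-10)
            assert phi[0] == pytest.approx(fit.scale, rel=1e-6)
            t_ref = fit.params[1] / fit.bse[1]
            p_ref = 2 * stats.t.sf(abs(t_ref), 6)
            assert p[0] == pytest.approx(p_ref, rel=1e-6, abs=1e-12)


class TestStoreyQ:
    def test_all_ones_stay_one(self):
        p = np.ones(50)
        np.testing.assert_allclose(storey_qvalues(p), 1.0)

    def test_single_p_bounded_by_itself(self):
        assert storey_qvalues(np.array([0.01]))[0] <= 0.01

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues(np.array([0.5, 1.5]))

    def test_matches_step_by_step_reference(self, rng):
        """Frozen 100-element vector vs an explicitly coded, loop-based
        Storey computation (lambda grid, natural-spline-smoothed pi0,
        backward running minimum)."""
        p = np.concatenate([rng.uniform(0, 1, 90), rng.uniform(0, 1e-3, 10)])

        # -- reference, written directly from the procedure's definition --
        m = len(p)
        lambdas = [round(0.05 * i, 2) for i in range(19)]
        pi0_raw = [sum(x > lam for x in p) / (m * (1 - lam)) for lam in lambdas]
        knots = np.quantile(lambdas, [0, 1 / 3, 2 / 3, 1.0])
        K = len(knots)

        def dfun(j, xv):
            t1 = max(xv - knots[j], 0.0) ** 3 - max(xv - knots[K - 1], 0.0) ** 3
            return t1 / (knots[K - 1] - knots[j])

        def basis_row(xv):
            return [1.0, xv] + [dfun(j, xv) - dfun(K - 2, xv) for j in range(K - 2)]

        A = np.array([basis_row(lam) for lam in lambdas])
        coef = np.linalg.solve(A.T @ A, A.T @ np.array(pi0_raw))
        pi0 = float(np.dot(basis_row(lambdas[-1]), coef))
        pi0 = min(max(pi0, 1.0 / m), 1.0)
        order = sorted(range(m), key=lambda i: p[i])
        q_ref = [0.0] * m
        prev = np.inf
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            q = min(pi0 * m * p[i] / rank, prev, 1.0)
            q_ref[i] = q
            prev = q
        # -----------------------------------------------------------------

        np.testing.assert_allclose(storey_qvalues(p), q_ref, atol=1e-8)

    def test_q_order_follows_p_order(self, rng):
        p = rng.uniform(0, 1, 500)
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_equals_bh_when_pi0_is_one(self, rng):
        p = rng.uniform(0, 1, 200)
        q = storey_qvalues(p, pi0=1.0)
        from statsmodels.stats.multitest import multipletests

        bh = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, bh, atol=1e-12)
        # estimated pi0 <= 1 so default q-values can only be smaller
        assert np.all(storey_qvalues(p) <= q + 1e-12)


class TestPermutations:
    def test_study_design_has_68_relabelings(self, paired_sheet):
        assert len(enumerate_label_permutations(paired_sheet)) == 68

    def test_one_vs_one_has_none(self):
        sheet = SampleSheet([PoolInfo("E1", "E", 1, 40), PoolInfo("M1", "M", 1, 40)])
        assert enumerate_label_permutations(sheet) == []

    def test_two_vs_two_matches_enumeration(self):
        pools = [PoolInfo(f"E{r}", "E", r, 40) for r in (1, 2)]
        pools += [PoolInfo(f"M{r}", "M", r, 40) for r in (1, 2)]
        sheet = SampleSheet(pools)
        perms = enumerate_label_permutations(sheet)
        assert len(perms) == 4  # C(4,2) - observed - complement
        observed = frozenset(np.flatnonzero(sheet.e_mask))
        for mask in perms:
            s = frozenset(np.flatnonzero(mask))
            assert s != observed and s != frozenset(range(4)) - observed

    def test_unbalanced_design_rejected(self):
        pools = [PoolInfo("E1", "E", 1, 40), PoolInfo("E2", "E", 2, 40), PoolInfo("M1", "M", 1, 40)]
        with pytest.raises(ValueError):
            enumerate_label_permutations(SampleSheet(pools))

    def test_complement_relabeling_reproduces_p_values(self, paired_sheet, rng):
        # swapping all labels flips the sign of beta but not the p-value
        major = rng.integers(1, 60, size=(50, 8))
        minor = rng.integers(1, 60, size=(50, 8))
        _, _, p_obs = glm_scan_arrays(major, minor, paired_sheet.e_mask)
        _, _, p_swap = glm_scan_arrays(major, minor, ~paired_sheet.e_mask)
        np.testing.assert_allclose(p_obs, p_swap, rtol=1e-12)

    def test_zero_permutations_gives_empty_result(self, paired_sheet, rng):
        major = rng.integers(1, 60, size=(10, 8))
        minor = rng.integers(1, 60, size=(10, 8))
        out = permutation_scan((major, minor), paired_sheet, n_perm=0)
        assert len(out) == 0

    def test_strong_consistent_signal_beats_every_permutation(self, paired_sheet, rng):
        # 50 SNPs fixed-different between treatments + 500 noise SNPs
        major = rng.integers(20, 40, size=(550, 8))
        minor = rng.integers(20, 40, size=(550, 8))
        major[:50, 4:] = 0
        minor[:50, :4] = 0
        _, _, p_obs = glm_scan_arrays(major, minor, paired_sheet.e_mask)
        observed = int((p_obs < 0.05).sum())
        perm = permutation_scan((major, minor), paired_sheet, mode="whole-genome")
        assert len(perm) == 68
        assert (perm["n_p_below"] < observed).all()

    def test_per_snp_mode_requires_seed(self, paired_sheet, rng):
        major = rng.integers(1, 60, size=(10, 8))
        minor = rng.integers(1, 60, size=(10, 8))
        with pytest.raises(ValueError, match="seed"):
            permutation_scan((major, minor), paired_sheet, mode="per-snp", n_perm=3)
        out = permutation_scan((major, minor), paired_sheet, mode="per-snp", n_perm=3, seed=1)
        assert len(out) == 3


def brute_force_clusters(positions, link_bp):
    """Transitive closure over the 'within link_bp' relation."""
    pos = sorted(positions)
    clusters = []
    for p in pos:
        placed = False
        for cl in clusters:
            if any(abs(p - q) <= link_bp for q in cl):
                cl.append(p)
                placed = True
        if not placed:
            clusters.append([p])
        # merge clusters connected through p
        merged = []
        for cl in clusters:
            if p in cl and merged and p in merged[-1]:
                merged[-1] = sorted(set(merged[-1]) | set(cl))
            else:
                merged.append(cl)
        clusters = merged
    return [(min(c), max(c), len(set(c))) for c in clusters]


class TestClustering:
    def test_gap_at_boundary_joins(self):
        peaks = cluster_top_snps(np.array(["2", "2"]), np.array([100, 50_100]))
        assert len(peaks) == 1 and peaks[0].n_snps == 2

    def test_gap_beyond_boundary_splits(self):
        peaks = cluster_top_snps(np.array(["2", "2"]), np.array([100, 50_101]))
        assert len(peaks) == 2

    def test_chromosomes_never_merge(self):
        peaks = cluster_top_snps(np.array(["2", "3"]), np.array([100, 200]))
        assert len(peaks) == 2

    def test_matches_transitive_closure_oracle(self, rng):
        positions = np.unique(rng.integers(1, 2_000_000, size=500))
        peaks = cluster_top_snps(np.array(["2"] * len(positions)), positions, 50_000)
        got = [(p.start, p.end, p.n_snps) for p in peaks]
        assert got == brute_force_clusters(positions.tolist(), 50_000)

    def test_major_peaks_filters_on_size(self):
        peaks = [Peak("2", 1, 10, n, np.arange(n)) for n in (1, 10, 11, 50)]
        assert [p.n_snps for p in major_peaks(peaks, 10)] == [11, 50]


class TestChromosomeExcess:
    def test_proportional_distribution_is_null(self):
        bg = {"2": 1000, "3": 1000, "XL": 500}
        top = {"2": 40, "3": 40, "XL": 20}
        out = chromosome_excess_test(top, bg)
        assert (out["p"] > 0.9).all()

    def test_extreme_concentration_detected(self):
        bg = {c: 1000 for c in "abcde"}
        top = {"a": 100}
        out = chromosome_excess_test(top, bg)
        assert out.loc[out["chrom"] == "a", "p"].iloc[0] < 1e-10

    def test_matches_direct_binomial_computation(self, rng):
        bg = {c: int(n) for c, n in zip("abcd", rng.integers(100, 1000, 4))}
        top = {c: int(n) for c, n in zip("abcd", rng.integers(0, 40, 4))}
        out = chromosome_excess_test(top, bg)
        n_top = sum(top.values())
        n_bg = sum(bg.values())
        for _, row in out.iterrows():
            expect = bg[row["chrom"]] / n_bg
            ref = stats.binomtest(top[row["chrom"]], n_top, expect).pvalue
            assert row["p"] == pytest.approx(ref)


class TestPeakCoverage:
    def _sites(self, rng, n=2000, boost=None):
        sites = []
        for pos in range(1, n + 1):
            cov = rng.poisson(50, size=2)
            if boost and boost[0] <= pos * 1000 <= boost[1]:
                cov = cov * 2
            counts = np.zeros((2, 6), dtype=np.int64)
            counts[:, 0] = cov
            sites.append(SyncSite("2", pos * 1000, "A", counts))
        return sites

    def test_uniform_coverage_shows_no_difference(self, rng):
        sites = self._sites(rng)
        peaks = [Peak("2", 100_000, 200_000, 5, np.array([100_000, 200_000]))]
        out = peak_coverage_check(peaks, sites, n_random=100, seed=0)
        assert out["p_value"] > 0.05

    def test_planted_coverage_excess_detected(self, rng):
        spans = [(100_000, 150_000), (400_000, 450_000), (700_000, 750_000),
                 (1_000_000, 1_050_000), (1_300_000, 1_350_000)]
        sites = []
        for pos in range(1, 2001):
            cov = rng.poisson(50, size=2)
            if any(a <= pos * 1000 <= b for a, b in spans):
                cov = cov * 2
            counts = np.zeros((2, 6), dtype=np.int64)
            counts[:, 0] = cov
            sites.append(SyncSite("2", pos * 1000, "A", counts))
        peaks = [Peak("2", a, b, 5, np.array([a, b])) for a, b in spans]
        out = peak_coverage_check(peaks, sites, n_random=100, seed=0)
        assert out["p_value"] < 0.05
        assert out["peak_mean_coverage"] > out["random_mean_coverage"]

    def test_zero_random_regions_rejected(self, rng):
        sites = self._sites(rng, n=100)
        peaks = [Peak("2", 1000, 2000, 1, np.array([1000]))]
        with pytest.raises(ValueError):
            peak_coverage_check(peaks, sites, n_random=0)


class TestFixedDifferences:
    def test_fully_fixed_snp_flagged(self, paired_sheet):
        snp = make_snp([30, 30, 30, 30, 0, 0, 0, 0], [0, 0, 0, 0, 30, 30, 30, 30])
        assert fixed_difference_flags([snp], paired_sheet).tolist() == [True]

    def test_single_discordant_pool_unflags(self, paired_sheet):
        snp = make_snp([30, 30, 30, 30, 1, 0, 0, 0], [0, 0, 0, 0, 29, 30, 30, 30])
        assert fixed_difference_flags([snp], paired_sheet).tolist() == [False]

    def test_direction_may_differ_between_replicates(self, paired_sheet):
        # replicate 1 fixed E-major, replicate 2 fixed M-major, others fixed
        snp = make_snp([30, 0, 30, 30, 0, 30, 0, 0], [0, 30, 0, 0, 30, 0, 30, 30])
        assert fixed_difference_flags([snp], paired_sheet).tolist() == [True]

    def test_matches_brute_force_definition(self, paired_sheet, rng):
        snps = []
        for i in range(300):
            if rng.random() < 0.3:
                major = np.where(rng.random(8) < 0.5, 30, 0)
                major[4:] = 30 - major[4:]
            else:
                major = rng.integers(0, 31, size=8)
            snps.append(make_snp(major, 30 - major, pos=i + 1))
        got = fixed_difference_flags(snps, paired_sheet)
        for snp, flag in zip(snps, got):
            f = snp.major / (snp.major + snp.minor)
            expected = all(
                (f[e] == 1 and f[m] == 0) or (f[e] == 0 and f[m] == 1)
                for e, m in paired_sheet.replicate_pairs()
            )
            assert flag == expected
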