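import numpy as np
import pandas as pd
import pytest

from poolscan.expression import (
    ancova_delta_sb,
    de_contrast,
    genes_near_snps,
    overlap_resampling_test,
)
from poolscan.io import GeneInterval


def gene(gid, start, end, chrom="2"):
    return GeneInterval(gid, chrom, start, end)


class TestGenesNearSnps:
    def test_flank_boundary_inclusive(self):
        g = [gene("g", 20_000, 21_000)]
        hit = genes_near_snps(np.array(["2"]), np.array([10_000]), g, 10_000)
        assert hit == {"g"}

    def test_one_bp_beyond_flank_excluded(self):
        g = [gene("g", 20_001, 21_000)]
        hit = genes_near_snps(np.array(["2"]), np.array([10_000]), g, 10_000)
        assert hit == set()

    def test_zero_flank_requires_containment(self):
        g = [gene("a", 100, 200), gene("b", 300, 400)]
        hit = genes_near_snps(np.array(["2", "2"]), np.array([150, 250]), g, 0)
        assert hit == {"a"}

    def test_monotone_in_flank(self, rng):
        genes = [gene(f"g{i}", int(s), int(s) + 500) for i, s in
                 enumerate(rng.integers(1, 500_000, 100))]
        snps = rng.integers(1, 500_000, 40)
        prev: set = set()
        for flank in (0, 1000, 10_000, 100_000):
            hit = genes_near_snps(np.array(["2"] * 40), snps, genes, flank)
            assert prev <= hit
            prev = hit

    def test_matches_brute_force_interval_check(self, rng):
        genes = [gene(f"g{i}", int(s), int(s) + int(rng.integers(100, 5000)))
                 for i, s in enumerate(rng.integers(1, 300_000, 80))]
        snps = rng.integers(1, 300_000, 30)
        flank = 10_000
        hit = genes_near_snps(np.array(["2"] * 30), snps, genes, flank)
        ref = {
            g.gene_id
            for g in genes
            if any(g.start - flank <= p <= g.end + flank for p in snps)
        }
        assert hit == ref

    def test_ties_keep_all_genes(self):
        g = [gene("a", 100, 200), gene("b", 150, 250)]
        hit = genes_near_snps(np.array(["2"]), np.array([160]), g, 0)
        assert hit == {"a", "b"}


class TestOverlapResampling:
    def test_query_equal_to_de_set_is_maximal(self):
        universe = [f"g{i}" for i in range(200)]
        de = set(universe[:20])
        out = overlap_resampling_test(de, de, universe, n_resample=1000, seed=0)
        assert out.observed_overlap_prop == 1.0
        assert out.significant
        assert out.empirical_p == pytest.approx(1 / 1001)

    def test_resample_mean_matches_hypergeometric(self):
        universe = [f"g{i}" for i in range(500)]
        de = set(universe[:100])  # 20% DE
        query = set(universe[400:440])
        out = overlap_resampling_test(query, de, universe, n_resample=2000, seed=1)
        se = np.sqrt(0.2 * 0.8 / 40) / np.sqrt(2000)
        assert abs(out.resample_mean - 0.2) < 3 * se * 10  # generous band

    def test_null_queries_significant_at_nominal_rate(self):
        rng = np.random.default_rng(3)
        universe = [f"g{i}" for i in range(400)]
        de = set(universe[:60])
        hits = 0
        n_iter = 200
        for i in range(n_iter):
            query = set(rng.choice(universe, 30, replace=False))
            out = overlap_resampling_test(query, de, universe, n_resample=200, seed=i)
            hits += out.significant
        assert hits / n_iter < 0.12

    def test_empirical_p_invariant_to_relabeling(self):
        universe = [f"g{i}" for i in range(100)]
        de = set(universe[:30])
        query = set(universe[20:40])
        out1 = overlap_resampling_test(query, de, universe, 500, seed=5)
        relabel = {g: f"x{g}" for g in universe}
        out2 = overlap_resampling_test(
            {relabel[g] for g in query},
            {relabel[g] for g in de},
            [relabel[g] for g in universe],
            500,
            seed=5,
        )
        assert out1.empirical_p == out2.empirical_p

    def test_oversized_query_rejected(self):
        with pytest.raises(ValueError):
            overlap_resampling_test({"a", "b"}, {"a"}, ["a"], 10, 0)


class TestDeContrast:
    def _stats(self, de_vals, non_vals, chrom_type="auto"):
        n1, n2 = len(de_vals), len(non_vals)
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n1 + n2)],
                "is_de": [True] * n1 + [False] * n2,
                "value": list(de_vals) + list(non_vals),
                "chrom_type": chrom_type,
            }
        )

    def test_symmetric_values_are_null(self):
        de = np.concatenate([np.linspace(-1, -0.1, 20), np.linspace(0.1, 1, 20)])
        out = de_contrast(self._stats(de, [0.0] * 100), "value")
        assert out.loc[0, "p_value"] > 0.5

    def test_planted_shift_detected(self, rng):
        non = rng.normal(0, 1, 300)
        de = rng.normal(0, 0.01, 200) + non.mean() + 0.1
        out = de_contrast(self._stats(de, non), "value")
        assert out.loc[0, "p_value"] < 0.001
        assert out.loc[0, "de_mean"] > out.loc[0, "non_de_mean"]

    def test_one_row_per_stratum(self, rng):
        df = pd.concat(
            [
                self._stats(rng.normal(size=10), rng.normal(size=30), ct)
                for ct in ("autosome", "XL", "XR")
            ],
            ignore_index=True,
        )
        out = de_contrast(df, "value")
        assert sorted(out["chrom_type"]) == ["XL", "XR", "autosome"]

    def test_two_sample_mode(self, rng):
        out = de_contrast(
            self._stats(rng.normal(1, 0.1, 50), rng.normal(0, 0.1, 50)),
            "value",
            mode="two-sample",
        )
        assert out.loc[0, "p_value"] < 0.001


class TestAncova:
    def _records(self, rng, n=300, effect=0.0):
        chrom = rng.choice(["autosome", "XL", "XR"], size=n)
        tajd_e = rng.normal(0, 1, n)
        tajd_m = rng.normal(0, 1, n)
        delta = rng.normal(0, 1, n)
        if effect:
            delta = delta + effect * tajd_m * (chrom == "XL")
        return pd.DataFrame(
            {"delta_sb": delta, "tajd_e": tajd_e, "tajd_m": tajd_m, "chrom_type": chrom}
        )

    def test_planted_chromosome_interaction_detected(self, rng):
        out = ancova_delta_sb(self._records(rng, n=500, effect=0.5))
        anova = out["anova"].set_index("term")
        assert anova.loc["tajd_m:chromosome", "p_value"] < 0.001

    def test_null_terms_near_nominal_rate(self):
        rng = np.random.default_rng(9)
        hits = {"tajd_e": 0, "tajd_m": 0}
        n_iter = 200
        for _ in range(n_iter):
            out = ancova_delta_sb(self._records(rng, n=90))
            anova = out["anova"].set_index("term")
            for term in hits:
                hits[term] += anova.loc[term, "p_value"] < 0.05
        for term, h in hits.items():
            assert 0.005 < h / n_iter < 0.12

    def test_coefficients_match_normal_equations_on_small_fixture(self, rng):
        df = pd.DataFrame(
            {
                "delta_sb": rng.normal(size=12),
                "tajd_e": rng.normal(size=12),
                "tajd_m": rng.normal(size=12),
                "chrom_type": ["autosome"] * 6 + ["XL"] * 6,
            }
        )
        out = ancova_delta_sb(df)
        # dummy coding follows sorted level order: baseline "XL",
        # indicator for "autosome"
        x_chrom = (df["chrom_type"] == "autosome").astype(float).to_numpy()
        X = np.column_stack(
            [
                np.ones(12),
                x_chrom,
                df["tajd_e"],
                df["tajd_m"],
                x_chrom * df["tajd_e"],
                x_chrom * df["tajd_m"],
            ]
        )
        y = df["delta_sb"].to_numpy()
        beta_ref = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(out["coefficients"]["estimate"].to_numpy(), beta_ref, atol=1e-8)

    def test_sparse_chromosome_type_rejected(self, rng):
        df = self._records(rng, n=50)
        df.loc[df.index[:-1], "chrom_type"] = "autosome"
        df.loc[df.index[-1], "chrom_type"] = "XL"
        with pytest.raises(ValueError, match="chromosome type"):
            ancova_delta_sb(df)


class TestPipelineLevelSignatures:
    def test_de_enriched_annotation_detected_by_overlap_test(self):
        """Genes preferentially flagged DE near selected loci: the overlap
        resampling test should call significance in nearly every draw of
        the annotation."""
        from poolscan import simulate

        cfg = simulate.SimulationConfig(
            chrom_plan=[
                simulate.ChromPlan("2", 500_000, 800, False),
                simulate.ChromPlan("3", 500_000, 800, False),
            ],
            selected_fraction=0.02,
            seed=4,
        )
        t = simulate.simulate_wright_fisher(cfg)
        sel = t.loci[t.loci["selected"]]
        hits = 0
        n_iter = 40
        for i in range(n_iter):
            genes = simulate.generate_gene_annotation_and_de(
                t, 2000, de_enrichment_near_selected=10.0, seed=i
            )
            query = genes_near_snps(sel["chrom"].to_numpy(), sel["pos"].to_numpy(), genes, 10_000)
            de = {g.gene_id for g in genes if g.is_de}
            out = overlap_resampling_test(query, de, [g.gene_id for g in genes], 300, seed=i + 1000)
            hits += out.significant
        assert hits / n_iter >= 0.90

    def test_de_genes_more_differentiated_when_de_tracks_selection(self):
        """When DE status is enriched near divergently selected loci, mean
        gene-level FST of DE genes exceeds that of non-DE genes."""
        from poolscan import calling, diversity, fst, simulate

        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = simulate.SimulationConfig(
                chrom_plan=[
                    simulate.ChromPlan("2", 400_000, 800, False),
                    simulate.ChromPlan("3", 400_000, 800, False),
                ],
                selected_fraction=0.03,
                sel_coeff_e=0.1,
                sel_coeff_m=-0.1,
                seed=seed,
            )
            t = simulate.simulate_wright_fisher(cfg)
            sites = simulate.sample_pool_counts(t, cfg)
            snps = calling.call_snps(sites).snps
            chroms, pos, major, minor = calling.snps_to_arrays(snps)
            sheet = cfg.sample_sheet()
            tab = fst.pairwise_fst_table(chroms, pos, major, minor, sheet)
            w = diversity.make_windows({"2": 400_000, "3": 400_000})
            wf = fst.window_fst(tab, w).groupby(["chrom", "start", "end"], as_index=False)["fst"].mean()
            genes = simulate.generate_gene_annotation_and_de(
                t, 800, de_enrichment_near_selected=10.0, seed=seed + 500
            )
            gm = diversity.gene_mean_stat(wf, genes, "fst")
            de = np.array([g.is_de for g in genes])
            vals = gm["fst"].to_numpy()
            wins += np.nanmean(vals[de]) > np.nanmean(vals[~de])
        assert wins / n_seeds >= 0.80
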