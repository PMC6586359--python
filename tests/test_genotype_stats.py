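"""Genotype-based estimators, binning, normalization and the block bootstrap."""

import numpy as np
import pytest

from ldmoments.basis import build_basis, evaluate_state
from ldmoments.genotype_stats import (
    DataStatsError,
    RecombinationMap,
    assign_bins,
    bootstrap_covariance,
    compute_binned_statistics,
    enumerate_pairs,
    evaluate_pair_statistics,
    genotype_pair_counts,
    pair_statistics,
    read_vcf,
    weir_D_hat,
)
from ldmoments.wright_fisher import WFConfig, simulate_diploid_panel

LEFT = [1, 1, 0, 0]
RIGHT = [1, 0, 1, 0]


def category_probs(f):
    probs = np.zeros(9)
    for h1 in range(4):
        for h2 in range(4):
            probs[3 * (LEFT[h1] + LEFT[h2]) + (RIGHT[h1] + RIGHT[h2])] += f[h1] * f[h2]
    return probs


class TestWeirDHat:
    def test_two_double_homozygotes(self):
        counts = np.zeros(9)
        counts[8] = 1  # AABB
        counts[0] = 1  # aabb
        assert weir_D_hat(counts, 2) == pytest.approx(0.25)

    def test_single_double_heterozygote_is_zero(self):
        counts = np.zeros(9)
        counts[4] = 1  # AaBb: no signed phase information
        assert weir_D_hat(counts, 1) == 0.0

    def test_monomorphic_locus_is_zero(self):
        counts = np.zeros(9)
        counts[2] = 3  # aaBB only: left locus monomorphic
        assert weir_D_hat(counts, 3) == 0.0

    def test_expectation_under_random_union(self, rng):
        """E[D-hat] = (1/2)(1 - 1/n) D: the raw genotype estimator is biased,
        which is exactly why the bias-corrected pair statistics exist."""
        f = np.array([0.4, 0.1, 0.15, 0.35])
        D = f[0] * f[3] - f[1] * f[2]
        n_d = 10
        counts = rng.multinomial(n_d, category_probs(f), size=150000)
        vals = weir_D_hat(counts, n_d)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert vals.mean() == pytest.approx(0.5 * (1 - 1 / n_d) * D, abs=3 * se)


class TestPairEstimators:
    def test_unbiased_for_population_statistics(self, rng):
        """Estimator means match the true statistics over many sampled pairs."""
        f = np.array([[0.35, 0.15, 0.2, 0.3], [0.1, 0.4, 0.25, 0.25]])
        truth = evaluate_state(build_basis(["a", "b"]), f)
        n_pairs, nd = 120000, [12, 9]
        counts = np.stack(
            [rng.multinomial(nd[p], category_probs(f[p]), size=n_pairs) for p in range(2)],
            axis=1,
        )
        ndarr = np.tile(nd, (n_pairs, 1))
        labels, vals = evaluate_pair_statistics(counts, ndarr, 2)
        mean = vals.mean(axis=0)
        se = vals.std(axis=0, ddof=1) / np.sqrt(n_pairs)
        z = (mean - [truth[l] for l in labels]) / np.maximum(se, 1e-15)
        assert np.max(np.abs(z)) < 4.5  # 18 simultaneous comparisons

    def test_monomorphic_pair_gives_zero(self):
        counts = np.zeros((1, 9))
        counts[0, 0] = 15  # everyone aabb
        stats = pair_statistics(counts, [15], 1)
        for label, value in stats.items():
            assert value == pytest.approx(0.0, abs=1e-12), label

    def test_allele_flip_invariance(self, rng):
        """Relabeling the counted allele at one locus (or both) leaves every
        basis statistic estimate unchanged; D-hat flips sign under a
        single-locus relabeling and is invariant under the double one."""
        counts = rng.multinomial(14, category_probs([0.4, 0.1, 0.15, 0.35]), size=50)
        left_map = np.array([3 * (2 - c // 3) + c % 3 for c in range(9)])
        left_flip = counts[:, left_map]
        both_flip = counts[:, ::-1]  # g -> 2-g at both loci reverses categories
        s0 = evaluate_pair_statistics(counts[:, None, :], np.full((50, 1), 14), 1)[1]
        for variant in (left_flip, both_flip):
            sv = evaluate_pair_statistics(variant[:, None, :], np.full((50, 1), 14), 1)[1]
            np.testing.assert_allclose(s0, sv, atol=1e-10)
        np.testing.assert_allclose(
            weir_D_hat(left_flip, 14), -weir_D_hat(counts, 14), atol=1e-12
        )
        np.testing.assert_allclose(
            weir_D_hat(both_flip, 14), weir_D_hat(counts, 14), atol=1e-12
        )

    def test_two_haplotype_population_stress_case(self, rng):
        """A population carrying only AB and ab haplotypes (maximal LD, so
        sampled tables are mostly homozygous) is still estimated without bias."""
        f = np.array([0.6, 0.0, 0.0, 0.4])  # D = 0.24
        truth = evaluate_state(build_basis(["p"]), f[None])
        counts = rng.multinomial(15, category_probs(f), size=60000)[:, None, :]
        labels, vals = evaluate_pair_statistics(counts, np.full((60000, 1), 15), 1)
        mean = vals.mean(axis=0)
        se = vals.std(axis=0, ddof=1) / np.sqrt(60000)
        for i, l in enumerate(labels):
            assert mean[i] == pytest.approx(truth[l], abs=4 * se[i] + 1e-12), l


class TestBinningAndMaps:
    def test_uniform_map_distance(self):
        rm = RecombinationMap.uniform(["chr1"], rate_cm_per_mb=1.0)
        m = rm.interpolate("chr1", np.array([1, 1_000_001]))
        assert (m[1] - m[0]) == pytest.approx(1e-2 * 1.0, rel=1e-9)  # 1 cM = 0.01 M

    def test_half_open_bins_and_bounds(self):
        edges = [1e-4, 1e-3, 1e-2]
        r = np.array([5e-5, 1e-4, 9.9e-4, 1e-3, 9.9e-3, 1e-2])
        np.testing.assert_array_equal(assign_bins(r, edges), [-1, 0, 0, 1, 1, -1])

    def test_pair_enumeration_matches_brute_force(self, rng):
        from ldmoments.genotype_stats import GenotypeMatrix

        pos = np.sort(rng.choice(np.arange(1, 3_000_000), size=60, replace=False))
        gm = GenotypeMatrix(
            chrom=np.zeros(60, dtype=int),
            chrom_names=["chr1"],
            positions=pos,
            genotypes=np.zeros((60, 4), dtype=np.int8),
            samples=["s1", "s2", "s3", "s4"],
            pop_of={f"s{i}": "p" for i in range(1, 5)},
        )
        rm = RecombinationMap.uniform(["chr1"], 1.0)
        r_min, r_max = 1e-5, 2e-3
        lefts, rights, r = enumerate_pairs(gm, rm, r_min, r_max)
        g = rm.interpolate("chr1", pos)
        expected = {
            (i, j)
            for i in range(60)
            for j in range(i + 1, 60)
            if r_min <= g[j] - g[i] <= r_max
        }
        assert set(zip(lefts.tolist(), rights.tolist())) == expected

    def test_short_range_pairs_excluded(self):
        r = np.array([5e-6])
        assert assign_bins(r, [1e-5, 1e-3])[0] == -1


class TestPipeline:
    @pytest.fixture(scope="class")
    def panel(self):
        cfg = WFConfig(
            pop_sizes=[200, 200],
            r=0.001,
            mig=np.array([[0, 0.002], [0.002, 0]]),
            init=np.array([[0.3, 0.2, 0.25, 0.25]] * 2),
            generations=30,
            replicates=4000,
            seed=21,
        )
        return simulate_diploid_panel(cfg, 4000, {"pop0": 25, "pop1": 25})

    def test_vcf_roundtrip_equals_in_memory(self, panel, tmp_path):
        panel.write_vcf(tmp_path / "p.vcf")
        panel.write_popmap(tmp_path / "p.popmap.tsv")
        gm = read_vcf(tmp_path / "p.vcf", tmp_path / "p.popmap.tsv")
        direct = panel.to_genotype_matrix()
        np.testing.assert_array_equal(gm.genotypes, direct.genotypes)
        np.testing.assert_array_equal(gm.positions, direct.positions)
        assert gm.samples == direct.samples

    def test_recmap_roundtrip(self, panel, tmp_path):
        panel.write_recmap(tmp_path / "map.txt")
        rm = RecombinationMap.read(tmp_path / "map.txt")
        direct = panel.recombination_map()
        got = rm.interpolate("chr1", panel.positions[:10])
        want = direct.interpolate("chr1", panel.positions[:10])
        np.testing.assert_allclose(got, want, rtol=1e-6)

    def test_binned_pipeline_determinism(self, panel):
        gm = panel.to_genotype_matrix()
        rm = panel.recombination_map()
        kw = dict(
            bin_edges=np.logspace(-3.1, -2.9, 3),
            r_min=5e-4,
            r_max=2e-3,
            normalization="pop0",
            n_boot=25,
            seed=11,
            block_by_chromosome=True,
            min_diploids=20,
        )
        d1 = compute_binned_statistics(gm, rm, ["pop0", "pop1"], **kw)
        d2 = compute_binned_statistics(gm, rm, ["pop0", "pop1"], **kw)
        np.testing.assert_array_equal(d1.means, d2.means)
        np.testing.assert_array_equal(d1.cov, d2.cov)
        assert d1.constant_labels() == ["pi2_1_1_1_1", "H_1_1"]
        np.testing.assert_allclose(d1.column("pi2_1_1_1_1"), 1.0, atol=1e-12)

    def test_output_files(self, panel, tmp_path):
        gm = panel.to_genotype_matrix()
        rm = panel.recombination_map()
        data = compute_binned_statistics(
            gm, rm, ["pop0", "pop1"],
            bin_edges=np.logspace(-3.1, -2.9, 3), r_min=5e-4, r_max=2e-3,
            normalization="pop0", n_boot=25, seed=11, block_by_chromosome=True,
        )
        data.write(tmp_path / "out")
        assert (tmp_path / "out.means.tsv").exists()
        assert (tmp_path / "out.cov.tsv").exists()
        assert (tmp_path / "out.meta.json").exists()


class TestBootstrap:
    def test_bootstrap_variance_matches_block_mean_variance(self, rng):
        """For independent equal-size blocks, the bootstrap variance of the
        grand mean equals the population variance of block means over B."""
        B, per_block = 60, 40
        block_means = rng.normal(0, 1.0, B)
        stats = np.repeat(block_means, per_block)[:, None] + rng.normal(
            0, 0.01, (B * per_block, 1)
        )
        bin_idx = np.zeros(B * per_block, dtype=int)
        block_idx = np.repeat(np.arange(B), per_block)
        out = bootstrap_covariance(
            stats, bin_idx, block_idx, 1, ["x"], None, 400, 3,
            np.array([0.0, 1.0]), "raw",
        )
        s2 = block_means.var(ddof=0)
        assert out.cov[0, 0, 0] == pytest.approx(s2 / B, rel=0.15)

    def test_identical_blocks_give_vanishing_covariance(self):
        stats = np.ones((1000, 2))
        bin_idx = np.zeros(1000, dtype=int)
        block_idx = np.arange(1000) % 50
        out = bootstrap_covariance(
            stats, bin_idx, block_idx, 1, ["x", "y"], None, 100, 0,
            np.array([0.0, 1.0]), "raw",
        )
        assert np.max(np.abs(out.cov)) < 1e-20

    def test_too_few_replicates_rejected(self):
        with pytest.raises(DataStatsError):
            bootstrap_covariance(
                np.ones((10, 1)), np.zeros(10, dtype=int), np.arange(10) % 2, 1,
                ["x"], None, 1, 0, np.array([0.0, 1.0]), "raw",
            )
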