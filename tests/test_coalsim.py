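"""SMC' sequence simulator, block generation, and VCF output."""

import math

import numpy as np
import pytest

from demoscope.coalsim import (
    RateSamplerConfig,
    SimBlock,
    simulate_blocks,
    simulate_window,
    write_vcf,
)
from demoscope.coalsim import _sample_marginal_tree, _Tree  # internal, for invariants
from demoscope.errors import InvalidInputError, UnsupportedFeatureError
from demoscope.timeline import compile_timeline


class TestSimBlock:
    def test_rejects_monomorphic_sites(self):
        with pytest.raises(InvalidInputError):
            SimBlock("b", 100, 1e-8, np.array([5]), np.array([[1, 1, 1, 1]]))

    def test_rejects_unsorted_positions(self):
        h = np.array([[1, 0], [0, 1]], dtype=np.uint8)
        with pytest.raises(InvalidInputError):
            SimBlock("b", 100, 1e-8, np.array([10, 5]), h)


class TestRateSampler:
    def test_lognormal_median(self, rng):
        cfg = RateSamplerConfig()
        draws = np.array([cfg.sample(rng) for _ in range(4000)])
        assert np.median(draws) == pytest.approx(1.1e-8, rel=0.1)
        assert np.all(draws >= 0) and np.all(np.isfinite(draws))

    def test_fixed(self, rng):
        cfg = RateSamplerConfig(family="fixed", fixed_rate=2e-8)
        assert cfg.sample(rng) == 2e-8

    def test_bad_family(self):
        with pytest.raises(InvalidInputError):
            RateSamplerConfig(family="cauchy")

    def test_truncation(self, rng):
        cfg = RateSamplerConfig(truncate_low=1e-8, truncate_high=2e-8)
        for _ in range(100):
            assert 1e-8 <= cfg.sample(rng) <= 2e-8


class TestSimulateWindow:
    def test_no_recombination_single_genealogy(self, const_pop):
        b = simulate_window(const_pop, 8, 10_000, r=0.0, seed=4)
        # every incidence pattern comes from one tree: at most 2n-2 branches
        pats = {tuple(row) for row in b.haplotypes}
        assert len(pats) <= 2 * 8 - 2
        # sites sharing a branch are perfectly correlated
        assert b.n_sites >= 1

    def test_determinism(self, const_pop):
        a = simulate_window(const_pop, 10, 50_000, r=1e-8, seed=11)
        b = simulate_window(const_pop, 10, 50_000, r=1e-8, seed=11)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)

    def test_different_seeds_differ(self, const_pop):
        a = simulate_window(const_pop, 10, 50_000, r=1e-8, seed=11)
        b = simulate_window(const_pop, 10, 50_000, r=1e-8, seed=12)
        assert a.n_sites != b.n_sites or not np.array_equal(a.positions, b.positions)

    def test_pair_diversity_matches_theta(self, const_pop):
        # n=2: mean pairwise diversity per site -> 4*N*mu = 5e-4
        tot = 0
        n_windows, L = 300, 20_000
        for i in range(n_windows):
            b = simulate_window(const_pop, 2, L, r=1e-8, seed=21, block_id=f"w{i}")
            tot += b.n_sites
        est = tot / (n_windows * L)
        se = math.sqrt(est / (n_windows * L))  # Poisson-ish bound
        assert abs(est - 5e-4) < 4 * se

    def test_watterson_segregating_sites(self, const_pop):
        n_windows, L, n = 120, 100_000, 20
        counts = [
            simulate_window(const_pop, n, L, r=1.1e-8, seed=31, block_id=f"w{i}").n_sites
            for i in range(n_windows)
        ]
        h = sum(1.0 / k for k in range(1, n))
        expect = 4 * 10_000 * 1.25e-8 * L * h  # ~177.4
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / math.sqrt(n_windows)
        assert abs(mean - expect) < 3 * se, (mean, expect, se)

    def test_marginal_tree_matches_standard_coalescent(self, bottleneck_pop):
        # SMC' property: per-position genealogy ~ standard coalescent.
        # Compare total tree length at the window's right end against r=0.
        n, L = 6, 50_000
        def right_end_tree_lengths(r, seed, reps):
            out = []
            for i in range(reps):
                b = simulate_window(
                    bottleneck_pop, n, L, r=r, mu=2e-7, seed=seed, block_id=f"w{i}"
                )
                right = b.positions > L - 10_000
                out.append(right.sum())  # mutation count ~ tree length there
            return np.array(out, dtype=float)

        with_rec = right_end_tree_lengths(2e-8, 41, 150)
        without = right_end_tree_lengths(0.0, 42, 150)
        se = math.hypot(
            with_rec.std(ddof=1) / math.sqrt(len(with_rec)),
            without.std(ddof=1) / math.sqrt(len(without)),
        )
        assert abs(with_rec.mean() - without.mean()) < 3 * se

    def test_exchangeability(self, const_pop, rng):
        b = simulate_window(const_pop, 10, 50_000, r=1e-8, seed=13)
        perm = rng.permutation(10)
        permuted = b.haplotypes[:, perm]
        # summary statistics invariant under haplotype relabeling
        assert sorted(b.haplotypes.sum(axis=1)) == sorted(permuted.sum(axis=1))

    def test_input_validation(self, const_pop):
        with pytest.raises(InvalidInputError):
            simulate_window(const_pop, 1, 1_000, r=1e-8)
        with pytest.raises(InvalidInputError):
            simulate_window(const_pop, 4, 0, r=1e-8)
        with pytest.raises(InvalidInputError):
            simulate_window(const_pop, 4, 1_000, r=-1e-8)

    def test_multi_population_unsupported(self):
        from demoscope.models import three_population_migration

        with pytest.raises(UnsupportedFeatureError):
            simulate_window(three_population_migration(), 4, 1_000, r=1e-8)


class TestTreeInvariants:
    def test_smc_prime_updates_keep_tree_consistent(self, const_pop):
        segments = compile_timeline(const_pop, 1).segments
        rng = np.random.default_rng(5)
        from demoscope.coalsim import _apply_recoalescence, _sample_recoalescence

        tree = _sample_marginal_tree(segments, 12, rng)
        tree.check()
        for _ in range(200):
            edges = tree.edges()
            lens = np.array([tree.parent_time(v) - tree.time[v] for v in edges])
            ci = int(rng.choice(len(edges), p=lens / lens.sum()))
            e = edges[ci]
            t_d = tree.time[e] + lens[ci] * rng.random()
            t_star, target = _sample_recoalescence(tree, segments, t_d, rng)
            if target != e:
                _apply_recoalescence(tree, e, t_star, target)
            tree.check()


class TestSimulateBlocks:
    def test_reproducible_and_block_keyed(self, const_pop):
        cfg = RateSamplerConfig()
        a = simulate_blocks(const_pop, 3, 4, 10_000, cfg, seed=9)
        b = simulate_blocks(const_pop, 3, 4, 10_000, cfg, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.haplotypes, y.haplotypes)
            assert x.rate == y.rate
        rates = {x.rate for x in a}
        assert len(rates) > 1  # per-block rates drawn independently

    def test_empirical_sfs_matches_analytic(self, bottleneck_pop):
        from demoscope.analytic import expected_sfs_analytic
        from demoscope.popgen_summaries import empirical_sfs, genotypes_from_blocks

        n_blocks, L, n_dip = 150, 50_000, 5
        n = 2 * n_dip
        blocks = simulate_blocks(
            bottleneck_pop, n_dip, n_blocks, L,
            RateSamplerConfig(family="fixed", fixed_rate=1e-8), seed=17,
        )
        # blocks are iid: use block-to-block scatter for the standard error
        per_block = np.zeros((n_blocks, n - 1))
        for i, b in enumerate(blocks):
            gm = genotypes_from_blocks([b])
            per_block[i] = empirical_sfs(gm).values
        an = expected_sfs_analytic(bottleneck_pop, n)
        expect = an.values * L
        mean = per_block.mean(axis=0)
        se = per_block.std(axis=0, ddof=1) / math.sqrt(n_blocks)
        z = (mean - expect) / se
        assert np.all(np.abs(z) < 3.0), z

    def test_validation(self, const_pop):
        with pytest.raises(InvalidInputError):
            simulate_blocks(const_pop, 0, 1, 100, RateSamplerConfig(), seed=0)
        with pytest.raises(InvalidInputError):
            simulate_blocks(const_pop, 2, 0, 100, RateSamplerConfig(), seed=0)


class TestWriteVcf:
    def test_round_trip(self, const_pop, tmp_path):
        pytest.importorskip("cyvcf2")
        from demoscope.popgen_summaries import genotypes_from_blocks, read_vcf

        blocks = simulate_blocks(
            const_pop, 4, 3, 20_000, RateSamplerConfig(), seed=23
        )
        p = tmp_path / "sim.vcf"
        write_vcf(blocks, p)
        gm_direct = genotypes_from_blocks(blocks)
        gm_read = read_vcf(p)
        np.testing.assert_array_equal(gm_read.dosages, gm_direct.dosages)
        np.testing.assert_array_equal(gm_read.positions, gm_direct.positions)

    def test_gt_encoding(self, tmp_path):
        # incidence in haplotypes {1, 3} of 4 -> "1|0  1|0" after pairing
        h = np.array([[1, 0, 1, 0]], dtype=np.uint8)
        b = SimBlock("c1", 100, 1e-8, np.array([7]), h)
        p = tmp_path / "enc.vcf"
        write_vcf([b], p)
        data_line = [ln for ln in p.read_text().splitlines() if not ln.startswith("#")][0]
        assert data_line.split("\t")[9:] == ["1|0", "1|0"]

    def test_empty_block_header_only(self, tmp_path):
        b = SimBlock(
            "c1", 100, 1e-8, np.empty(0, dtype=np.int64), np.empty((0, 4), dtype=np.uint8)
        )
        p = tmp_path / "empty.vcf"
        write_vcf([b], p)
        text = p.read_text().splitlines()
        assert any("##contig=<ID=c1" in ln for ln in text)
        assert all(ln.startswith("#") for ln in text)

    def test_unsorted_positions_rejected(self, tmp_path):
        h = np.array([[1, 0], [0, 1]], dtype=np.uint8)
        b = SimBlock("c1", 100, 1e-8, np.array([5, 10]), h)
        object.__setattr__(b, "positions", np.array([10, 5]))  # corrupt post-hoc
        with pytest.raises(InvalidInputError):
            write_vcf([b], tmp_path / "bad.vcf")
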