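"""Coalescent simulators: exactness, determinism, full-model behavior."""

import math

import numpy as np
import pytest
from scipy import stats

from sweepgf import (MutationModel, ParameterError, StarlikeModel,
                     SweepParams)
from sweepgf.observables import expected_iton_lengths_gf, expected_tmrca
from sweepgf.simulate import (ReplicateDataset, Trajectory, block_distances,
                              hybrid_iton_sample, pair_sweep_outcomes,
                              simulate_blocks, simulate_hybrid_genealogy,
                              simulate_trajectory_sweep)


class TestHybridSampler:
    def test_mean_tmrca_matches_closed_form(self):
        R = 100_000
        res = hybrid_iton_sample(2, 0.25, 0.5, R, seed=11)
        se = res["tmrca"].std() / math.sqrt(R)
        assert abs(res["tmrca"].mean() - expected_tmrca(0.25, 0.5)) < 3 * se

    def test_degenerate_origin_sample(self):
        res = hybrid_iton_sample(4, 0.0, 0.0, 500, seed=2)
        assert np.all(res["tmrca"] == 0.0)
        assert np.all(res["titon"] == 0.0)

    def test_old_sweep_neutral_tmrca(self):
        res = hybrid_iton_sample(2, 0.3, 25.0, 40_000, seed=3)
        assert stats.kstest(res["tmrca"], "expon").pvalue > 0.01

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_iton_means_match_gf_derivatives(self, n):
        """The hybrid sampler is an exact sampler of the analytic model."""
        R = 200_000
        al, Ta = 0.14, 0.25
        res = hybrid_iton_sample(n, al, Ta, R, seed=5)
        emp = res["titon"].mean(axis=0)
        se = res["titon"].std(axis=0) / math.sqrt(R)
        ref = expected_iton_lengths_gf(n, al, Ta)
        assert np.all(np.abs(emp - ref) < 3.5 * se + 1e-12)

    def test_seed_determinism(self):
        a = hybrid_iton_sample(4, 0.1, 0.3, 1000, seed=77)
        b = hybrid_iton_sample(4, 0.1, 0.3, 1000, seed=77)
        assert np.array_equal(a["titon"], b["titon"])
        assert np.array_equal(a["tmrca"], b["tmrca"])

    def test_per_replicate_alpha_array(self):
        al = np.array([0.0, np.inf] * 500)
        res = hybrid_iton_sample(2, al, 0.0, 1000, seed=6)
        # alpha=0, Ta=0 replicates coalesce instantly; neutral ones do not
        assert np.all(res["tmrca"][al == 0.0] == 0.0)
        assert np.all(res["tmrca"][np.isinf(al)] > 0.0)


class TestLabeledSimulator:
    def test_matches_vectorized_means(self):
        rng = np.random.default_rng(10)
        R = 20_000
        acc = np.zeros((R, 3))
        for i in range(R):
            g = simulate_hybrid_genealogy(4, 0.25, StarlikeModel(0.14),
                                          rng=rng)
            acc[i] = g.iton_lengths()
        ref = expected_iton_lengths_gf(4, 0.14, 0.25)
        se = acc.std(axis=0) / math.sqrt(R)
        assert np.all(np.abs(acc.mean(axis=0) - ref) < 4 * se)

    def test_exchangeability_of_labels(self):
        """Permuting sample labels leaves i-Ton summaries invariant in
        distribution: every singleton carrier is equally frequent."""
        rng = np.random.default_rng(11)
        counts = np.zeros(4)
        for _ in range(4000):
            g = simulate_hybrid_genealogy(4, 0.2, StarlikeModel(0.3),
                                          rng=rng)
            for carriers, length in g.branches:
                if len(carriers) == 1:
                    counts[next(iter(carriers))] += length
        assert counts.std() / counts.mean() < 0.05

    def test_branch_lengths_consistent_with_tmrca(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            g = simulate_hybrid_genealogy(5, 0.4, StarlikeModel(0.2),
                                          rng=rng)
            assert all(l >= 0 for _, l in g.branches)
            assert max(l for _, l in g.branches) <= g.tmrca + 1e-12

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            simulate_hybrid_genealogy(1, 0.1, StarlikeModel(0.1), seed=1)
        with pytest.raises(ParameterError):
            simulate_hybrid_genealogy(4, 0.1, "not-a-model", seed=1)


class TestNeutralOracleMsprime:
    def test_iton_means_against_msprime(self):
        """Independent oracle: neutral i-Ton branch lengths from msprime."""
        msprime = pytest.importorskip("msprime")
        R = 2000
        acc = np.zeros((R, 3))
        for i, ts in enumerate(msprime.sim_ancestry(
                samples=2, ploidy=2, population_size=0.5,
                num_replicates=R, random_seed=99)):
            tree = ts.first()
            for node in tree.nodes():
                if tree.parent(node) != -1:
                    k = tree.num_samples(node)
                    if 1 <= k <= 3:
                        acc[i, k - 1] += tree.branch_length(node)
        emp = acc.mean(axis=0)
        se = acc.std(axis=0) / math.sqrt(R)
        ours = hybrid_iton_sample(4, np.inf, 0.0, 100_000, seed=13)
        ours_mean = ours["titon"].mean(axis=0)
        assert np.all(np.abs(emp - ours_mean) < 4 * se)


class TestTrajectorySimulator:
    def test_logistic_path_monotone_and_bounded(self):
        params = SweepParams(10_000, 0.05, 1e-7)
        traj = Trajectory.logistic(params)
        assert np.all(np.diff(traj.X) <= 0)
        assert traj.X[0] > 0.99 and traj.X[-1] < 1e-3
        assert traj.times[-1] == pytest.approx(params.t_fix)

    def test_no_recombination_no_escape(self):
        out = pair_sweep_outcomes(SweepParams(10_000, 0.05, 0.0), 10_000,
                                  5000, seed=13)
        assert out["fail_to_escape"] == 1.0

    def test_starlike_bias_positive_at_moderate_alpha(self):
        """At intermediate distances the full model coalesces more pairs
        than e^{-2 alpha}: coalescence near the sweep origin truncates the
        escape opportunity the star-like approximation integrates in
        full."""
        params = SweepParams(10_000, 0.05, 1e-7)
        out = pair_sweep_outcomes(params, 20_000, 50_000, seed=14)
        ref = math.exp(-2 * params.alpha_at(20_000))
        assert out["fail_to_escape"] - ref > 0.02

    def test_burst_sits_late_in_the_sweep(self):
        params = SweepParams(10_000, 0.05, 1e-7)
        out = pair_sweep_outcomes(params, 10_000, 20_000, seed=15)
        frac = out["coal_frac_of_tfix"].mean()
        assert 0.5 < frac <= 1.0

    def test_full_genealogy_r0_coalesces_by_origin(self):
        params = SweepParams(2000, 0.05, 0.0, Ta=0.1)
        rng = np.random.default_rng(16)
        for _ in range(50):
            g = simulate_trajectory_sweep(4, params, 1000, rng=rng)
            assert g.tmrca <= params.Ta + params.t_fix_coal + 1e-9

    def test_neutral_limit_far_away(self):
        """Far from the target (and with a brief sweep epoch), tmrca
        behaves neutrally: the only residual effect is the slightly
        smaller ancestral background during the sweep, which vanishes
        with t_fix/(2Ne)."""
        params = SweepParams(10_000, 0.2, 1e-7, Ta=0.05)
        rng = np.random.default_rng(17)
        tm = [simulate_trajectory_sweep(2, params, 5_000_000, rng=rng).tmrca
              for _ in range(2000)]
        assert stats.kstest(tm, "expon").pvalue > 0.01


class TestBlocks:
    def test_block_distances_layout(self):
        d = block_distances(6, 100)
        assert np.allclose(d, [250, 150, 50, 50, 150, 250])
        with pytest.raises(ParameterError):
            block_distances(5, 100)

    def test_neutral_pair_diversity_equals_theta(self):
        """Mean pairwise differences per block ~ theta under the mutation
        convention (theta/2 per branch-length unit, 2 branches)."""
        theta = 0.5
        params = SweepParams(10_000, 0.05, 1e-7, Ta=0.1)
        ds = simulate_blocks(params, (10_000, 100), 2,
                             MutationModel(theta, 30), mode="neutral",
                             seed=18, x=2)
        k = ds.configs[:, 0, 0].astype(float)
        se = k.std() / math.sqrt(k.size)
        assert abs(k.mean() - theta) < 3 * se

    def test_far_blocks_indistinguishable_from_neutral(self):
        """Blocks at alpha > 5 carry configuration frequencies matching the
        neutral model (chi-square)."""
        from sweepgf.observables import neutral_bsfs_probabilities

        theta = 0.5
        mut = MutationModel(theta, 2)
        params = SweepParams(10_000, 0.005, 1e-7, Ta=0.1)
        ds = simulate_blocks(params, (4000, 2000), 4, mut, mode="sweep",
                             seed=19)
        sel = ds.alphas > 5.0
        assert sel.sum() > 1000
        codes = ds.codes()[sel, 0]
        ref = neutral_bsfs_probabilities(mut).flat
        obs = np.bincount(codes, minlength=64).astype(float)
        exp = ref * obs.sum()
        pool = exp >= 5
        chi2 = (((obs[pool] - exp[pool]) ** 2) / exp[pool]).sum() \
            + ((obs[~pool].sum() - exp[~pool].sum()) ** 2
               / max(exp[~pool].sum(), 1e-9))
        dof = pool.sum()
        assert stats.chi2.sf(chi2, dof) > 0.01

    def test_sweep_blocks_match_analytic_bsfs(self):
        from sweepgf.observables import bsfs_probabilities

        mut = MutationModel(0.5, 2)
        params = SweepParams(10_000, 0.05, 1e-7, Ta=0.1)
        B = 30_000
        # all blocks at the same distance: compare frequencies to the table
        al = params.alpha_at(5_000)
        rng = np.random.default_rng(20)
        res = hybrid_iton_sample(4, al, params.Ta, B, rng=rng)
        k = rng.poisson(mut.theta / 2 * res["titon"])
        from sweepgf.observables import BsfsTable

        codes = BsfsTable.config_code(k, 2)
        freq = np.bincount(codes, minlength=64) / B
        tab = bsfs_probabilities(al, params.Ta, mut)
        se = np.sqrt(tab.flat * (1 - tab.flat) / B)
        assert np.all(np.abs(freq - tab.flat) < 4 * se + 5 / B)

    def test_subsampled_dataset_shape(self):
        mut = MutationModel(0.5, 2)
        params = SweepParams(10_000, 0.05, 1e-7, Ta=0.1)
        ds = simulate_blocks(params, (4, 100), 6, mut, mode="sweep", seed=21)
        assert ds.configs.shape == (4, 15, 3)   # C(6,4) subsamples

    def test_tsv_roundtrip_identical(self, tmp_path):
        mut = MutationModel(0.5, 2)
        params = SweepParams(10_000, 0.05, 1e-7, Ta=0.1)
        ds = simulate_blocks(params, (20, 100), 4, mut, mode="sweep",
                             seed=22)
        path = tmp_path / "ds.tsv"
        ds.to_tsv(path)
        back = ReplicateDataset.from_tsv(path)
        assert np.array_equal(back.configs, ds.configs)
        assert np.allclose(back.distances, ds.distances)
        assert back.kmax == ds.kmax and back.mode == ds.mode
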