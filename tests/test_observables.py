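"""Analytic observables: tmrca, SFS, topologies, i-Ton marginals, bSFS."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sweepgf import ParameterError, StarlikeModel
from sweepgf.gf import make_sample, neutral_gf
from sweepgf.observables import (BsfsTable, MutationModel,
                                 bsfs_probabilities, expected_iton_lengths_gf,
                                 expected_sfs, expected_tmrca,
                                 expected_tmrca_gf, iton_marginal_distribution,
                                 lineage_count_pmf, neutral_bsfs_probabilities,
                                 tmrca_distribution, topology_probs_n4)


class TestExpectedTmrca:
    def test_closed_form(self):
        assert expected_tmrca(0.25, 0.5) == pytest.approx(1 - math.exp(-1))
        assert expected_tmrca(0.0, 0.0) == 0.0
        assert expected_tmrca(np.inf, 0.2) == 1.0
        assert expected_tmrca(0.3, 40.0) == pytest.approx(1.0, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(al=st.floats(0.0, 4.0), Ta=st.floats(0.0, 4.0))
    def test_dual_path_agreement(self, al, Ta):
        assert expected_tmrca(al, Ta) == pytest.approx(
            expected_tmrca_gf(al, Ta), abs=1e-10)

    def test_duration_correction_shifts_ta(self):
        corr = 0.0921
        assert expected_tmrca(0.1, 0.2, ta_correction=corr) == \
            pytest.approx(expected_tmrca(0.1, 0.2 + corr))


class TestTmrcaDistribution:
    def test_atom_and_pieces(self):
        d = tmrca_distribution(0.1, 0.3)
        (loc, mass), = d.masses
        assert loc == pytest.approx(0.3)
        assert mass == pytest.approx(math.exp(-0.5))
        # density is neutral below Ta and scaled-neutral above
        assert d.pdf(0.2) == pytest.approx(math.exp(-0.2))
        assert d.pdf(0.5) == pytest.approx(
            math.exp(-0.5) * (1 - math.exp(-0.2)))

    def test_cdf_levels(self):
        al, Ta = 0.1, 0.3
        d = tmrca_distribution(al, Ta)
        p02 = math.exp(-2 * al)
        assert d.cdf(0.2) == pytest.approx(1 - math.exp(-0.2))
        assert d.cdf(0.4) == pytest.approx(1 - math.exp(-0.4) * (1 - p02))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(al=st.floats(0.0, 3.0), Ta=st.floats(0.0, 3.0))
    def test_total_mass_and_mean(self, al, Ta):
        d = tmrca_distribution(al, Ta)
        assert d.total_mass() == pytest.approx(1.0, abs=1e-10)
        assert d.mean() == pytest.approx(expected_tmrca(al, Ta), abs=1e-10)

    def test_neutral_limit_no_atom(self):
        d = tmrca_distribution(np.inf, 0.7)
        assert not d.masses
        grid = np.linspace(0, 5, 100)
        assert np.allclose(d.pdf(grid), np.exp(-grid), atol=1e-12)

    def test_gf_inversion_reproduces_distribution(self):
        """Inverting the pairwise GF in omega gives the same density."""
        from sweepgf import gf_with_sweep
        from sweepgf.observables import PiecewiseExpDensity

        al, Ta = 0.2, 0.4
        model = StarlikeModel(al)
        inv = gf_with_sweep(make_sample(2), model).collapse_time(
            "w").invert_delta()
        masses, comps = inv.invert_single("w", Ta, model=model)
        dd = PiecewiseExpDensity.from_components(masses, comps)
        ref = tmrca_distribution(al, Ta)
        grid = np.linspace(0, 5, 200)
        assert np.allclose(np.atleast_1d(dd.cdf(grid)),
                           np.atleast_1d(ref.cdf(grid)), atol=1e-10)


class TestExpectedSFS:
    def test_neutral_proportions(self):
        p = expected_sfs(4, np.inf, 0.5)
        ref = np.array([2.0, 1.0, 2 / 3])
        assert np.allclose(p, ref / ref.sum(), atol=1e-12)

    @pytest.mark.parametrize("al,Ta", [(0.0, 0.1), (0.25, 0.5), (0.1, 1.0),
                                       (1.0, 0.0), (0.069, 0.25)])
    def test_marginal_moments_match_full_gf(self, al, Ta):
        """The occupancy/partition decomposition agrees with GF derivatives."""
        et = expected_iton_lengths_gf(4, al, Ta)
        assert np.allclose(et / et.sum(), expected_sfs(4, al, Ta),
                           atol=1e-10)

    def test_proportions_sum_to_one(self):
        for n in (2, 5, 9, 10):
            p = expected_sfs(n, 0.2, 0.3)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            assert (p >= 0).all()

    def test_singleton_excess_at_center(self):
        p = expected_sfs(9, 0.0, 0.1)
        pn = expected_sfs(9, np.inf, 0.1)
        assert p[0] > pn[0]

    def test_sweep_signature_shifts_with_age(self):
        """Recent sweeps at alpha=0.25 leave a strong high-frequency
        excess; as the sweep ages the multiple-merger signal erodes and the
        intermediate classes recover toward neutrality from below."""
        pn = expected_sfs(9, np.inf, 0.1)
        p0 = expected_sfs(9, 0.25, 0.0)
        assert p0[7] > 2 * pn[7]          # i=8 excess for a fresh sweep
        mids = [expected_sfs(9, 0.25, ta)[4] for ta in (0.0, 0.5, 1.0)]
        assert mids[0] < mids[1] < mids[2]

    def test_degenerate_zero_tree_rejected(self):
        with pytest.raises(ParameterError):
            expected_sfs(4, 0.0, 0.0)

    def test_sample_size_range(self):
        with pytest.raises(ParameterError):
            expected_sfs(11, 0.1, 0.1)

    def test_lineage_count_pmf_normalizes(self):
        for t in (0.01, 0.3, 2.0):
            tot = sum(lineage_count_pmf(9, k, t) for k in range(1, 10))
            assert tot == pytest.approx(1.0, abs=1e-9)


class TestTopologyProbs:
    def test_neutral_limit(self):
        ps, pa, pst = topology_probs_n4(np.inf, 0.3)
        assert ps == pytest.approx(1 / 3, abs=1e-12)
        assert pa == pytest.approx(2 / 3, abs=1e-12)
        assert pst == 0.0

    def test_full_star_at_origin(self):
        assert topology_probs_n4(0.0, 0.0) == (0.0, 0.0, 1.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(al=st.floats(0, 5), Ta=st.floats(0, 5))
    def test_sum_to_one_identity(self, al, Ta):
        assert sum(topology_probs_n4(al, Ta)) == pytest.approx(1.0,
                                                               abs=1e-12)

    def test_probabilities_in_unit_interval(self):
        for al in (0.0, 0.1, 0.5, 2.0):
            for Ta in (0.0, 0.2, 1.0, 3.0):
                for p in topology_probs_n4(al, Ta):
                    assert -1e-12 <= p <= 1 + 1e-12


class TestItonMarginals:
    def test_neutral_tripleton_atom(self):
        d = iton_marginal_distribution(3, np.inf, 0.7)
        (loc, mass), = d.masses
        assert loc == 0.0
        assert mass == pytest.approx(1 / 3, abs=1e-10)

    def test_neutral_singleton_doubleton_no_atoms(self):
        for i in (1, 2):
            d = iton_marginal_distribution(i, np.inf, 0.7)
            assert not d.masses

    @pytest.mark.parametrize("al,Ta", [(0.1, 0.3), (0.069, 0.1),
                                       (0.14, 0.25)])
    def test_discontinuity_counts(self, al, Ta):
        """n-1 = 3 jumps for singletons at {Ta, 2Ta, 4Ta}; floor(n/i)+1
        discontinuities for i > 1."""
        d1 = iton_marginal_distribution(1, al, Ta)
        locs = d1.discontinuities()
        assert len(locs) == 3
        assert np.allclose(sorted(locs), [Ta, 2 * Ta, 4 * Ta], atol=1e-8)
        assert len(iton_marginal_distribution(2, al, Ta).discontinuities()) \
            == 3
        assert len(iton_marginal_distribution(3, al, Ta).discontinuities()) \
            == 2

    @pytest.mark.parametrize("i", [1, 2, 3])
    def test_normalization_and_mean(self, i):
        al, Ta = 0.14, 0.25
        d = iton_marginal_distribution(i, al, Ta)
        assert d.total_mass() == pytest.approx(1.0, abs=1e-8)
        ref = expected_iton_lengths_gf(4, al, Ta)[i - 1]
        assert d.mean() == pytest.approx(ref, abs=1e-8)

    def test_density_nonnegative_on_grid(self):
        grid = np.linspace(0, 8, 10_000)
        for i in (1, 2, 3):
            d = iton_marginal_distribution(i, 0.069, 0.25)
            assert (d.pdf(grid) > -1e-9).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            iton_marginal_distribution(4, 0.1, 0.1)
        with pytest.raises(ParameterError):
            iton_marginal_distribution(1, 0.1, 0.1, n=5)


class TestBsfs:
    def test_table_size_64_at_kmax2(self):
        tab = bsfs_probabilities(0.1, 0.1, MutationModel(0.5, 2))
        assert tab.flat.size == 64

    def test_sum_to_one(self):
        tab = bsfs_probabilities(0.1, 0.1, MutationModel(0.5, 2))
        assert tab.sum() == pytest.approx(1.0, abs=1e-8)
        assert (tab.probs >= -1e-12).all()

    def test_neutral_pair_geometric_law(self):
        """The mutation convention: a neutral pair's block mutation count is
        geometric, P[k] = (1/(1+theta)) (theta/(1+theta))^k."""
        th = 0.5
        g2 = neutral_gf(make_sample(2)).collapse_to_iton()
        C = g2.taylor([1], [th / 2], [6])
        for k in range(6):
            pk = (th / 2) ** k * (-1) ** k * C[k]
            ref = (1 / (1 + th)) * (th / (1 + th)) ** k
            assert pk == pytest.approx(ref, rel=1e-12)

    def test_neutral_table_matches_sweep_table_at_infinite_alpha(self):
        mut = MutationModel(0.7, 2)
        a = neutral_bsfs_probabilities(mut)
        b = bsfs_probabilities(np.inf, 0.5, mut)
        assert np.allclose(a.probs, b.probs, atol=1e-10)

    def test_invalid_theta(self):
        with pytest.raises(ParameterError):
            MutationModel(0.0, 2)

    def test_config_code_caps(self):
        k = np.array([[0, 1, 2], [3, 7, 0], [1, 1, 1]])
        codes = BsfsTable.config_code(k, 2)
        assert codes[0] == 0 * 16 + 1 * 4 + 2
        assert codes[1] == 3 * 16 + 3 * 4 + 0
        assert codes[2] == 1 * 16 + 1 * 4 + 1

    def test_tsv_export_roundtrip_values(self, tmp_path):
        tab = bsfs_probabilities(0.2, 0.3, MutationModel(0.5, 2))
        path = tmp_path / "tab.tsv"
        tab.to_tsv(path)
        rows = path.read_text().strip().splitlines()
        assert rows[1].split("\t") == ["k1", "k2", "k3", "prob"]
        vals = [float(r.split("\t")[3]) for r in rows[2:]]
        assert len(vals) == 64
        assert sum(vals) == pytest.approx(1.0, abs=1e-8)
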