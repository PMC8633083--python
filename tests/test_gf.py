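"""The GF engine: recursion, sweep embedding, inversion, calculus."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sweepgf import (GFError, StarlikeModel, gf_with_sweep, make_sample,
                     neutral_gf)
from sweepgf.gf import MAX_FULL_GF_N, PartitionModel


def omega_zero(gf):
    return {v: 0.0 for v in gf.variables()}


class TestNeutralGF:
    def test_pairwise_gf_is_exponential_transform(self):
        # after substituting the total-time variable, phi = 1/(1+omega)
        gt = neutral_gf(make_sample(2)).collapse_time("w")
        for w in (0.0, 0.3, 1.7, 10.0):
            assert gt.evaluate({"w": w}) == pytest.approx(1 / (1 + w),
                                                          abs=1e-14)

    @pytest.mark.parametrize("n", range(1, 7))
    def test_normalization(self, n):
        gf = neutral_gf(make_sample(n))
        assert gf.evaluate(omega_zero(gf)) == pytest.approx(1.0, abs=1e-12)

    def test_tmrca_mean_n3_kingman(self):
        # classical sum_{k=2..3} 1/C(k,2) = 4/3 in 2Ne generations
        d = neutral_gf(make_sample(3)).collapse_time("w").diff("w")
        assert -d.evaluate({"w": 0.0}) == pytest.approx(4 / 3, abs=1e-12)

    @pytest.mark.parametrize("i,expected", [(1, 2.0), (2, 1.0), (3, 2 / 3)])
    def test_iton_means_n4_kingman(self, i, expected):
        gf = neutral_gf(make_sample(4)).collapse_to_iton()
        d = gf.diff(i)
        assert -d.evaluate(omega_zero(gf)) == pytest.approx(expected,
                                                            abs=1e-11)

    def test_label_permutation_symmetry(self):
        gf = neutral_gf(make_sample(4))
        vals = {"a": 0.1, "b": 0.7, "c": 0.2, "d": 0.4}
        perm = {"a": "c", "b": "d", "c": "a", "d": "b"}

        def assign(mapping):
            return {v: sum(mapping[x] for x in v) / len(v) * len(v)
                    for v in gf.variables()}

        def val(labelled):
            pt = {v: sum(labelled[x] for x in v) for v in gf.variables()}
            return gf.evaluate(pt)

        permuted = {perm[k]: v for k, v in vals.items()}
        assert val(vals) == pytest.approx(val(permuted), rel=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(GFError):
            neutral_gf([])

    def test_sample_size_cap(self):
        with pytest.raises(GFError):
            make_sample(MAX_FULL_GF_N + 1)

    def test_collapse_substitution_identity(self):
        # merged GF at omega_1=...=u equals labeled GF with every omega=u
        gf = neutral_gf(make_sample(4))
        gi = gf.collapse_to_iton()
        for u in (0.0, 0.3, 1.1):
            a = gf.evaluate({v: u for v in gf.variables()})
            b = gi.evaluate({v: u for v in gi.variables()})
            assert a == pytest.approx(b, rel=1e-12)


class TestSweepGF:
    def test_pairwise_delta_form_term_by_term(self):
        """phi*[w,delta] matches the printed four-path expression."""
        al = 0.3
        model = StarlikeModel(al)
        gs = gf_with_sweep(make_sample(2), model).collapse_time("w")
        pe = 1 - math.exp(-al)
        P = {m: math.comb(2, m) * pe ** m * (1 - pe) ** (2 - m)
             for m in range(3)}
        for w, delta in [(0.2, 0.7), (1.1, 0.05), (0.0, 2.0)]:
            ref = (1 / (1 + delta + w)
                   + delta * P[0] / (1 + delta + w)
                   + delta * P[1] / ((1 + delta + w) * (1 + w))
                   + delta * P[2] / ((1 + delta + w) * (1 + w)))
            assert gs.evaluate({"w": w}, delta=delta, model=model) == \
                pytest.approx(ref, rel=1e-12)

    def test_pairwise_inverted_matches_printed_form(self):
        """phi*[w,Ta] = e^{-Ta(1+w)}P02 + (1-e^{-Ta(1+w)}+e^{-Ta(1+w)}
        (1-P02))/(1+w)."""
        al = 0.3
        model = StarlikeModel(al)
        inv = gf_with_sweep(make_sample(2), model).collapse_time(
            "w").invert_delta()
        p0 = math.exp(-2 * al)
        for w, Ta in [(0.0, 0.5), (0.4, 0.2), (2.0, 1.5), (0.7, 0.0)]:
            e = math.exp(-Ta * (1 + w))
            ref = e * p0 + ((1 - e) + e * (1 - p0)) / (1 + w)
            assert inv.evaluate({"w": w}, Ta=Ta, model=model) == \
                pytest.approx(ref, rel=1e-12)

    def test_delta_zero_limit_is_neutral(self):
        gs = gf_with_sweep(make_sample(3), StarlikeModel(0.5))
        neut = neutral_gf(make_sample(3))
        lim = gs.limit_delta_zero()
        pt = {v: 0.2 for v in neut.variables()}
        assert lim.evaluate(pt) == pytest.approx(neut.evaluate(pt),
                                                 rel=1e-12)

    def test_large_ta_limit_is_neutral(self):
        model = StarlikeModel(0.4)
        inv = gf_with_sweep(make_sample(2), model).collapse_time(
            "w").invert_delta()
        assert inv.evaluate({"w": 0.8}, Ta=60.0, model=model) == \
            pytest.approx(1 / 1.8, rel=1e-10)

    def test_all_escape_nesting(self):
        """Pe -> 1 (every lineage escapes) equals the neutral GF at all Ta."""
        built = gf_with_sweep(make_sample(4), StarlikeModel(0.1))
        inv = built.collapse_to_iton().invert_delta()
        free = StarlikeModel(np.inf)
        neut = neutral_gf(make_sample(4)).collapse_to_iton()
        pt = {1: 0.3, 2: 0.1, 3: 0.7}
        for Ta in (0.0, 0.2, 1.0, 4.0):
            assert inv.evaluate(pt, Ta=Ta, model=free) == \
                pytest.approx(neut.evaluate(pt), rel=1e-11)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(al=st.floats(0.0, 5.0), Ta=st.floats(0.0, 4.0),
           n=st.integers(2, 5))
    def test_normalization_property(self, al, Ta, n):
        model = StarlikeModel(al)
        inv = gf_with_sweep(make_sample(n), model).collapse_to_iton(
        ).invert_delta()
        pt = {v: 0.0 for v in inv.variables()}
        assert inv.evaluate(pt, Ta=Ta, model=model) == pytest.approx(
            1.0, abs=1e-12)

    def test_invert_without_delta_rejected(self):
        with pytest.raises(GFError):
            neutral_gf(make_sample(3)).invert_delta()

    def test_bad_partition_model_rejected(self):
        class Broken(PartitionModel):
            def structures(self, lineages):
                yield ("x",), tuple(lineages)

            def weight(self, pkey):
                return 0.5      # does not sum to one

            def signature(self):
                return ("broken",)

        with pytest.raises(GFError):
            gf_with_sweep(make_sample(3), Broken())

    def test_sweep_terms_have_at_most_n_factors(self):
        gs = gf_with_sweep(make_sample(4), StarlikeModel(0.2))
        for t in gs.terms:
            assert len(t.dfs) + sum(p for *_, p in t.facs) <= 4


class TestCalculus:
    def test_taylor_matches_termwise_derivatives(self):
        model = StarlikeModel(0.25)
        inv = gf_with_sweep(make_sample(4), model).collapse_to_iton(
        ).invert_delta()
        pt = [0.1, 0.2, 0.3]
        Ta = 0.4
        C = inv.taylor([1, 2, 3], pt, [2, 2, 2], Ta=Ta, model=model)
        point = dict(zip([1, 2, 3], pt))
        d11 = inv.diff(1).diff(2).evaluate(point, Ta=Ta, model=model)
        assert d11 == pytest.approx(C[1, 1, 0], rel=1e-9)
        d201 = inv.diff(1).diff(1).diff(3).evaluate(point, Ta=Ta,
                                                    model=model)
        assert d201 == pytest.approx(C[2, 0, 1] * 2, rel=1e-9)

    def test_limit_inf_drops_branch_classes(self):
        # P(no tripleton branch) under neutrality = 1/3 (symmetric trees)
        gf = neutral_gf(make_sample(4)).collapse_to_iton()
        lim = gf.limit_inf(3)
        assert lim.evaluate({1: 0.0, 2: 0.0}) == pytest.approx(1 / 3,
                                                               abs=1e-12)

    def test_single_variable_inversion_neutral_pair(self):
        # phi = 1/(1+w) inverts to a unit-rate exponential density
        gt = neutral_gf(make_sample(2)).collapse_time("w")
        masses, comps = gt.invert_single("w", Ta=0.0)
        assert not masses
        [(tau, c, k, d)] = comps
        assert (tau, k) == (0.0, 0)
        assert c == pytest.approx(1.0) and d == pytest.approx(1.0)
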