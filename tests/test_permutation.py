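import itertools

import numpy as np
import pytest

from conftest import make_resid
from towse.permutation import (derive_rng, joint_test, make_plan,
                               permute_residuals, pvalue_tow, pvalue_vw,
                               tow_se_test, vw_tow_se_test)
from towse.residualize import ResidualizedData
from towse.tow import tow_statistic
from towse.vw import vw_min_p


class TestPermutedStatistics:
    def test_exhaustive_enumeration_includes_identity_first(self, worked_n3):
        plan = make_plan(3, exhaustive=True)
        obs, perm = permute_residuals(worked_n3, plan)
        assert perm["all"][0] == pytest.approx(obs["all"])  # identity ordering

    def test_worked_n3_multiset(self, worked_n3):
        plan = make_plan(3, exhaustive=True)
        obs, perm = permute_residuals(worked_n3, plan)
        assert obs["all"] == pytest.approx(2.0)
        assert sorted(perm["all"]) == pytest.approx([0.5, 0.5, 0.5, 0.5, 2.0, 2.0])

    def test_fixed_seed_reproduces_stream(self, rng):
        r = make_resid(rng, 12, 3)
        plan = make_plan(12, B=50, seed=99)
        _, perm1 = permute_residuals(r, plan)
        _, perm2 = permute_residuals(r, make_plan(12, B=50, seed=99))
        np.testing.assert_array_equal(perm1["all"], perm2["all"])

    def test_exhaustive_matches_brute_force_recompute(self, rng):
        # oracle: recompute T for every ordering via the statistic itself
        n = 4
        r = make_resid(rng, n, 2)
        plan = make_plan(n, exhaustive=True)
        _, perm = permute_residuals(r, plan)
        brute = []
        for p in itertools.permutations(range(n)):
            rp = ResidualizedData(y_res=r.y_res[list(p)], X_res=r.X_res)
            brute.append(tow_statistic(rp).value)
        np.testing.assert_allclose(np.sort(perm["all"]), np.sort(brute), atol=1e-12)

    def test_exhaustive_capped(self):
        with pytest.raises(ValueError, match="exhaustive"):
            make_plan(20, exhaustive=True)


class TestPvalueTow:
    def test_extreme_observed(self):
        assert pvalue_tow(5.0, np.zeros(99)) == pytest.approx(1 / 100)

    def test_zero_statistic_gives_one(self):
        assert pvalue_tow(0.0, np.abs(np.random.default_rng(0).normal(size=50))) == 1.0

    def test_worked_n3_exhaustive_p(self, worked_n3):
        plan = make_plan(3, exhaustive=True)
        obs, perm = permute_residuals(worked_n3, plan)
        assert pvalue_tow(obs["all"], perm["all"], exhaustive=True) == pytest.approx(2 / 6)

    def test_invariant_to_trait_rescaling(self, rng):
        r = make_resid(rng, 15, 4)
        p1 = tow_se_test(r, B=200, seed=5).p_value
        r2 = ResidualizedData(y_res=2.7 * r.y_res, X_res=r.X_res)
        p2 = tow_se_test(r2, B=200, seed=5).p_value
        assert p1 == p2

    def test_exhaustive_exactness_small_n(self, rng):
        # engine p-value equals enumeration over all n! orderings for n <= 5
        for n in (3, 4, 5):
            r = make_resid(rng, n, 2)
            res = tow_se_test(r, exhaustive=True)
            t_obs = tow_statistic(r).value
            brute = [tow_statistic(ResidualizedData(y_res=r.y_res[list(p)],
                                                    X_res=r.X_res)).value
                     for p in itertools.permutations(range(n))]
            expected = np.mean(np.array(brute) >= t_obs - 1e-12)
            assert res.p_value == pytest.approx(expected)


class TestPvalueVw:
    def test_corrected_never_below_raw_min(self, rng):
        for _ in range(20):
            r = make_resid(rng, 14, 5, sparse_frac=0.5)
            mafs = rng.uniform(0, 0.4, size=5)
            _, vw_res = joint_test(r, mafs, B=120,
                                   seed=int(rng.integers(2**31 - 1)))
            assert vw_res.p_value >= vw_res.diagnostics["raw_min_p"]

    def test_empty_common_equals_rare_only_tow(self, rng):
        r = make_resid(rng, 12, 3)
        mafs = np.array([0.001, 0.004, 0.008])  # everything rare
        tow_res, vw_res = joint_test(r, mafs, B=300, seed=17)
        assert vw_res.p_value == pytest.approx(tow_res.p_value)

    def test_matches_double_loop_oracle(self, rng):
        # brute force: explicit loops over permutations and lambda grid,
        # sharing the engine's permuted statistics
        r = make_resid(rng, 6, 3)
        mafs = np.array([0.002, 0.005, 0.2])
        plan = make_plan(6, B=100, seed=23)
        from towse.vw import partition_variants
        part = partition_variants(mafs)
        obs, perm = permute_residuals(r, plan, {"rare": part.rare, "common": part.common})
        p_engine, vw = pvalue_vw(obs["rare"], obs["common"],
                                 perm["rare"], perm["common"])

        grid = vw.lambda_grid
        B = plan.B

        def std(v, arr):
            return (v - arr.mean()) / arr.std(ddof=1)

        zr_b = [std(v, perm["rare"]) for v in perm["rare"]]
        zc_b = [std(v, perm["common"]) for v in perm["common"]]
        zr_o, zc_o = std(obs["rare"], perm["rare"]), std(obs["common"], perm["common"])
        min_obs = min((1 + sum(l * a + (1 - l) * b >= l * zr_o + (1 - l) * zc_o
                               for a, b in zip(zr_b, zc_b))) / (B + 1)
                      for l in grid)
        mins = []
        for bidx in range(B):
            per_lam = []
            for l in grid:
                t_b = l * zr_b[bidx] + (1 - l) * zc_b[bidx]
                per_lam.append(sum(l * a + (1 - l) * c >= t_b
                                   for a, c in zip(zr_b, zc_b)) / B)
            mins.append(min(per_lam))
        expected = (1 + sum(m <= min_obs for m in mins)) / (B + 1)
        assert vw.value == pytest.approx(min_obs)
        assert p_engine == pytest.approx(expected)


class TestCalibration:
    def test_super_uniform_under_exchangeable_null(self):
        # rejection fraction within the exact binomial 99% interval at each level
        from scipy.stats import binom

        rng = np.random.default_rng(77)
        reps, n, B = 1000, 60, 200
        pvals = np.empty(reps)
        for i in range(reps):
            r = make_resid(rng, n, 4, sparse_frac=0.3)
            pvals[i] = tow_se_test(r, B=B, seed=int(rng.integers(2**31 - 1))).p_value
        for alpha in (0.05, 0.01):
            lo = binom.ppf(0.005, reps, alpha) / reps
            hi = binom.ppf(0.995, reps, alpha) / reps
            assert lo <= (pvals <= alpha).mean() <= hi

    def test_vw_test_result_fields(self, rng):
        r = make_resid(rng, 20, 4)
        mafs = np.array([0.003, 0.006, 0.1, 0.2])
        res = vw_tow_se_test(r, mafs, B=100, seed=3, set_name="gene1")
        assert res.kind == "VW-TOW-SE" and res.set_name == "gene1"
        assert res.M_rare == 2 and res.M_common == 2
        assert 1 / 101 <= res.p_value <= 1.0


def test_derive_rng_label_independence():
    a1 = derive_rng(5, "setA").integers(0, 1000, 5)
    b = derive_rng(5, "setB").integers(0, 1000, 5)
    a2 = derive_rng(5, "setA").integers(0, 1000, 5)
    np.testing.assert_array_equal(a1, a2)
    assert not np.array_equal(a1, b)
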