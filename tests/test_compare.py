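"""Dice overlap, group t maps, FWE thresholding, RSN summaries and ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from aslrest import compare as cp
from aslrest.grids import MetricMap


def _mmap(data, mask=None, kind="fc_z"):
    data = np.asarray(data, dtype=float)
    if mask is None:
        mask = np.ones(data.shape, bool)
    return MetricMap(data, mask, kind)


class TestDice:
    def test_identity_nonempty(self):
        a = np.zeros((4, 4, 2), bool)
        a[:2] = True
        assert cp.dice(a, a) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 2), bool)
        b = np.zeros((4, 4, 2), bool)
        a[0], b[1] = True, True
        assert cp.dice(a, b) == 0.0

    def test_constructed_formula_case(self):
        a = np.zeros(12, bool)
        b = np.zeros(12, bool)
        a[:4] = True          # |a| = 4
        b[2:8] = True         # |b| = 6, |a&b| = 2
        assert cp.dice(a, b) == pytest.approx(0.4)

    def test_both_empty_defined_zero(self):
        z = np.zeros((3, 3, 3), bool)
        assert cp.dice(z, z) == 0.0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cp.dice(np.zeros((2, 2)), np.zeros((3, 3)))

    @given(st.integers(0, 2**32 - 1))
    @settings(deadline=None, max_examples=40)
    def test_symmetry_and_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((5, 5, 3)) > 0.5
        b = rng.random((5, 5, 3)) > 0.5
        assert cp.dice(a, b) == cp.dice(b, a)
        inter = a & b
        if inter.any():
            # moving one voxel out of the intersection cannot increase dice
            # while the two mask sizes are held fixed
            i = tuple(np.argwhere(inter)[0])
            b2 = b.copy()
            b2[i] = False
            outside = np.argwhere(~a & ~b)
            if len(outside):
                b2[tuple(outside[0])] = True
                assert cp.dice(a, b2) <= cp.dice(a, b)


class TestOneSampleT:
    def test_identical_constant_maps_flagged_infinite(self):
        maps = [_mmap(np.full((2, 2, 1), 3.0)) for _ in range(4)]
        res = cp.one_sample_t(maps)
        assert np.all(np.isinf(res.t_map.data))
        assert res.degenerate.all()

    def test_sign_symmetric_cohort_gives_zero_t(self, rng):
        v = rng.normal(size=(2, 2, 2))
        maps = [_mmap(v), _mmap(-v), _mmap(2 * v), _mmap(-2 * v)]
        res = cp.one_sample_t(maps, sided="two")
        assert np.allclose(res.t_map.data, 0.0, atol=1e-10)

    def test_matches_hand_computed_t(self):
        vals = np.array([1.2, 0.8, 1.5, 1.1, 0.9])
        maps = [_mmap(np.full((1, 1, 1), v)) for v in vals]
        res = cp.one_sample_t(maps)
        expected = vals.mean() / (vals.std(ddof=1) / np.sqrt(5))
        assert res.t_map.data[0, 0, 0] == pytest.approx(expected, abs=1e-12)
        assert res.df == 4

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            cp.one_sample_t([_mmap(np.zeros((1, 1, 1)))] * 2)


class TestPairedT:
    def test_identical_cohorts_give_zero(self, rng):
        maps = [_mmap(rng.normal(size=(2, 2, 1))) for _ in range(4)]
        res = cp.paired_t(maps, maps)
        assert np.allclose(res.t_map.data, 0.0, atol=1e-12)

    def test_constant_offset_sets_t_sign(self, rng):
        base = [rng.normal(size=(2, 2, 1)) for _ in range(5)]
        maps_a = [_mmap(b + 0.5) for b in base]
        maps_b = [_mmap(b) for b in base]
        res = cp.paired_t(maps_a, maps_b)
        assert np.all(res.t_map.data > 0)

    def test_reduces_to_one_sample_of_differences(self, rng):
        a = [rng.normal(size=(2, 2, 1)) for _ in range(4)]
        b = [rng.normal(size=(2, 2, 1)) for _ in range(4)]
        res = cp.paired_t([_mmap(x) for x in a], [_mmap(x) for x in b], sided="two")
        ref = cp.one_sample_t([_mmap(x - y) for x, y in zip(a, b)], sided="two")
        assert np.allclose(res.t_map.data, ref.t_map.data, atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cp.paired_t([_mmap(np.zeros((1, 1, 1)))] * 3, [_mmap(np.zeros((1, 1, 1)))] * 4)


class TestFweThreshold:
    def test_stringent_alpha_empties_mask(self, rng):
        maps = [_mmap(rng.normal(size=(4, 4, 2))) for _ in range(5)]
        res = cp.fwe_threshold(cp.one_sample_t(maps), alpha=1e-12)
        assert res.sig_mask.sum() == 0

    def test_single_voxel_reduces_to_uncorrected(self, rng):
        maps = [_mmap(rng.normal(size=(1, 1, 1))) for _ in range(6)]
        res = cp.fwe_threshold(cp.one_sample_t(maps), alpha=0.05)
        assert res.threshold == pytest.approx(stats.t.isf(0.05, 5), abs=1e-12)

    def test_unknown_method_rejected(self, rng):
        maps = [_mmap(rng.normal(size=(2, 2, 1))) for _ in range(4)]
        with pytest.raises(ValueError, match="unknown"):
            cp.fwe_threshold(cp.one_sample_t(maps), method="rft")

    def test_permutation_path_runs_and_is_seeded(self, rng):
        maps = [_mmap(rng.normal(size=(3, 3, 2)) + 2.0) for _ in range(8)]
        a = cp.fwe_threshold(cp.one_sample_t(maps), method="permutation", seed=3,
                             n_permutations=200)
        b = cp.fwe_threshold(cp.one_sample_t(maps), method="permutation", seed=3,
                             n_permutations=200)
        assert a.threshold == b.threshold
        assert a.sig_mask.sum() > 0  # strong planted mean survives

    def test_null_familywise_error_controlled(self):
        # 120 null cohorts: rate of any-significant-voxel should stay near or
        # below alpha (binomial upper bound)
        rng = np.random.default_rng(99)
        alpha, hits, n_cohorts = 0.05, 0, 120
        for _ in range(n_cohorts):
            maps = [_mmap(rng.normal(size=(6, 6, 4))) for _ in range(8)]
            res = cp.fwe_threshold(cp.one_sample_t(maps), alpha=alpha)
            hits += int(res.sig_mask.any())
        upper = alpha + 1.96 * np.sqrt(alpha * (1 - alpha) / n_cohorts)
        assert hits / n_cohorts <= upper


class TestRsnSummaries:
    def test_constant_and_single_voxel_means(self):
        const = np.full((3, 3, 2), 4.0)
        single = np.zeros((3, 3, 2))
        single[1, 1, 1] = 7.0
        masks = {"a": np.ones((3, 3, 2), bool)}
        single_mask = np.zeros((3, 3, 2), bool)
        single_mask[1, 1, 1] = True
        df = cp.extract_rsn_means(
            {("s1", "cvBOLD", "cbf"): const, ("s2", "cvBOLD", "cbf"): single},
            {"a": masks["a"], "b": single_mask})
        assert list(df.columns) == cp.SUMMARY_COLUMNS
        assert df.set_index(["subject", "rsn"]).loc[("s1", "a"), "value"] == 4.0
        assert df.set_index(["subject", "rsn"]).loc[("s2", "b"), "value"] == 7.0

    def test_planted_contrast_recovered_exactly(self):
        cbf = np.full((4, 4, 2), 40.0)
        net = np.zeros((4, 4, 2), bool)
        net[:2] = True
        cbf[net] = 60.0
        df = cp.extract_rsn_means({("s1", "cvBOLD", "cbf"): cbf},
                                  {"net": net, "rest": ~net})
        vals = df.set_index("rsn")["value"]
        assert vals["net"] == 60.0 and vals["rest"] == 40.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cp.extract_rsn_means({}, {"bad": np.zeros((2, 2, 2), bool)})


class TestAnova:
    def _summary(self, groups):
        rows = []
        for rsn, vals in groups.items():
            for i, v in enumerate(vals):
                rows.append((f"s{i}", rsn, "cvBOLD", "cbf", v))
        return pd.DataFrame(rows, columns=cp.SUMMARY_COLUMNS)

    def test_identical_groups_give_zero_f(self):
        f, df, p = cp.anova_across_rsns(self._summary({"a": [1, 2, 3], "b": [1, 2, 3]}), "cbf")
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_equal_squared_t(self, rng):
        a, b = rng.normal(size=6), rng.normal(size=6) + 1
        f, _, _ = cp.anova_across_rsns(self._summary({"a": a, "b": b}), "cbf")
        t, _ = stats.ttest_ind(a, b)
        assert f == pytest.approx(t**2, abs=1e-10)

    def test_three_group_textbook_oracle(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0], "c": [5.0, 6.0, 7.0]}
        f, df, p = cp.anova_across_rsns(self._summary(groups), "cbf")
        # hand computation of the F ratio
        all_vals = np.concatenate([np.array(v) for v in groups.values()])
        grand = all_vals.mean()
        ssb = sum(3 * (np.mean(v) - grand) ** 2 for v in groups.values())
        ssw = sum(((np.array(v) - np.mean(v)) ** 2).sum() for v in groups.values())
        expected = (ssb / 2) / (ssw / 6)
        assert f == pytest.approx(expected, abs=1e-10)
        assert df == (2, 6)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            cp.anova_across_rsns(self._summary({"a": [1.0], "b": [1.0, 2.0]}), "cbf")


class TestPairedByRsn:
    def test_bonferroni_applied_across_rsns(self, rng):
        rows = []
        for rsn in ("r0", "r1", "r2"):
            for i in range(6):
                base = rng.normal()
                rows.append((f"s{i}", rsn, "cvBOLD", "alff",
                             base + 0.01 * rng.normal() + (1.0 if rsn == "r0" else 0.0)))
                rows.append((f"s{i}", rsn, "ccBOLD", "alff", base + 0.01 * rng.normal()))
        summary = pd.DataFrame(rows, columns=cp.SUMMARY_COLUMNS)
        out = cp.paired_t_by_rsn(summary, "alff", "cvBOLD", "ccBOLD")
        assert np.allclose(out["p_bonferroni"], np.minimum(out["p"] * 3, 1.0))
        assert bool(out.set_index("rsn").loc["r0", "significant"])
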