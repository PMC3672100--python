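"""Seed-FC, ALFF, Kendall's W and ReHo against independent oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aslrest import metrics as mx
from aslrest.grids import FuncSeries
from aslrest.synth import default_affine


def _series(data, tr=0.9):
    return FuncSeries(np.asarray(data, dtype=float), np.diag([3.0, 3.0, 3.0, 1.0]), tr)


def kendalls_w_bruteforce(mat):
    """Independent oracle: the defining variance-of-rank-sums formula,
    computed with explicit loops and counting-based average ranks."""
    mat = [list(map(float, row)) for row in mat]
    k, n = len(mat), len(mat[0])
    ranks = []
    for row in mat:
        r = []
        for v in row:
            less = sum(1 for u in row if u < v)
            equal = sum(1 for u in row if u == v)
            r.append(less + (equal + 1) / 2.0)
        ranks.append(r)
    rank_sums = [sum(ranks[j][t] for j in range(k)) for t in range(n)]
    mean_r = sum(rank_sums) / n
    s = sum((r - mean_r) ** 2 for r in rank_sums)
    tie = 0.0
    for row in mat:
        for v in set(row):
            t = row.count(v)
            if t > 1:
                tie += t**3 - t
    denom = k * k * (n**3 - n) - k * tie
    return 0.0 if denom <= 0 else 12.0 * s / denom


class TestSeedVoxels:
    def test_tiny_radius_on_voxel_center_selects_exactly_that_voxel(self):
        shape = (8, 8, 8)
        affine = default_affine(shape, (3.0,) * 3)
        center = affine[:3, :3] @ [4, 4, 4] + affine[:3, 3]
        vox = mx.seed_voxels(mx.SeedSpec(tuple(center), 1.0), affine, shape,
                             np.ones(shape, bool))
        assert vox.shape == (1, 3)
        assert list(vox[0]) == [4, 4, 4]

    def test_matches_brute_force_distance_scan(self):
        shape = (12, 12, 10)
        affine = default_affine(shape, (3.0,) * 3)
        center = affine[:3, :3] @ [6, 6, 5] + affine[:3, 3]
        seed = mx.SeedSpec(tuple(center), 10.0)
        got = {tuple(v) for v in mx.seed_voxels(seed, affine, shape, np.ones(shape, bool))}
        expected = set()
        for ijk in itertools.product(range(12), range(12), range(10)):
            world = affine[:3, :3] @ ijk + affine[:3, 3]
            if np.linalg.norm(world - center) <= 10.0:
                expected.add(ijk)
        assert got == expected

    def test_empty_result_is_an_error(self):
        shape = (6, 6, 6)
        affine = default_affine(shape, (3.0,) * 3)
        mask = np.zeros(shape, bool)
        with pytest.raises(ValueError, match="no in-mask voxel"):
            mx.seed_voxels(mx.SeedSpec((0.0, -50.0, 31.0), 2.0), affine, shape, mask)


class TestFcMap:
    def test_identical_and_negated_series(self, rng):
        ts = rng.normal(size=30)
        data = np.stack([ts, -ts, np.full(30, 2.0)]).reshape(3, 1, 1, 30)
        fc = mx.fc_map(_series(data), ts, np.ones((3, 1, 1), bool))
        assert fc.data[0, 0, 0] == pytest.approx(1.0)
        assert fc.data[1, 0, 0] == pytest.approx(-1.0)
        assert fc.data[2, 0, 0] == 0.0  # constant voxel
        assert fc.flags[2, 0, 0]

    def test_constant_seed_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            mx.fc_map(_series(np.zeros((1, 1, 1, 10))), np.ones(10), np.ones((1, 1, 1), bool))


class TestFisherZ:
    def test_closed_forms(self):
        from aslrest.grids import MetricMap
        r = np.array([[[0.0, 0.5]]])
        fc = MetricMap(r, np.ones_like(r, bool), "fc_r")
        z = mx.fisher_z(fc)
        assert z.data[0, 0, 0] == 0.0
        assert z.data[0, 0, 1] == pytest.approx(np.arctanh(0.5), abs=1e-12)

    @given(st.lists(st.floats(-0.999, 0.999), min_size=1, max_size=8))
    @settings(deadline=None, max_examples=50)
    def test_odd_symmetry(self, rs):
        from aslrest.grids import MetricMap
        r = np.array(rs).reshape(1, 1, -1)
        mask = np.ones_like(r, bool)
        zp = mx.fisher_z(MetricMap(r, mask, "fc_r")).data
        zn = mx.fisher_z(MetricMap(-r, mask, "fc_r")).data
        assert np.allclose(zp, -zn, atol=1e-12)

    def test_r_beyond_one_rejected(self):
        from aslrest.grids import MetricMap
        r = np.full((1, 1, 1), 1.2)
        with pytest.raises(ValueError, match="corrupt"):
            mx.fisher_z(MetricMap(r, np.ones_like(r, bool), "fc_r"))

    def test_r_of_one_clipped_and_flagged(self):
        from aslrest.grids import MetricMap
        r = np.ones((1, 1, 1))
        z = mx.fisher_z(MetricMap(r, np.ones_like(r, bool), "fc_r"))
        assert np.isfinite(z.data[0, 0, 0])
        assert z.flags[0, 0, 0]


class TestAlff:
    def test_constant_series_zero(self):
        s = _series(np.full((2, 2, 1, 100), 9.0))
        out = mx.alff_map(s, np.ones((2, 2, 1), bool))
        assert np.allclose(out.data, 0.0, atol=1e-12)

    def test_sinusoid_closed_form(self):
        n, tr, amp = 200, 0.9, 3.7
        freqs = np.fft.rfftfreq(n, tr)
        band = (freqs >= 0.01 - 1e-12) & (freqs <= 0.08 + 1e-12) & (freqs > 0)
        f = freqs[band][3]
        t = np.arange(n) * tr
        x = amp * np.sin(2 * np.pi * f * t)
        out = mx.alff_map(_series(x.reshape(1, 1, 1, n)), np.ones((1, 1, 1), bool))
        assert out.data[0, 0, 0] == pytest.approx(amp / band.sum(), abs=1e-8)

    def test_homogeneous_scaling(self, rng):
        x = rng.normal(size=(1, 1, 1, 120))
        a = mx.alff_map(_series(x), np.ones((1, 1, 1), bool)).data
        b = mx.alff_map(_series(2.5 * x), np.ones((1, 1, 1), bool)).data
        assert np.allclose(b, 2.5 * a, atol=1e-10)

    def test_matches_direct_periodogram_oracle(self, rng):
        n, tr = 96, 0.9
        x = rng.normal(size=n)
        out = mx.alff_map(_series(x.reshape(1, 1, 1, n)), np.ones((1, 1, 1), bool)).data[0, 0, 0]
        # direct DFT evaluation, no shared code path
        xc = x - x.mean()
        freqs = [k / (n * tr) for k in range(n // 2 + 1)]
        amps = []
        for k, f in enumerate(freqs):
            if 0.01 - 1e-12 <= f <= 0.08 + 1e-12 and f > 0:
                re = sum(xc[t] * np.cos(2 * np.pi * k * t / n) for t in range(n))
                im = sum(xc[t] * np.sin(2 * np.pi * k * t / n) for t in range(n))
                amps.append(2.0 * np.sqrt(re**2 + im**2) / n)
        assert out == pytest.approx(np.mean(amps), abs=1e-10)

    def test_band_without_bins_rejected(self):
        s = _series(np.zeros((1, 1, 1, 10)), tr=0.1)
        with pytest.raises(ValueError, match="bins"):
            mx.alff_map(s, np.ones((1, 1, 1), bool), 0.01, 0.02)


class TestKendallsW:
    def test_perfect_concordance(self):
        assert mx.kendalls_w(np.tile(np.arange(6.0), (4, 1))) == 1.0

    def test_opposite_rankings_zero(self):
        assert mx.kendalls_w(np.array([[1, 2, 3], [3, 2, 1]])) == 0.0

    def test_all_constant_defined_zero(self):
        assert mx.kendalls_w(np.ones((3, 5))) == 0.0

    def test_random_integer_case_matches_bruteforce(self, rng):
        for _ in range(20):
            mat = rng.integers(0, 5, size=(3, 4)).astype(float)
            assert mx.kendalls_w(mat) == pytest.approx(kendalls_w_bruteforce(mat), abs=1e-12)

    @given(st.integers(0, 2**32 - 1))
    @settings(deadline=None, max_examples=40)
    def test_range_invariant(self, seed):
        mat = np.random.default_rng(seed).normal(size=(5, 8))
        w = mx.kendalls_w(mat)
        assert 0.0 <= w <= 1.0

    def test_invalid_shapes_rejected(self):
        with pytest.raises(ValueError):
            mx.kendalls_w(np.ones((1, 5)))
        with pytest.raises(ValueError):
            mx.kendalls_w(np.ones((3, 1)))


class TestReho:
    def test_identical_neighborhood_gives_w_one(self, rng):
        base = rng.normal(size=20)
        data = np.broadcast_to(base, (5, 5, 5, 20)).copy()
        out = mx.reho_map(_series(data), np.ones((5, 5, 5), bool), min_neighbors=13)
        assert out.data[2, 2, 2] == pytest.approx(1.0, abs=1e-12)

    def test_matches_kendalls_w_at_interior_voxel(self, rng):
        data = rng.normal(size=(5, 5, 5, 15))
        mask = np.ones((5, 5, 5), bool)
        out = mx.reho_map(_series(data), mask)
        neigh = data[1:4, 1:4, 1:4].reshape(27, 15)
        assert out.data[2, 2, 2] == pytest.approx(mx.kendalls_w(neigh), abs=1e-10)

    def test_white_noise_near_null_expectation(self, rng):
        n, k = 60, 27
        data = rng.normal(size=(7, 7, 7, n))
        out = mx.reho_map(_series(data), np.ones((7, 7, 7), bool))
        interior = out.data[2:5, 2:5, 2:5]
        null = [mx.kendalls_w(rng.normal(size=(k, n))) for _ in range(200)]
        lo, hi = np.quantile(null, [0.001, 0.999])
        assert lo * 0.5 <= interior.mean() <= hi * 2.0
        # mean of W under the null is close to 1/K for independent series
        assert abs(interior.mean() - np.mean(null)) < 3 * np.std(null)

    def test_values_in_unit_interval_and_edges_flagged(self, small_subject):
        s = small_subject
        out = mx.reho_map(s.cvbold, s.brain_mask)
        assert out.data.min() >= 0.0 and out.data.max() <= 1.0
        assert out.flags is not None and out.flags.any()  # mask-boundary voxels
        assert np.all(out.data[out.flags] == 0.0)

    def test_invalid_neighborhood_rejected(self):
        with pytest.raises(ValueError, match="neighborhood"):
            mx.reho_map(_series(np.zeros((3, 3, 3, 5))), np.ones((3, 3, 3), bool),
                        neighborhood=9)
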