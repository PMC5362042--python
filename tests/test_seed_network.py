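import numpy as np
import pytest
from scipy import stats

import mfcparc as mp
from mfcparc.connectivity import FISHER_CLIP
from mfcparc.seed_network import _one_sample_t_greater


def single_vertex_atlas(n_regions, n_seed=4):
    """n_seed unassigned seed vertices followed by one vertex per region."""
    region_of = np.concatenate([np.zeros(n_seed, int), np.arange(1, n_regions + 1)])
    return mp.RegionAtlas(
        region_of=region_of,
        region_names={i: f"r{i}" for i in range(1, n_regions + 1)},
    )


class TestRegionAverage:
    def test_single_vertex_region_returns_its_data(self):
        atlas = single_vertex_atlas(2, n_seed=1)
        data = np.arange(9.0).reshape(3, 3)
        np.testing.assert_array_equal(mp.region_average(data, atlas, 1), data[1])

    def test_two_vertex_average(self):
        atlas = mp.RegionAtlas(region_of=np.array([1, 1]), region_names={1: "r"})
        data = np.array([[1.0, 2, 3], [3.0, 2, 1]])
        np.testing.assert_array_equal(mp.region_average(data, atlas, 1), [2, 2, 2])

    def test_empty_region_rejected(self):
        atlas = single_vertex_atlas(2)
        with pytest.raises(mp.InputError):
            mp.region_average(np.zeros((6, 3)), atlas, 99)


class TestOneSampleT:
    def test_hand_computed_small_sample(self):
        # z = {0.1, 0.2, 0.3}: mean 0.2, sd 0.1 -> t = 0.2/(0.1/sqrt 3) = 3.4641
        t, p = _one_sample_t_greater(np.array([0.1, 0.2, 0.3]))
        assert t == pytest.approx(3.4641, abs=1e-4)
        assert p == pytest.approx(stats.t.sf(3.4641016, df=2), abs=1e-6)
        assert p == pytest.approx(0.0371, abs=2e-3)

    def test_negative_mean_has_right_tail_above_half(self):
        t, p = _one_sample_t_greater(np.array([-0.3, -0.1, -0.2, -0.25]))
        assert t < 0 and p > 0.5

    def test_zero_variance_limits(self):
        assert _one_sample_t_greater(np.array([0.5, 0.5, 0.5])) == (np.inf, 0.0)
        assert _one_sample_t_greater(np.array([-0.5, -0.5])) == (-np.inf, 1.0)
        assert _one_sample_t_greater(np.zeros(4)) == (0.0, 0.5)


class TestFdrBH:
    def test_step_up_by_hand(self):
        reject, adj = mp.fdr_bh([0.001, 0.02, 0.03, 0.5], alpha=0.05)
        np.testing.assert_array_equal(reject, [True, True, True, False])

    def test_all_ones_reject_nothing(self):
        reject, adj = mp.fdr_bh([1.0, 1.0, 1.0])
        assert not reject.any()
        np.testing.assert_array_equal(adj, 1.0)

    def test_single_p_is_its_own_adjustment(self):
        reject, adj = mp.fdr_bh([0.04], alpha=0.05)
        assert reject[0] and adj[0] == pytest.approx(0.04)

    def test_matches_step_up_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            m = int(rng.integers(1, 21))
            p = rng.random(m)
            reject, _ = mp.fdr_bh(p, alpha=0.05)
            np.testing.assert_array_equal(reject, _bh_oracle(p, 0.05))

    def test_out_of_range_rejected(self):
        with pytest.raises(mp.InputError):
            mp.fdr_bh([0.2, 1.2])


def _bh_oracle(p, alpha):
    """Literal step-up: largest i with p_(i) <= i/m * alpha; reject all below."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, bool)
    kmax = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i / m * alpha:
            kmax = i
    reject[order[:kmax]] = True
    return reject


class TestFmriSeedNetwork:
    def _subjects(self, build, n=6, t=40, seed=0):
        rng = np.random.default_rng(seed)
        return [
            mp.SubjectTimeSeries(build(rng), subject_id=f"s{i}") for i in range(n)
        ]

    def test_perfectly_coupled_region_is_significant(self):
        atlas = single_vertex_atlas(3, n_seed=2)

        def build(rng):
            sig = rng.standard_normal(40)
            data = rng.standard_normal((5, 40))
            data[0] = data[1] = sig  # seed vertices
            data[2] = sig  # region 1 copies the seed signal
            return data

        res = mp.fmri_seed_network(self._subjects(build), atlas, [0, 1])
        row = res.table.set_index("region_id")
        assert row.loc[1, "significant"]
        assert row.loc[1, "statistic"] == np.inf  # z pinned at the clip maximum
        assert not row.loc[3, "significant"]

    def test_anticorrelated_region_not_significant_one_sided(self):
        atlas = single_vertex_atlas(2, n_seed=1)

        def build(rng):
            sig = rng.standard_normal(40)
            noise = 0.3 * rng.standard_normal(40)
            return np.vstack([sig, -sig + noise, rng.standard_normal(40)])

        res = mp.fmri_seed_network(self._subjects(build), atlas, [0])
        row = res.table.set_index("region_id")
        assert row.loc[1, "statistic"] < 0
        assert row.loc[1, "raw_p"] > 0.5
        assert not row.loc[1, "significant"]

    def test_invariant_to_vertex_and_region_ordering(self):
        rng = np.random.default_rng(3)
        data = [rng.standard_normal((8, 30)) for _ in range(5)]
        region_of = np.array([0, 0, 1, 1, 2, 2, 3, 3])
        atlas = mp.RegionAtlas(region_of=region_of, region_names={1: "a", 2: "b", 3: "c"})
        subs = [mp.SubjectTimeSeries(d) for d in data]
        res1 = mp.fmri_seed_network(subs, atlas, [0, 1])
        perm = np.array([1, 0, 3, 2, 5, 4, 7, 6])  # permute within regions
        subs_p = [mp.SubjectTimeSeries(d[perm]) for d in data]
        res2 = mp.fmri_seed_network(subs_p, atlas, [0, 1])
        np.testing.assert_allclose(
            res1.table["statistic"], res2.table["statistic"], atol=1e-10
        )

    def test_corrected_p_at_least_raw_p(self):
        rng = np.random.default_rng(4)
        subs = [mp.SubjectTimeSeries(rng.standard_normal((10, 30))) for _ in range(6)]
        atlas = single_vertex_atlas(6, n_seed=4)
        res = mp.fmri_seed_network(subs, atlas, [0, 1, 2, 3])
        assert (res.table["corrected_p"] >= res.table["raw_p"] - 1e-15).all()


class TestThicknessSeedNetwork:
    def test_region_copying_seed_is_significant(self):
        rng = np.random.default_rng(5)
        n = 20
        seed_vals = rng.uniform(2, 4, (n, 2))
        region1 = seed_vals.mean(axis=1, keepdims=True)  # exact copy of seed average
        region2 = rng.uniform(2, 4, (n, 1))
        stack = mp.ThicknessStack(np.hstack([seed_vals, region1, region2]))
        atlas = mp.RegionAtlas(
            region_of=np.array([0, 0, 1, 2]), region_names={1: "copy", 2: "noise"}
        )
        res = mp.thickness_seed_network(stack, atlas, [0, 1])
        row = res.table.set_index("region_id")
        assert row.loc[1, "statistic"] == pytest.approx(np.arctanh(FISHER_CLIP))
        assert row.loc[1, "significant"]
        assert not row.loc[2, "significant"]

    def test_null_p_uses_fisher_standard_error(self):
        # z/SE with SE = 1/sqrt(n-3): at n = 248 and z = 0.4 the one-sided
        # p is Phi-bar(0.4 * sqrt(245)) which is far below 1e-5
        rng = np.random.default_rng(6)
        stack = mp.ThicknessStack(rng.uniform(2, 4, (248, 4)))
        atlas = mp.RegionAtlas(region_of=np.array([0, 0, 1, 1]), region_names={1: "r"})
        res = mp.thickness_seed_network(stack, atlas, [0, 1])
        z = res.table["statistic"].iloc[0]
        expected = stats.norm.sf(z * np.sqrt(248 - 3))
        assert res.table["raw_p"].iloc[0] == pytest.approx(expected, rel=1e-10)
        assert stats.norm.sf(0.4 * np.sqrt(245)) < 1e-5

    def test_null_exceedance_of_z_threshold_matches_normal_tail(self):
        # independent-noise thickness: fraction of regions with z > 0.4 at
        # n = 40 should match the Normal(0, 1/sqrt(37)) tail
        rng = np.random.default_rng(7)
        n, m = 40, 500
        data = rng.uniform(2, 4, (n, m + 2))
        stack = mp.ThicknessStack(data)
        region_of = np.concatenate([[0, 0], np.arange(1, m + 1)])
        atlas = mp.RegionAtlas(
            region_of=region_of, region_names={i: f"r{i}" for i in range(1, m + 1)}
        )
        res = mp.thickness_seed_network(stack, atlas, [0, 1], z_threshold=0.4)
        frac = res.table["significant"].mean()
        tail = stats.norm.sf(0.4 * np.sqrt(37))
        mc_se = np.sqrt(tail * (1 - tail) / m)
        assert abs(frac - tail) < 4 * mc_se + 1e-3


def test_atlas_rejects_named_region_without_vertices():
    with pytest.raises(mp.InputError):
        mp.RegionAtlas(region_of=np.array([0, 1]), region_names={1: "a", 2: "ghost"})
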