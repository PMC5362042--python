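import numpy as np
import pytest

import mfcparc as mp
from mfcparc.model_selection import KSelection, SilhouetteCurve, VICurve, mean_silhouette


def parc(labels, ids=None):
    labels = np.asarray(labels)
    return mp.Parcellation(
        labels=labels,
        k=labels.max(),
        algorithm="ward",
        seed_vertex_ids=np.arange(len(labels)) if ids is None else ids,
    )


class TestVariationOfInformation:
    def test_identical_partitions_give_zero(self):
        p = parc([1, 2, 1, 2, 2])
        assert mp.variation_of_information(p, p) == 0.0

    def test_orthogonal_two_by_two_partitions(self):
        # independent balanced partitions: H = ln 2 each, I = 0 -> VI = 2 ln 2
        p = parc([1, 1, 2, 2])
        q = parc([1, 2, 1, 2])
        assert mp.variation_of_information(p, q) == pytest.approx(2 * np.log(2))

    def test_lump_versus_singletons(self):
        p = mp.Parcellation(
            labels=np.ones(8, int), k=1, algorithm="ward",
            seed_vertex_ids=np.arange(8),
        )
        q = parc(np.arange(1, 9))
        assert mp.variation_of_information(p, q) == pytest.approx(np.log(8))

    def test_symmetry_and_label_permutation_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = parc(_relabel(rng, 30, 3))
            b = parc(_relabel(rng, 30, 4))
            vi = mp.variation_of_information(a, b)
            assert vi == pytest.approx(mp.variation_of_information(b, a))
            swapped = parc(_swap(a.labels))
            assert mp.variation_of_information(swapped, b) == pytest.approx(vi)
            assert 0 <= vi <= np.log(30) + 1e-12

    def test_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(5, 50))
            p, q, r = (parc(_relabel(rng, n, int(rng.integers(2, 5)))) for _ in range(3))
            vi = mp.variation_of_information
            assert vi(p, r) <= vi(p, q) + vi(q, r) + 1e-9

    def test_vertex_set_mismatch_rejected(self):
        p = parc([1, 2, 1, 2])
        q = parc([1, 2, 1, 2], ids=np.arange(10, 14))
        with pytest.raises(mp.InputError):
            mp.variation_of_information(p, q)


def _relabel(rng, n, k):
    """Random surjective labelling of n items onto 1..k."""
    labels = np.concatenate([np.arange(1, k + 1), rng.integers(1, k + 1, n - k)])
    return rng.permutation(labels)


def _swap(labels):
    out = labels.copy()
    mx = labels.max()
    out[labels == 1] = mx
    out[labels == mx] = 1
    from mfcparc.parcellation import canonical_labels

    return canonical_labels(out)


class TestSplitHalfVI:
    def test_identical_units_with_ward_give_exact_zero(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal((8, 30))
        mats = [
            mp.SeedCorrelationMatrix(
                z=z, seed_vertex_ids=np.arange(8),
                target_vertex_ids=8 + np.arange(30), modality="fmri",
            )
            for _ in range(8)
        ]
        curve = mp.split_half_vi(mats, [2, 3, 4], "ward", n_repeats=10, rng_seed=0)
        for samples in curve.vi_samples:
            np.testing.assert_array_equal(samples, 0.0)

    def test_strong_structure_is_stable_at_k2(self, strong_matrices):
        curve = mp.split_half_vi(strong_matrices, [2], "ward", n_repeats=20, rng_seed=0)
        assert curve.mean_vi[0] < 0.05

    def test_pure_noise_is_unstable_at_k2(self, noise_matrices):
        curve = mp.split_half_vi(noise_matrices, [2], "ward", n_repeats=20, rng_seed=0)
        assert curve.mean_vi[0] > 0.2

    def test_too_few_units_rejected(self, strong_matrices):
        with pytest.raises(mp.InputError):
            mp.split_half_vi(strong_matrices[:3], [2], "ward", n_repeats=2)


class TestSilhouette:
    def test_two_separated_tight_blobs_approach_one(self):
        rng = np.random.default_rng(3)
        x = np.vstack(
            [rng.normal(0, 0.01, (10, 3)), rng.normal(100, 0.01, (10, 3))]
        )
        labels = np.repeat([1, 2], 10)
        assert mean_silhouette(x, labels) > 0.99

    def test_all_singletons_score_zero_by_convention(self):
        x = np.random.default_rng(4).standard_normal((6, 3))
        assert mean_silhouette(x, np.arange(1, 7)) == 0.0

    def test_matches_sklearn_where_defined(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(5)
        x = rng.standard_normal((30, 4))
        labels = 1 + rng.integers(0, 3, 30)
        labels[:3] = [1, 2, 3]
        assert mean_silhouette(x, labels) == pytest.approx(
            silhouette_score(x, labels), abs=1e-10
        )

    def test_curve_shape_over_subjects(self, strong_matrices):
        curve = mp.silhouette_curve(strong_matrices[:5], [2, 3], "ward")
        assert curve.k_values == [2, 3]
        assert all(len(v) == 5 for v in curve.per_subject_values)
        assert np.all(np.abs(curve.mean_silhouette) <= 1)


class TestSelectK:
    def _curves(self, mean_sil, vi_samples):
        ks = list(range(2, 2 + len(mean_sil)))
        sil = SilhouetteCurve(
            k_values=ks, per_subject_values=[np.array([v]) for v in mean_sil]
        )
        vi = VICurve(
            k_values=ks, vi_samples=[np.asarray(s, float) for s in vi_samples],
            n_repeats=len(vi_samples[0]),
        )
        return vi, sil

    def test_strict_peak_is_selected(self):
        vi, sil = self._curves(
            [0.8, 0.5, 0.3], [[0.0] * 5, [0.1] * 5, [0.2] * 5]
        )
        assert mp.select_k(vi, sil).k == 2

    def test_exact_tie_goes_to_smallest_k(self):
        vi, sil = self._curves(
            [0.7, 0.7, 0.3], [[0.0] * 5, [0.1] * 5, [0.2] * 5]
        )
        assert mp.select_k(vi, sil).k == 2

    def test_strictly_significant_vi_growth_reports_no_plateau(self):
        rng = np.random.default_rng(6)
        samples = [rng.normal(mu, 0.01, 30) for mu in (0.2, 0.5, 0.9)]
        vi, sil = self._curves([0.8, 0.5, 0.3], samples)
        sel = mp.select_k(vi, sil)
        assert sel.vi_plateau_k is None
        assert sel.k == 2 and not sel.disagree

    def test_flat_vi_step_yields_plateau_candidate(self):
        rng = np.random.default_rng(7)
        flat = rng.normal(0.5, 0.05, 30)
        samples = [rng.normal(0.2, 0.05, 30), flat, flat + rng.normal(0, 0.05, 30)]
        vi, sil = self._curves([0.8, 0.5, 0.3], samples)
        sel = mp.select_k(vi, sil)
        assert sel.vi_plateau_k == 4
        assert sel.disagree

    def test_mismatched_curves_rejected(self):
        vi, _ = self._curves([0.5, 0.4], [[0.1] * 3, [0.2] * 3])
        _, sil = self._curves([0.5, 0.4, 0.3], [[0.1]] * 3)
        with pytest.raises(mp.InputError):
            mp.select_k(vi, sil)
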