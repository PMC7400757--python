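"""Voxel-wise ANOVA against scipy, exhaustive permutation toys, invariances."""

import numpy as np
import pytest
from scipy import stats as sstats

from eloreta_npv import (
    SubjectMapSet, f_ratio_map, permutation_correct, subject_normalize,
)


def map_set(arr, n1, kind="npv"):
    arr = np.asarray(arr, dtype=float)
    labels = ("responder",) * n1 + ("nonresponder",) * (arr.shape[0] - n1)
    return SubjectMapSet(maps=arr, labels=labels, map_kind=kind)


class TestSubjectNormalize:
    def test_mean_becomes_one(self):
        arr = np.array([[[2.0, 6.0]], [[1.0, 3.0]], [[4.0, 4.0]], [[1.0, 1.0]]])
        out = subject_normalize(map_set(arr, 2, kind="power"))
        assert np.allclose(out.maps.mean(axis=(1, 2)), 1.0)

    def test_idempotent_and_scale_removing(self):
        rng = np.random.default_rng(0)
        arr = rng.exponential(size=(4, 5, 2))
        arr[1] = 7.0 * arr[0]  # subjects differing by a global factor
        out = subject_normalize(map_set(arr, 2, kind="power"))
        assert np.allclose(out.maps[0], out.maps[1], atol=1e-12)
        again = subject_normalize(out)
        assert np.allclose(out.maps, again.maps, atol=1e-14)

    def test_npv_maps_rejected(self):
        arr = np.ones((4, 2, 1))
        with pytest.raises(ValueError, match="power"):
            subject_normalize(map_set(arr, 2, kind="npv"))

    def test_zero_map_rejected(self):
        arr = np.ones((4, 2, 1))
        arr[0] = 0.0
        with pytest.raises(ValueError, match="zero"):
            subject_normalize(map_set(arr, 2, kind="power"))


class TestFRatio:
    def test_hand_computed_anova(self):
        arr = np.array([1.0, 2, 3, 4, 5, 6]).reshape(6, 1, 1)
        sm = f_ratio_map(map_set(arr, 3))
        assert sm.F[0, 0] == pytest.approx(13.5, abs=1e-12)
        assert sm.logF[0, 0] == pytest.approx(np.log(13.5), abs=1e-12)

    def test_identical_groups_give_zero(self):
        arr = np.array([1.0, 2, 3, 1, 2, 3]).reshape(6, 1, 1)
        assert f_ratio_map(map_set(arr, 3)).F[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy_oneway_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n1, n2 = rng.integers(2, 6, size=2)
            arr = rng.normal(size=(n1 + n2, 3, 2))
            sm = f_ratio_map(map_set(arr, int(n1)))
            for v in range(3):
                for b in range(2):
                    want = sstats.f_oneway(arr[:n1, v, b], arr[n1:, v, b]).statistic
                    assert sm.F[v, b] == pytest.approx(want, rel=1e-9, abs=1e-9)

    def test_zero_within_variance_gives_inf_sentinel(self):
        arr = np.array([1.0, 1, 2, 2]).reshape(4, 1, 1)
        with pytest.warns(RuntimeWarning, match="within-group"):
            sm = f_ratio_map(map_set(arr, 2))
        assert np.isinf(sm.F[0, 0])


class TestPermutation:
    def test_exhaustive_toy_p(self):
        """Groups {1,2,3} vs {4,5,6}: only the true split and its mirror reach F=13.5."""
        arr = np.array([1.0, 2, 3, 4, 5, 6]).reshape(6, 1, 1)
        sm = permutation_correct(map_set(arr, 3), n_perm=500, seed=0)
        assert sm.exhaustive
        assert sm.n_permutations == 20
        assert sm.p_corrected[0, 0] == pytest.approx(0.1, abs=1e-12)

    def test_identical_maps_give_p_one(self):
        arr = np.tile(np.array([[1.0, 2.0]]), (6, 1))[:, None, :]
        sm = permutation_correct(map_set(arr, 3), n_perm=200, seed=0)
        assert np.all(sm.p_corrected == 1.0)

    def test_monotone_rescaling_invariance(self):
        """Per-voxel monotone rescaling shared by all subjects leaves p unchanged."""
        rng = np.random.default_rng(3)
        arr = rng.exponential(size=(10, 4, 2))
        base = permutation_correct(map_set(arr, 5), n_perm=300, seed=9)
        scaled = arr * np.array([0.1, 10.0, 3.0, 0.5])[None, :, None]
        sm2 = permutation_correct(map_set(scaled, 5), n_perm=300, seed=9)
        assert np.array_equal(base.p_corrected, sm2.p_corrected)

    def test_fixed_seed_bitwise_identical(self):
        rng = np.random.default_rng(4)
        arr = rng.normal(size=(12, 5, 2)) ** 2
        a = permutation_correct(map_set(arr, 6), n_perm=300, seed=5)
        b = permutation_correct(map_set(arr, 6), n_perm=300, seed=5)
        assert np.array_equal(a.p_corrected, b.p_corrected)
        assert a.extreme == b.extreme

    def test_correction_is_per_band(self):
        """A strong effect in one band does not alter another band's p-values."""
        rng = np.random.default_rng(6)
        null_band = rng.normal(size=(12, 6, 1)) ** 2
        arr = np.concatenate([null_band, null_band.copy()], axis=2)
        arr[:6, 0, 1] += 50.0  # plant an effect in band 1 only
        a = permutation_correct(map_set(null_band, 6), n_perm=250, seed=2)
        b = permutation_correct(map_set(arr, 6), n_perm=250, seed=2)
        assert np.array_equal(a.p_corrected[:, 0], b.p_corrected[:, 0])

    def test_extreme_tie_break_prefers_larger_F(self):
        rng = np.random.default_rng(8)
        arr = rng.normal(size=(10, 3, 1)) ** 2 * 0.01
        arr[:5, 2, 0] += 5.0   # strong effect at voxel 2
        arr[:5, 1, 0] += 3.0   # weaker effect at voxel 1
        sm = permutation_correct(map_set(arr, 5), n_perm=200, seed=1)
        assert sm.extreme[0] == 2

    def test_small_groups_rejected(self):
        arr = np.ones((3, 2, 1))
        with pytest.raises(ValueError, match="at least 2"):
            map_set(arr, 1)

    def test_log_transform_requires_positive(self):
        arr = np.zeros((6, 2, 1))
        with pytest.raises(ValueError, match="positive"):
            permutation_correct(map_set(arr, 3), n_perm=200, seed=0, log_transform=True)
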