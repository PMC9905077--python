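"""Windowing, reference normalization, downsampling, CNR, visibility grading."""

import numpy as np
import pytest

from cochlect.core import Volume3D
from cochlect import normalize
from cochlect.phantom import simulate_staining


class TestWindowing:
    def test_full_range_rescale(self):
        v = Volume3D(np.linspace(0, 255, 64).reshape(1, 8, 8), 10.0)
        out = normalize.window_to_8bit(v, 0, 100)
        assert out.data.min() == 0 and out.data.max() == 255

    def test_two_valued_volume_maps_to_extremes(self):
        d = np.full((1, 4, 4), 10.0)
        d[0, 2:] = 20.0
        out = normalize.window_to_8bit(Volume3D(d, 10.0), 0, 100)
        assert set(np.unique(out.data)) == {0, 255}

    @pytest.mark.parametrize("seed", range(20))
    def test_monotone_map_preserves_voxel_order(self, seed):
        rng = np.random.default_rng(seed)
        v = Volume3D(rng.normal(size=(4, 16, 16)), 10.0)
        out = normalize.window_to_8bit(v).data.astype(int).ravel()
        vals = v.data.ravel()
        order = np.argsort(vals)
        assert (np.diff(out[order]) >= 0).all()

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError, match="dynamic range"):
            normalize.window_to_8bit(Volume3D(np.ones((1, 8, 8)), 10.0))

    def test_bad_percentiles_rejected(self):
        v = Volume3D(np.random.default_rng(0).random((1, 8, 8)), 10.0)
        with pytest.raises(ValueError):
            normalize.window_to_8bit(v, 50, 10)


class TestReferenceNormalization:
    @staticmethod
    def _refs_and_volume(scale=1.0, noise=0.01, seed=0, target_a=200.0, target_b=40.0):
        rng = np.random.default_rng(seed)
        d = np.zeros((4, 24, 24))
        mask_a = np.zeros_like(d, bool)
        mask_b = np.zeros_like(d, bool)
        mask_a[:, :8, :] = True
        mask_b[:, 16:, :] = True
        d[mask_a] = 0.30
        d[mask_b] = 0.05
        d[:, 8:16, :] = 0.12
        d = (d + rng.normal(0, noise, d.shape)) * scale
        return Volume3D(d, 18.9), normalize.ReferencePair(mask_a, mask_b, target_a, target_b)

    def test_reference_means_hit_targets(self):
        v, refs = self._refs_and_volume()
        out = normalize.normalize_to_references(v, refs)
        ma, mb = refs.means(out)
        assert ma == pytest.approx(200.0, abs=0.5)
        assert mb == pytest.approx(40.0, abs=0.5)

    def test_fixed_point_when_already_normalized(self):
        v, refs = self._refs_and_volume()
        once = normalize.normalize_to_references(v, refs)
        twice = normalize.normalize_to_references(once, refs)
        assert np.abs(twice.data - once.data).max() <= 1.0

    def test_cross_scale_closure(self):
        # the same object scanned on two days at grey scales 0.7 and 1.3
        # lands on identical means after normalization (affine closure)
        va, refs_a = self._refs_and_volume(scale=0.7, seed=1)
        vb, refs_b = self._refs_and_volume(scale=1.3, seed=1)
        na = normalize.normalize_to_references(va, refs_a)
        nb = normalize.normalize_to_references(vb, refs_b)
        assert na.data.mean() == pytest.approx(nb.data.mean(), abs=2.0)

    def test_degenerate_references_rejected(self):
        v, refs = self._refs_and_volume(noise=0.0)
        v.data[refs.mask_b] = 0.30  # same mean as A
        with pytest.raises(ValueError, match="degenerate"):
            normalize.normalize_to_references(v, refs)

    def test_order_preserved_when_targets_ordered_like_means(self):
        v, refs = self._refs_and_volume()
        out = normalize.normalize_to_references(v, refs)
        ma, mb = refs.means(v)
        assert (ma > mb) == (refs.target_a > refs.target_b)
        assert out.meta["normalization"]["gain"] > 0


class TestDownsample:
    def test_factor_three_scales_voxel_size(self):
        v = Volume3D(np.random.default_rng(0).random((6, 6, 6)).astype(np.float32), 6.3)
        out = normalize.downsample(v, 3)
        assert out.voxel_size_um == pytest.approx(18.9)
        assert out.shape == (2, 2, 2)

    def test_factor_one_is_identity(self):
        v = Volume3D(np.random.default_rng(1).random((4, 4, 4)), 6.3)
        assert np.array_equal(normalize.downsample(v, 1).data, v.data)

    def test_block_mean_conserves_global_mean(self):
        v = Volume3D(np.random.default_rng(2).random((8, 8, 8)), 6.3)
        out = normalize.downsample(v, 2)
        assert out.data.mean() == pytest.approx(v.data.mean(), rel=1e-6)

    def test_non_multiple_grid_cropped_with_warning(self):
        v = Volume3D(np.random.default_rng(3).random((7, 7, 7)), 6.3)
        with pytest.warns(UserWarning, match="cropping"):
            out = normalize.downsample(v, 2)
        assert out.shape == (3, 3, 3)

    def test_bad_factor_rejected(self):
        v = Volume3D(np.ones((4, 4, 4)), 6.3)
        with pytest.raises(ValueError):
            normalize.downsample(v, 0)


class TestReferenceContrast:
    @staticmethod
    def _noisy(sd, seed=5):
        return TestReferenceNormalization._refs_and_volume(noise=sd, seed=seed)

    def test_zero_noise_is_degenerate(self):
        v, refs = self._noisy(0.0)
        with pytest.raises(ValueError, match="zero pooled"):
            normalize.reference_contrast(v, refs)

    def test_cnr_matches_closed_form(self):
        sd = 0.02
        v, refs = self._noisy(sd)
        cnr = normalize.reference_contrast(v, refs)
        assert cnr == pytest.approx(0.25 / sd, rel=0.1)

    def test_doubling_noise_halves_cnr(self):
        c1 = normalize.reference_contrast(*self._noisy(0.01)[::1])
        c2 = normalize.reference_contrast(*self._noisy(0.02))
        assert c2 == pytest.approx(c1 / 2, rel=0.1)


class TestVisibilityGrading:
    # grading is statistical (noise vs sector occupancy), so it runs at the
    # desk working resolution rather than on the coarse fast phantom
    @pytest.fixture(scope="class")
    @staticmethod
    def graded_phantom(desk_phantom, desk_frame, desk_reference):
        return desk_phantom, desk_frame, desk_reference

    @staticmethod
    def _grades(ph, frame, ref, t_h):
        grey, _ = simulate_staining(ph, t_h)
        thr = 3 * ph.spec.texture_sd
        return normalize.grade_visibility(grey, ph.labels, frame, thr, ref)

    def test_fully_stained_grades_three_everywhere(self, graded_phantom):
        grades = self._grades(*graded_phantom, 72.0)
        assert all(g.grade == 3 for g in grades)

    def test_unstained_grades_zero_everywhere(self, graded_phantom):
        grades = self._grades(*graded_phantom, 0.0)
        assert all(g.grade == 0 for g in grades)

    def test_front_parked_mid_second_turn(self, graded_phantom):
        # 36 h at 1 turn/day puts the front at 540°: turn 1 fully stained,
        # turn 3 still invisible
        grades = self._grades(*graded_phantom, 36.0)
        by = {(g.structure, g.turn): g.grade for g in grades}
        assert all(by[(s, 1)] == 3 for s in ("bm", "sl", "rm", "cpb_ooc"))
        assert all(by[(s, 3)] == 0 for s in ("bm", "sl", "rm", "cpb_ooc"))

    def test_grades_non_decreasing_in_time(self, graded_phantom):
        times = (0.0, 12.0, 24.0, 48.0, 72.0)
        history = [self._grades(*graded_phantom, t) for t in times]
        for earlier, later in zip(history, history[1:]):
            for ge, gl in zip(earlier, later):
                assert gl.grade >= ge.grade

    def test_grades_recomputable_from_slice_fractions(self, graded_phantom):
        grades = self._grades(*graded_phantom, 36.0)
        assert all(g.consistent() for g in grades)

    def test_missing_structure_rejected(self, graded_phantom):
        ph, frame, ref = graded_phantom
        with pytest.raises(ValueError, match="absent"):
            normalize.grade_visibility(
                ph.grey, ph.labels, frame, 0.01, ref, structures=("bm", "nonexistent")
            )
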