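import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msdiffusion import core_shell_split, label_components, mirror_nawm
from msdiffusion.roi import lr_flip, roi_table


def _cube(shape, lo, size):
    m = np.zeros(shape, dtype=bool)
    sl = tuple(slice(l, l + s) for l, s in zip(lo, size))
    m[sl] = True
    return m


class TestLabelComponents:
    def test_corner_adjacency_merges_under_26(self):
        m = np.zeros((4, 4, 4), dtype=bool)
        m[0, 0, 0] = m[1, 1, 1] = True  # share only a corner
        assert label_components(m, connectivity=26).n_rois == 1
        assert label_components(m, connectivity=6).n_rois == 2

    def test_sorted_by_descending_size(self):
        m = _cube((10, 10, 10), (0, 0, 0), (3, 3, 3))
        m[8, 8, 8] = True
        lab = label_components(m, connectivity=26)
        assert lab.n_rois == 2
        assert list(lab.sizes) == [27, 1]
        assert lab.labels[1, 1, 1] == 1  # the cube is ROI 1
        assert lab.labels[8, 8, 8] == 2

    def test_empty_mask_yields_zero_rois(self):
        lab = label_components(np.zeros((5, 5, 5), dtype=bool))
        assert lab.n_rois == 0

    def test_relabeling_foreground_is_idempotent(self):
        rng = np.random.default_rng(0)
        m = rng.random((12, 12, 12)) > 0.8
        lab1 = label_components(m)
        lab2 = label_components(lab1.labels > 0)
        np.testing.assert_array_equal(lab1.labels, lab2.labels)

    def test_size_tie_broken_by_min_zyx(self):
        m = np.zeros((6, 6, 6), dtype=bool)
        m[5, 5, 5] = True  # equal sizes; lower (z,y,x) must get id 1
        m[0, 0, 0] = True
        lab = label_components(m)
        assert lab.labels[0, 0, 0] == 1
        assert lab.labels[5, 5, 5] == 2


class TestMirrorNAWM:
    def test_symmetric_phantom_maps_to_exact_mirror(self):
        shape = (10, 6, 6)
        wm = np.ones(shape, dtype=bool)
        lesion = _cube(shape, (1, 2, 2), (2, 2, 2))
        lab = label_components(lesion)
        pairs = mirror_nawm(lab, wm)
        assert len(pairs) == 1 and pairs[0].valid
        np.testing.assert_array_equal(pairs[0].nawm_mask, lesion[::-1])
        assert not np.any(pairs[0].nawm_mask & lesion)

    def test_mirror_covered_by_other_lesion_invalidates_pair(self):
        shape = (10, 6, 6)
        wm = np.ones(shape, dtype=bool)
        lesion = _cube(shape, (1, 2, 2), (2, 2, 2))
        other = lesion[::-1].copy()  # second lesion exactly on the mirror site
        lab = label_components(lesion | other)
        pairs = mirror_nawm(lab, wm)
        assert len(pairs) == 2
        assert not any(p.valid for p in pairs)

    def test_partial_overlap_removes_only_overlapping_voxels(self):
        shape = (10, 6, 6)
        wm = np.ones(shape, dtype=bool)
        lesion = _cube(shape, (1, 2, 2), (2, 2, 2))
        blocker = _cube(shape, (7, 2, 2), (1, 1, 1))  # covers 1 mirrored voxel
        lab = label_components(lesion | blocker)
        pairs = mirror_nawm(lab, wm, min_retention=0.5)
        big = next(p for p in pairs if p.lesion_mask.sum() == 8)
        assert big.valid
        assert big.nawm_mask.sum() == 8 - 1
        assert not np.any(big.nawm_mask & blocker)

    def test_retention_threshold_drops_poor_matches(self):
        shape = (10, 6, 6)
        wm = np.ones(shape, dtype=bool)
        lesion = _cube(shape, (1, 2, 2), (2, 2, 2))
        blocker = _cube(shape, (7, 2, 2), (1, 2, 2))  # covers half the mirror
        lab = label_components(lesion | blocker)
        big = next(
            p
            for p in mirror_nawm(lab, wm, min_retention=0.6)
            if p.lesion_mask.sum() == 8
        )
        assert not big.valid

    def test_non_involutive_transform_rejected(self):
        lab = label_components(_cube((6, 6, 6), (0, 2, 2), (2, 2, 2)))
        wm = np.ones((6, 6, 6), dtype=bool)
        with pytest.raises(ValueError, match="involution"):
            mirror_nawm(lab, wm, flip_transform=lambda m: np.roll(m, 1, axis=0))

    def test_double_flip_restores_lesion_voxels(self):
        lesion = _cube((10, 6, 6), (1, 2, 2), (3, 2, 2))
        np.testing.assert_array_equal(lr_flip(lr_flip(lesion)), lesion)


class TestCoreShell:
    @pytest.mark.parametrize(
        "size,expected_core,expected_shell",
        [((3, 3, 3), 1, 26), ((5, 5, 5), 27, 98)],
    )
    def test_cube_erosion_counts(self, size, expected_core, expected_shell):
        m = _cube((9, 9, 9), (2, 2, 2), size)
        cs = core_shell_split(m)
        assert cs is not None
        assert cs.core_mask.sum() == expected_core
        assert cs.shell_mask.sum() == expected_shell

    def test_thin_slab_is_ineligible(self):
        assert core_shell_split(_cube((9, 9, 9), (2, 2, 2), (2, 5, 5))) is None

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError):
            core_shell_split(np.zeros((4, 4, 4), dtype=bool))

    def test_edge_touching_lesion_loses_border_to_shell(self):
        m = _cube((4, 9, 9), (0, 2, 2), (4, 5, 5))  # touches x = 0 face
        cs = core_shell_split(m)
        assert cs is not None
        assert not cs.core_mask[0].any()

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_partition_invariant_on_random_blobs(self, seed):
        """core + shell partitions every eligible lesion exactly."""
        rng = np.random.default_rng(seed)
        m = rng.random((10, 10, 10)) > 0.35
        cs = core_shell_split(m | _cube((10, 10, 10), (3, 3, 3), (3, 3, 3)))
        if cs is None:
            return
        lesion = m | _cube((10, 10, 10), (3, 3, 3), (3, 3, 3))
        assert not np.any(cs.core_mask & cs.shell_mask)
        np.testing.assert_array_equal(cs.core_mask | cs.shell_mask, lesion)
        # every shell voxel touches the exterior within its 26-neighborhood
        from scipy.ndimage import binary_dilation

        # out-of-grid counts as exterior, matching the erosion convention
        exterior_touch = binary_dilation(
            ~lesion, structure=np.ones((3, 3, 3)), border_value=1
        )
        assert np.all(exterior_touch[cs.shell_mask])


def test_roi_table_reports_sizes_pairs_and_cores():
    shape = (12, 8, 8)
    wm = np.ones(shape, dtype=bool)
    lesion = _cube(shape, (1, 2, 2), (3, 3, 3))
    lab = label_components(lesion, voxel_size=(2.0, 2.0, 2.0))
    pairs = mirror_nawm(lab, wm)
    cores = {1: core_shell_split(lab.mask(1), 1)}
    df = roi_table(lab, pairs, cores)
    row = df.iloc[0]
    assert row["size_voxels"] == 27
    assert row["volume_mm3"] == 27 * 8.0
    assert bool(row["pair_valid"]) and bool(row["core_eligible"])
    assert row["core_voxels"] + row["shell_voxels"] == 27
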