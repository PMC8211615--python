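import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nvcvis import phantom, preprocess
from nvcvis.segmentation import (
    GrowParams,
    assemble_labels,
    bright_peak_window,
    import_nerve_labels,
    segment_brainstem,
    volume_grow,
    window_around_seed,
)
from nvcvis.volumes_io import (
    BRAINSTEM,
    CSF_VESSEL,
    NERVE,
    REST,
    BoundingBox,
    LabelVolume,
    Volume,
    write_labels,
)


def _bfs_oracle(data, seeds, lower, upper, connectivity, bbox=None, barrier=None):
    """Exhaustive flood fill, one voxel at a time."""
    if connectivity == 6:
        offs = [d for d in itertools.product((-1, 0, 1), repeat=3)
                if sum(map(abs, d)) == 1]
    else:
        offs = [d for d in itertools.product((-1, 0, 1), repeat=3)
                if any(d)]
    ok = (data >= lower) & (data <= upper)
    if bbox is not None:
        ok &= bbox.mask(data.shape)
    if barrier is not None:
        ok &= ~barrier
    mask = np.zeros_like(ok)
    stack = [tuple(s) for s in seeds]
    while stack:
        v = stack.pop()
        if mask[v] or not ok[v]:
            continue
        mask[v] = True
        for d in offs:
            n = tuple(np.add(v, d))
            if all(0 <= c < s for c, s in zip(n, data.shape)) and not mask[n]:
                stack.append(n)
    return mask


class TestVolumeGrow:
    def test_uniform_volume_whole_grid(self):
        data = np.full((5, 5, 5), 10.0)
        mask = volume_grow(data, GrowParams([(2, 2, 2)], 5, 15))
        assert mask.all()

    def test_hand_built_cross_6conn(self):
        data = np.zeros((3, 3, 3))
        cross = [(1, 1, 1), (0, 1, 1), (2, 1, 1), (1, 0, 1), (1, 2, 1),
                 (1, 1, 0), (1, 1, 2)]
        for c in cross:
            data[c] = 1.0
        mask = volume_grow(data, GrowParams([(1, 1, 1)], 0.5, 1.5, connectivity=6))
        expect = np.zeros((3, 3, 3), bool)
        for c in cross:
            expect[c] = True
        np.testing.assert_array_equal(mask, expect)

    def test_bbox_clips_to_seed_side(self):
        data = np.zeros((3, 3, 3))
        data[:, 1, 1] = 1.0
        bbox = BoundingBox((0, 0, 0), (1, 2, 2))
        mask = volume_grow(
            data, GrowParams([(0, 1, 1)], 0.5, 1.5, bbox=bbox, connectivity=6)
        )
        expect = _bfs_oracle(data, [(0, 1, 1)], 0.5, 1.5, 6, bbox=bbox)
        np.testing.assert_array_equal(mask, expect)
        assert not mask[2, 1, 1]

    def test_seed_outside_window_names_seed(self):
        data = np.zeros((3, 3, 3))
        with pytest.raises(ValueError, match=r"seed \(1, 1, 1\)"):
            volume_grow(data, GrowParams([(1, 1, 1)], 5, 6))

    def test_empty_seed_list(self):
        with pytest.raises(ValueError, match="empty seed"):
            volume_grow(np.zeros((3, 3, 3)), GrowParams([], 0, 1))

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            GrowParams([(0, 0, 0)], 5, 4)

    @settings(max_examples=60, deadline=None)
    @given(
        shape=st.tuples(*[st.integers(2, 4)] * 3),
        conn=st.sampled_from([6, 26]),
        data=st.data(),
    )
    def test_matches_bfs_oracle_small(self, shape, conn, data):
        vals = data.draw(
            st.lists(
                st.integers(0, 3),
                min_size=int(np.prod(shape)),
                max_size=int(np.prod(shape)),
            )
        )
        arr = np.array(vals, float).reshape(shape)
        in_window = np.argwhere((arr >= 1) & (arr <= 2))
        if len(in_window) == 0:
            return
        seed = tuple(in_window[data.draw(st.integers(0, len(in_window) - 1))])
        mask = volume_grow(arr, GrowParams([seed], 1, 2, connectivity=conn))
        expect = _bfs_oracle(arr, [seed], 1, 2, conn)
        np.testing.assert_array_equal(mask, expect)


class TestAssembleLabels:
    def _like(self, shape):
        return Volume.from_spacing(np.zeros(shape), 0.4)

    def test_priority_nerve_wins(self):
        shape = (3, 3, 3)
        full = np.ones(shape, bool)
        lv = assemble_labels(full, full, full, self._like(shape))
        assert (lv.labels == NERVE).all()

    def test_nothing_is_rest(self):
        shape = (3, 3, 3)
        empty = np.zeros(shape, bool)
        lv = assemble_labels(empty, empty, empty, self._like(shape))
        assert (lv.labels == REST).all()

    def test_matches_per_voxel_oracle(self, rng):
        shape = (5, 5, 5)
        csf = rng.random(shape) < 0.4
        bs = rng.random(shape) < 0.4
        nerve = rng.random(shape) < 0.2
        lv = assemble_labels(csf, bs, nerve, self._like(shape))
        for idx in np.ndindex(shape):
            if nerve[idx]:
                expect = NERVE
            elif csf[idx]:
                expect = CSF_VESSEL
            elif bs[idx]:
                expect = BRAINSTEM
            else:
                expect = REST
            assert lv.labels[idx] == expect

    def test_partition_and_counts(self, rng):
        shape = (6, 6, 6)
        csf = rng.random(shape) < 0.5
        bs = rng.random(shape) < 0.5
        nerve = rng.random(shape) < 0.3
        lv = assemble_labels(csf, bs, nerve, self._like(shape))
        assert (lv.labels == NERVE).sum() == nerve.sum()
        assert (lv.labels == CSF_VESSEL).sum() == (csf & ~nerve).sum()
        assert (lv.labels == BRAINSTEM).sum() == (bs & ~csf & ~nerve).sum()


class TestSegmentBrainstem:
    def test_phantom_dice(self, small_spec, small_phantom):
        ciss, _, truth = small_phantom
        diffused = preprocess.anisotropic_diffusion(ciss, iterations=4)
        closed = preprocess.grey_closing(diffused, radius=3)
        from scipy import ndimage

        lo, hi = bright_peak_window(closed, nsigma=3.0)

        def interior_seed(mask):
            dist = ndimage.distance_transform_edt(mask)
            return tuple(int(c) for c in np.unravel_index(np.argmax(dist), dist.shape))

        csf_seed = interior_seed(truth.masks["csf"])
        csf = volume_grow(closed, GrowParams([csf_seed], lo, hi, connectivity=26))
        bs_seed = interior_seed(truth.masks["brainstem"])
        blo, bhi = window_around_seed(diffused, bs_seed, nsigma=4.0)
        bs = segment_brainstem(
            diffused, csf, GrowParams([bs_seed], blo, bhi, connectivity=6)
        )
        truth_bs = truth.masks["brainstem"]
        dice = 2 * (bs & truth_bs).sum() / (bs.sum() + truth_bs.sum())
        assert dice >= 0.90

    def test_full_csf_blocks_everything(self):
        data = np.full((4, 4, 4), 10.0)
        csf = np.ones((4, 4, 4), bool)
        with pytest.raises(ValueError, match="seed"):
            segment_brainstem(data, csf, GrowParams([(1, 1, 1)], 0, 20))

    def test_barrier_removal_is_monotone(self, rng):
        data = rng.integers(0, 3, (5, 5, 5)).astype(float)
        data[2, 2, 2] = 1.0
        barrier = rng.random((5, 5, 5)) < 0.3
        barrier[2, 2, 2] = False
        p = GrowParams([(2, 2, 2)], 1, 2, connectivity=6)
        with_barrier = volume_grow(data, p, barrier=barrier)
        without = volume_grow(data, p)
        assert (without | with_barrier == without).all()
        assert with_barrier.sum() <= without.sum()


class TestImportNerveLabels:
    def test_round_trip(self, tmp_path, small_phantom):
        ciss, _, truth = small_phantom
        mask = truth.masks["nerve"]
        lv = LabelVolume(
            mask.astype(np.int16), {0: "REST", 1: "NERVE"}, ciss.spacing, ciss.affine
        )
        write_labels(lv, tmp_path / "nerve.nii.gz")
        back = import_nerve_labels(tmp_path / "nerve.nii.gz", ciss)
        np.testing.assert_array_equal(back, mask)

    def test_grid_mismatch(self, tmp_path, small_phantom):
        ciss, _, _ = small_phantom
        lv = LabelVolume(
            np.zeros((8, 8, 8), np.int16), {0: "REST"}, (1,) * 3, np.eye(4)
        )
        write_labels(lv, tmp_path / "bad.nii.gz")
        with pytest.raises(ValueError, match="mismatch"):
            import_nerve_labels(tmp_path / "bad.nii.gz", ciss)

    def test_empty_mask_warns(self, tmp_path, small_phantom):
        ciss, _, _ = small_phantom
        lv = LabelVolume(
            np.zeros(ciss.shape, np.int16), {0: "REST"}, ciss.spacing, ciss.affine
        )
        write_labels(lv, tmp_path / "empty.nii.gz")
        with pytest.warns(UserWarning, match="empty"):
            mask = import_nerve_labels(tmp_path / "empty.nii.gz", ciss)
        assert not mask.any()
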