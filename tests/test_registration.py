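import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from nvcvis import phantom
from nvcvis.registration import (
    MIOptions,
    RigidTransform,
    landmark_rigid,
    mutual_information,
    reformat,
    register,
)
from nvcvis.volumes_io import Volume


def _entropy_bits(p):
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


class TestRigidTransform:
    def test_orthonormality_enforced(self):
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))

    def test_reflection_rejected(self):
        with pytest.raises(ValueError, match="proper"):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_params_round_trip(self):
        c = np.array([3.0, -2.0, 5.0])
        T = RigidTransform.from_params([4.0, -6.0, 3.0], [1.0, 2.0, -0.5], c)
        rv, sh = T.params(c)
        np.testing.assert_allclose(rv, [4.0, -6.0, 3.0], atol=1e-9)
        np.testing.assert_allclose(sh, [1.0, 2.0, -0.5], atol=1e-9)

    def test_inverse_compose_identity(self, rng):
        T = RigidTransform.from_params(rng.uniform(-20, 20, 3), rng.uniform(-5, 5, 3))
        I = T.compose(T.inverse())
        np.testing.assert_allclose(I.matrix, np.eye(4), atol=1e-9)


class TestLandmarkRigid:
    def test_identity_on_identical_sets(self, rng):
        pts = rng.uniform(-10, 10, (5, 3))
        T = landmark_rigid(pts, pts)
        np.testing.assert_allclose(T.matrix, np.eye(4), atol=1e-9)

    def test_exact_recovery_30deg_z(self, rng):
        moving = rng.uniform(-10, 10, (6, 3))
        R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        t = np.array([1.0, 2.0, 3.0])
        fixed = moving @ R.T + t
        T = landmark_rigid(fixed, moving)
        np.testing.assert_allclose(T.rotation, R, atol=1e-9)
        np.testing.assert_allclose(T.translation, t, atol=1e-9)
        np.testing.assert_allclose(T.apply(moving), fixed, atol=1e-9)

    def test_reflection_gets_proper_rotation(self):
        moving = np.array(
            [[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 0], [0, 1, 1]], float
        )
        fixed = moving.copy()
        fixed[:, 2] *= -1  # pure reflection correspondence
        T = landmark_rigid(fixed, moving)
        assert np.linalg.det(T.rotation) == pytest.approx(1.0)
        residual = np.linalg.norm(T.apply(moving) - fixed)
        assert residual > 0.1

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="3 landmark"):
            landmark_rigid(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_rejected(self):
        line = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2], [3, 3, 3]], float)
        with pytest.raises(ValueError, match="degenerate landmark"):
            landmark_rigid(line, line)


class TestMutualInformation:
    def test_self_mi_equals_marginal_entropy(self, rng):
        data = rng.integers(0, 8, (16, 16, 16)).astype(float)
        v = Volume.from_spacing(data, 1.0)
        opt = MIOptions(bins=8, sampling=1.0)
        mi = mutual_information(v, v, RigidTransform.identity(), opt)
        hist, _ = np.histogram(data, bins=8, range=(data.min(), data.max()))
        h = _entropy_bits(hist / hist.sum())
        assert mi == pytest.approx(h, abs=1e-9)

    def test_two_valued_hand_computation(self):
        # joint histogram: fixed 0/1 vs moving 0/1 fully correlated -> MI = 1 bit
        data = np.zeros((4, 4, 4))
        data[:2] = 1.0
        v = Volume.from_spacing(data, 1.0)
        opt = MIOptions(bins=8, sampling=1.0)
        mi = mutual_information(v, v, RigidTransform.identity(), opt)
        assert mi == pytest.approx(1.0, abs=1e-9)

    def test_anticorrelated_two_valued(self):
        # moving = 1 - fixed: deterministic relation, MI still 1 bit
        data = np.zeros((4, 4, 4))
        data[:2] = 1.0
        f = Volume.from_spacing(data, 1.0)
        m = Volume.from_spacing(1.0 - data, 1.0)
        opt = MIOptions(bins=8, sampling=1.0)
        mi = mutual_information(f, m, RigidTransform.identity(), opt)
        assert mi == pytest.approx(1.0, abs=1e-9)

    def test_independent_volumes_near_zero(self, rng):
        a = Volume.from_spacing(rng.random((24, 24, 24)), 1.0)
        b = Volume.from_spacing(rng.random((24, 24, 24)), 1.0)
        opt = MIOptions(bins=8, sampling=1.0)
        mi = mutual_information(a, b, RigidTransform.identity(), opt)
        assert 0.0 <= mi < 0.02

    def test_symmetry_under_inverse(self, rng):
        a = Volume.from_spacing(rng.random((12, 12, 12)), 1.0)
        b = Volume.from_spacing(rng.random((12, 12, 12)) + a.data, 1.0)
        T = RigidTransform.identity()
        opt = MIOptions(bins=8, sampling=1.0)
        assert mutual_information(a, b, T, opt) == pytest.approx(
            mutual_information(b, a, T.inverse(), opt), abs=0.05
        )

    def test_empty_overlap_raises(self):
        v = Volume.from_spacing(np.ones((8, 8, 8)), 1.0)
        far = RigidTransform(np.eye(3), np.array([1000.0, 0.0, 0.0]))
        with pytest.raises(ValueError, match="overlap"):
            mutual_information(v, v, far, MIOptions(bins=8))

    def test_non_negative(self, rng):
        a = Volume.from_spacing(rng.random((10, 10, 10)), 1.0)
        b = Volume.from_spacing(rng.random((10, 10, 10)), 1.0)
        for _ in range(3):
            T = RigidTransform.from_params(rng.uniform(-5, 5, 3), rng.uniform(-2, 2, 3))
            assert mutual_information(a, b, T, MIOptions(bins=8)) >= 0.0


class TestReformat:
    def test_identity_same_grid(self, rng):
        v = Volume.from_spacing(rng.random((8, 8, 8)), 1.0)
        out = reformat(v, v, RigidTransform.identity())
        np.testing.assert_allclose(out.data, v.data, atol=1e-12)

    def test_half_voxel_shift_of_ramp(self):
        # trilinear interpolation is exact on affine intensity functions
        n = 10
        i = np.arange(n, dtype=float)
        data = np.broadcast_to(i[:, None, None], (n, n, n)).copy()
        v = Volume.from_spacing(data, 1.0)
        T = RigidTransform(np.eye(3), np.array([0.5, 0.0, 0.0]))
        out = reformat(v, v, T)
        interior = out.data[1:-1, :, :]
        expect = data[1:-1, :, :] - 0.5
        np.testing.assert_allclose(interior, expect, atol=1e-9)

    def test_output_dims_follow_fixed(self, rng):
        moving = Volume.from_spacing(rng.random((8, 8, 8)), 1.0)
        fixed = Volume.from_spacing(np.zeros((12, 10, 9)), 0.7)
        T = RigidTransform.from_params([3.0, 0.0, 0.0], [1.0, 0.0, 0.0])
        out = reformat(moving, fixed, T)
        assert out.shape == fixed.shape
        np.testing.assert_allclose(out.affine, fixed.affine)


@pytest.fixture(scope="module")
def offset_phantom():
    spec = phantom.PhantomSpec(
        shape=(64, 64, 64),
        seed=11,
        tof_rot_deg=(3.0, -2.0, 4.0),
        tof_shift_mm=(1.5, -1.0, 0.8),
    )
    return phantom.generate(spec)


class TestRegister:
    def test_recovers_truth(self, offset_phantom):
        ciss, tof, truth = offset_phantom
        opt = MIOptions(bins=48, pyramid_levels=3, sampling=0.5, seed=0)
        res = register(ciss, tof, None, opt)
        err = res.transform.compose(truth.true_rigid.inverse())
        c = ciss.world_center()
        trans_err = np.linalg.norm(
            res.transform.apply(c) - truth.true_rigid.apply(c)
        )
        assert err.rotation_angle_deg() < 1.0
        assert trans_err < 0.4  # one voxel at 64^3 desk scale
        assert res.mi >= res.mi_init

    def test_init_at_truth_stays_near_truth(self, offset_phantom):
        ciss, tof, truth = offset_phantom
        opt = MIOptions(
            bins=48, pyramid_levels=1, sampling=0.5, seed=0, grid_span_deg=0.0
        )
        res = register(ciss, tof, truth.true_rigid, opt)
        assert res.mi >= res.mi_init - 1e-9
        err = res.transform.compose(truth.true_rigid.inverse())
        assert err.rotation_angle_deg() < 1.0

    def test_self_registration_identity(self):
        spec = phantom.PhantomSpec(shape=(48, 48, 48), seed=5)
        ciss, _, _ = phantom.generate(spec)
        opt = MIOptions(bins=32, pyramid_levels=2, sampling=1.0, seed=0,
                        grid_span_deg=4.0)
        res = register(ciss, ciss, None, opt)
        assert res.transform.rotation_angle_deg() < 0.5
        assert np.linalg.norm(res.transform.translation) < 0.2
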