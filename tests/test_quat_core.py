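import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from quatdba.quat_core import (
    EULER_ORDERS,
    EulerAngles,
    canonical_sign,
    cost_dot,
    dist_geodesic,
    dist_rotangle,
    dist_tangent,
    euler_to_quat,
    markley_average,
    normalize,
    quat_log,
    quat_mul,
    quat_to_euler,
)
from conftest import random_unit_quats

IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])
ROT90X = np.array([np.cos(np.pi / 4), np.sin(np.pi / 4), 0.0, 0.0])

ALL_DISTANCES = [cost_dot, dist_geodesic, dist_tangent, dist_rotangle]


class TestDistances:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            (IDENTITY, IDENTITY, 0.0),
            (IDENTITY, np.array([0.0, 1.0, 0.0, 0.0]), 1.0),
        ],
    )
    def test_cost_dot_examples(self, x, y, expected):
        assert cost_dot(x, y) == pytest.approx(expected, abs=1e-12)

    def test_geodesic_is_rotation_angle(self):
        assert dist_geodesic(IDENTITY, ROT90X) == pytest.approx(np.pi / 2, abs=1e-12)
        assert dist_geodesic(IDENTITY, IDENTITY) == 0.0

    def test_rotangle_modes(self):
        assert dist_rotangle(ROT90X, ROT90X) == pytest.approx(0.0, abs=1e-7)
        assert dist_rotangle(ROT90X, ROT90X, mode="as-printed") == pytest.approx(1.0)
        assert dist_rotangle(IDENTITY, ROT90X) == pytest.approx(np.pi / 2, abs=1e-12)

    def test_tangent_matches_log_difference(self, rng):
        for _ in range(100):
            x, y = random_unit_quats(rng, 2)
            expected = np.linalg.norm(quat_log(x) - quat_log(y))
            assert dist_tangent(x, y) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("dist", ALL_DISTANCES)
    def test_symmetric_nonnegative_and_double_cover(self, dist, rng):
        """All four distances: symmetric, >= 0, zero on (q, q) and (q, -q)."""
        for _ in range(100):
            x, y = random_unit_quats(rng, 2)
            d = dist(x, y)
            assert d >= 0.0
            assert dist(y, x) == pytest.approx(d, abs=1e-9)
            assert dist(x, x) == pytest.approx(0.0, abs=1e-6)
            assert dist(x, -x) == pytest.approx(0.0, abs=1e-6)

    def test_cost_dot_bounded_by_one(self, rng):
        qs = random_unit_quats(rng, 50)
        for i in range(25):
            assert 0.0 <= cost_dot(qs[i], qs[i + 25]) <= 1.0

    @pytest.mark.parametrize("dist", ALL_DISTANCES)
    def test_nonfinite_rejected(self, dist):
        bad = np.array([np.nan, 0.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            dist(bad, IDENTITY)


class TestMarkley:
    def test_repeated_quaternion_is_fixed_point(self, rng):
        q = random_unit_quats(rng, 1)[0]
        avg = markley_average(np.array([q, q, q]))
        assert cost_dot(avg, q) == pytest.approx(0.0, abs=1e-12)

    def test_sign_invariance_pair(self, rng):
        q = random_unit_quats(rng, 1)[0]
        avg = markley_average(np.array([q, -q]))
        assert cost_dot(avg, q) == pytest.approx(0.0, abs=1e-12)

    def test_sign_invariance_random_flips(self, rng):
        qs = random_unit_quats(rng, 5)
        w = rng.uniform(0.1, 1.0, size=5)
        base = markley_average(qs, w)
        for _ in range(10):
            signs = rng.choice([-1.0, 1.0], size=5)
            flipped = markley_average(qs * signs[:, None], w)
            np.testing.assert_allclose(flipped, base, atol=1e-12)

    def test_coaxial_pair_bisects(self, rng):
        """Equal-weight coaxial rotations average to the half-angle rotation."""
        for _ in range(20):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            t1, t2 = rng.uniform(-np.pi * 0.9, np.pi * 0.9, size=2)
            while abs(t1 - t2) >= np.pi:
                t1, t2 = rng.uniform(-np.pi * 0.9, np.pi * 0.9, size=2)
            def q_of(t):
                return np.concatenate([[np.cos(t / 2)], np.sin(t / 2) * axis])
            avg = markley_average(np.array([q_of(t1), q_of(t2)]))
            expected = q_of((t1 + t2) / 2)
            assert cost_dot(avg, expected) == pytest.approx(0.0, abs=1e-9)

    def test_weight_validation(self, rng):
        qs = random_unit_quats(rng, 3)
        with pytest.raises(ValueError):
            markley_average(qs, np.zeros(3))
        with pytest.raises(ValueError):
            markley_average(qs, np.array([1.0, -0.5, 0.2]))
        with pytest.raises(ValueError):
            markley_average(np.empty((0, 4)))

    def test_degenerate_tie_warns(self):
        # two orthogonal rotations with equal weight: top eigenvalue is double
        qs = np.array([IDENTITY, [0.0, 1.0, 0.0, 0.0]])
        with pytest.warns(RuntimeWarning):
            avg = markley_average(qs)
        assert np.linalg.norm(avg) == pytest.approx(1.0)

    def test_unit_norm_output(self, rng):
        for _ in range(20):
            qs = random_unit_quats(rng, 4)
            w = rng.uniform(0.0, 1.0, size=4) + 1e-3
            assert np.linalg.norm(markley_average(qs, w)) == pytest.approx(1.0, abs=1e-12)


class TestEuler:
    @pytest.mark.parametrize("order", EULER_ORDERS)
    def test_roundtrip_all_orders(self, order):
        e = EulerAngles(rx=10.0, ry=20.0, rz=30.0, order=order)
        back = quat_to_euler(euler_to_quat(e), order)
        assert back.rx == pytest.approx(10.0, abs=1e-9)
        assert back.ry == pytest.approx(20.0, abs=1e-9)
        assert back.rz == pytest.approx(30.0, abs=1e-9)

    def test_zero_angles_identity(self):
        q = euler_to_quat(EulerAngles(0.0, 0.0, 0.0))
        np.testing.assert_allclose(q, IDENTITY, atol=1e-15)

    @pytest.mark.parametrize("order", EULER_ORDERS)
    def test_gimbal_lock_roundtrips_to_same_rotation(self, order):
        """Middle angle at 90 deg: the roundtrip rotation is unchanged even
        though the angle split is not unique (third angle zeroed)."""
        mid_axis = order[1]
        angles = {"X": 25.0, "Y": 25.0, "Z": 25.0}
        angles[mid_axis] = 90.0
        e = EulerAngles(rx=angles["X"], ry=angles["Y"], rz=angles["Z"], order=order)
        q = euler_to_quat(e)
        q2 = euler_to_quat(quat_to_euler(q, order))
        assert cost_dot(q, q2) == pytest.approx(0.0, abs=1e-9)

    @given(
        rx=st.floats(-179.9, 179.9),
        ry=st.floats(-89.0, 89.0),
        rz=st.floats(-179.9, 179.9),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_roundtrip_is_rotation_identity(self, rx, ry, rz):
        e = EulerAngles(rx=rx, ry=ry, rz=rz, order="ZXY")
        q = euler_to_quat(e)
        q2 = euler_to_quat(quat_to_euler(q, "ZXY"))
        assert cost_dot(q, q2) == pytest.approx(0.0, abs=1e-9)


class TestHelpers:
    def test_canonical_sign_rule(self):
        np.testing.assert_allclose(canonical_sign(np.array([-1.0, 0, 0, 0])), IDENTITY)
        np.testing.assert_allclose(
            canonical_sign(np.array([0.0, -1.0, 0, 0])), [0.0, 1.0, 0, 0]
        )

    def test_quat_mul_matches_scipy(self, rng):
        from scipy.spatial.transform import Rotation

        a, b = random_unit_quats(rng, 2)
        ours = quat_mul(a, b)
        ra = Rotation.from_quat(np.roll(a, -1))
        rb = Rotation.from_quat(np.roll(b, -1))
        theirs = np.roll((ra * rb).as_quat(), 1)
        assert min(np.linalg.norm(ours - theirs), np.linalg.norm(ours + theirs)) < 1e-12

    def test_normalize_rejects_zero(self):
        with pytest.raises(ValueError):
            normalize(np.zeros(4))
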