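"""Quaternion↔Euler conversion in the intrinsic Y–Z–X sequence.

Two independent oracles guard the conversion: scipy's Rotation (never used
in the implementation) and a brute-force factorization that scans an angle
grid for the Y·Z·X product closest to the quaternion's rotation matrix.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from mindmotion.kinematics import (
    EulerAngles,
    OrientationRecording,
    QuaternionSample,
    euler_array_to_quat_yzx,
    euler_yzx_to_quat,
    normalize_quaternion,
    quat_array_to_euler_yzx,
    quat_to_euler_yzx,
    read_recording,
    to_euler_trace,
    write_recording,
)

from conftest import random_unit_quats


def _ry(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rz(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def _rx(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def yzx_matrix(yaw_deg, pitch_deg, roll_deg):
    y, p, r = np.radians([yaw_deg, pitch_deg, roll_deg])
    return _ry(y) @ _rz(p) @ _rx(r)


class TestNormalize:
    @pytest.mark.parametrize(
        "q, expected",
        [
            ((0, 0, 0, 2), (0, 0, 0, 1)),
            ((0, 0, 0, -1), (0, 0, 0, 1)),
            ((1, 1, 1, 1), (0.5, 0.5, 0.5, 0.5)),
        ],
    )
    def test_examples(self, q, expected):
        out = normalize_quaternion(QuaternionSample(0.0, *q))
        np.testing.assert_allclose(out.vec, expected, atol=1e-12)

    def test_zero_quaternion_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            normalize_quaternion(QuaternionSample(0.0, 0, 0, 0, 0))

    def test_negative_timestamp_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            QuaternionSample(-1.0, 0, 0, 0, 1)


class TestQuatToEuler:
    def test_identity(self):
        e = quat_to_euler_yzx(QuaternionSample(0.0, 0, 0, 0, 1))
        assert (e.yaw, e.pitch, e.roll) == (0.0, 0.0, 0.0)

    def test_pure_yaw_90(self):
        h = np.pi / 4
        e = quat_to_euler_yzx(QuaternionSample(0.0, 0.0, np.sin(h), 0.0, np.cos(h)))
        np.testing.assert_allclose([e.yaw, e.pitch, e.roll], [90, 0, 0], atol=1e-9)

    def test_non_unit_rejected(self):
        with pytest.raises(ValueError, match="normalize"):
            quat_to_euler_yzx(QuaternionSample(0.0, 0, 0, 0, 1.01))

    def test_matches_scipy_oracle(self, rng):
        q = random_unit_quats(rng, 500)
        ours = quat_array_to_euler_yzx(q)
        ref = Rotation.from_quat(q).as_euler("YZX", degrees=True)
        away_from_lock = np.abs(ours[:, 1]) < 89.0
        np.testing.assert_allclose(
            ours[away_from_lock], ref[away_from_lock], atol=1e-8
        )

    @staticmethod
    def _grid_best(target, grid_y, grid_p, grid_r):
        """Brute-force scan: angles whose Y·Z·X product is Frobenius-closest."""
        ry = np.stack([_ry(a) for a in np.radians(grid_y)])
        rz = np.stack([_rz(a) for a in np.radians(grid_p)])
        rx = np.stack([_rx(a) for a in np.radians(grid_r)])
        yz = np.einsum("aij,bjk->abik", ry, rz)
        full = np.einsum("abij,cjk->abcik", yz, rx)
        d2 = ((full - target) ** 2).sum(axis=(-2, -1))
        iy, ip, ir = np.unravel_index(np.argmin(d2), d2.shape)
        return grid_y[iy], grid_p[ip], grid_r[ir]

    def test_matches_bruteforce_factorization(self, rng):
        """Grid-scan oracle: the YZX factorization minimizing the Frobenius
        distance to the rotation matrix agrees within grid resolution."""
        coarse = np.arange(-180.0, 180.0, 4.0)
        coarse_p = np.arange(-90.0, 90.1, 4.0)
        fine = 0.1
        checked = 0
        for q in random_unit_quats(rng, 200):
            e = quat_array_to_euler_yzx(q)
            if abs(e[1]) >= 80:
                continue
            checked += 1
            if checked > 100:
                break
            target = Rotation.from_quat(q).as_matrix()
            y0, p0, r0 = self._grid_best(target, coarse, coarse_p, coarse)
            span = np.arange(-4.0, 4.05, fine)
            y1, p1, r1 = self._grid_best(target, y0 + span, p0 + span, r0 + span)
            found = np.array([y1, p1, r1])
            diff = np.abs((found - e + 180) % 360 - 180)
            assert np.all(diff <= fine * 2), (e, found)

    def test_gimbal_lock_convention(self):
        # pitch exactly +90: roll forced to 0, residual absorbed into yaw
        q = euler_array_to_quat_yzx(np.array([30.0, 90.0, 20.0]))
        e = quat_array_to_euler_yzx(q)
        assert e[2] == 0.0
        np.testing.assert_allclose(e[1], 90.0, atol=1e-6)
        # the rotation itself is preserved despite the reparametrization
        np.testing.assert_allclose(
            yzx_matrix(*e), yzx_matrix(30.0, 90.0, 20.0), atol=1e-6
        )


class TestEulerToQuat:
    def test_identity(self):
        q = euler_yzx_to_quat(EulerAngles(0, 0, 0))
        np.testing.assert_allclose(q.vec, [0, 0, 0, 1], atol=1e-12)

    def test_yaw_180_flips_forward_vector(self):
        q = euler_yzx_to_quat(EulerAngles(180, 0, 0))
        m = Rotation.from_quat(q.vec).as_matrix()
        fwd = np.array([0.0, 0.0, 1.0])  # horizontal forward, orthogonal to Y
        np.testing.assert_allclose(m @ fwd, -fwd, atol=1e-12)

    def test_round_trip_named_angles(self):
        q = euler_yzx_to_quat(EulerAngles(30, 20, 10))
        e = quat_to_euler_yzx(q)
        np.testing.assert_allclose([e.yaw, e.pitch, e.roll], [30, 20, 10], atol=1e-6)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            euler_yzx_to_quat(EulerAngles(np.nan, 0, 0))


@settings(max_examples=200, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_round_trip_recovers_rotation(seed):
    """euler(quat(euler(q))) reproduces the rotation (sign-free) to 1e-6."""
    q = random_unit_quats(np.random.default_rng(seed), 8)
    back = euler_array_to_quat_yzx(quat_array_to_euler_yzx(q))
    err = np.minimum(
        np.linalg.norm(back - q, axis=1), np.linalg.norm(back + q, axis=1)
    )
    assert err.max() < 1e-6


class TestToEulerTrace:
    def _recording(self, t, euler):
        return OrientationRecording(t=t, quats=euler_array_to_quat_yzx(euler))

    def test_constant_orientation_gives_flat_trace(self):
        t = np.arange(100) / 50.0
        euler = np.tile([12.0, -5.0, 3.0], (100, 1))
        tr = to_euler_trace(self._recording(t, euler))
        for ch, v in zip(("yaw", "pitch", "roll"), (12.0, -5.0, 3.0)):
            np.testing.assert_allclose(tr.channel(ch), v, atol=1e-9)

    def test_shortest_arc_unwrap(self):
        # 0° and 350° yaw are 10° apart the short way round
        t = np.array([0.0, 0.1, 0.2, 0.3])
        rec = OrientationRecording(
            t=t,
            quats=euler_array_to_quat_yzx(
                np.array([[0.0, 0, 0], [350.0, 0, 0], [340.0, 0, 0], [330.0, 0, 0]])
            ),
            nominal_rate=10.0,
        )
        tr = to_euler_trace(rec)
        np.testing.assert_allclose(tr.yaw, [0.0, -10.0, -20.0, -30.0], atol=1e-9)

    def test_sinusoid_recovered_through_jittered_sampling(self, rng):
        n, rate = 2000, 50.0
        t = np.arange(n) / rate + np.clip(
            rng.normal(0, 0.002, n), -0.009, 0.009
        )
        t[0] = 0.0
        yaw = 10 * np.sin(2 * np.pi * 0.4 * t)
        euler = np.column_stack([yaw, np.zeros(n), np.zeros(n)])
        tr = to_euler_trace(self._recording(t, euler))
        truth = 10 * np.sin(2 * np.pi * 0.4 * tr.times)
        assert np.abs(tr.yaw - truth).max() < 0.1

    def test_resampled_length(self, rng):
        t = np.sort(rng.uniform(0, 10, 300))
        t[0], t[-1] = 0.0, 10.0
        euler = np.zeros((300, 3))
        tr = to_euler_trace(self._recording(t, euler))
        assert abs(len(tr) - round(10 * 50)) <= 1

    def test_duplicate_timestamps_rejected(self):
        t = np.array([0.0, 0.02, 0.02, 0.06])
        with pytest.raises(ValueError, match="duplicate"):
            OrientationRecording(t=t, quats=np.tile([0, 0, 0, 1.0], (4, 1)))

    def test_too_short_recording_rejected(self):
        rec = OrientationRecording(
            t=np.array([0.0, 0.01]), quats=np.tile([0, 0, 0, 1.0], (2, 1))
        )
        with pytest.raises(ValueError, match="shorter"):
            to_euler_trace(rec)


class TestRecordingIO:
    def test_round_trip(self, tmp_path, rng):
        q = random_unit_quats(rng, 50)
        rec = OrientationRecording(
            t=np.arange(50) / 50.0,
            quats=q,
            participant="patient1",
            session=3,
            segment="sitting@fireplace",
        )
        path = write_recording(rec, tmp_path / "seg.csv")
        assert path.read_text().splitlines()[0] == "t,qx,qy,qz,qw"
        back = read_recording(path)
        np.testing.assert_allclose(back.quats, q, atol=1e-8)
        assert (back.participant, back.session, back.segment) == (
            "patient1",
            3,
            "sitting@fireplace",
        )

    def test_malformed_csv_reports_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("t,qx,qy,qz,qw\n0.0,0,0,0,1\n0.02,0,nan,0,1\n")
        with pytest.raises(ValueError, match="line 3"):
            read_recording(p)
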