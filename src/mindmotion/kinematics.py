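"""Head-orientation kinematics: quaternion streams and Euler-angle traces.

A head-mounted display reports orientation as timestamped unit quaternions
(scalar-last ``qx, qy, qz, qw`` — the Unity/GearVR convention).  Analysis
works on Euler angles in the intrinsic Y–Z–X sequence, the natural frame for
a seated wearer: yaw about the vertical Y axis (looking left/right), pitch
about Z (up/down), roll about X (head tilt).  This module owns the
quaternion↔Euler conversion, including a deterministic gimbal-lock
convention, and the resampling of jittery sensor timestamps onto a uniform
grid so spectral analysis downstream is well-posed.

Angles are degrees in all public interfaces; radians appear only inside the
trigonometric kernels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "QuaternionSample",
    "EulerAngles",
    "EulerTrace",
    "OrientationRecording",
    "normalize_quaternion",
    "quat_to_euler_yzx",
    "euler_yzx_to_quat",
    "quat_array_to_euler_yzx",
    "euler_array_to_quat_yzx",
    "to_euler_trace",
    "read_recording",
    "write_recording",
]

#: |pitch| closer than this (degrees) to 90° triggers the gimbal convention.
GIMBAL_MARGIN_DEG = 0.1

#: Largest tolerated deviation from unit norm before conversion refuses.
UNIT_NORM_TOL = 1e-3

RECORDING_COLUMNS = ["t", "qx", "qy", "qz", "qw"]


@dataclass(frozen=True)
class QuaternionSample:
    """One timestamped orientation sample, scalar-last unit quaternion."""

    t: float
    qx: float
    qy: float
    qz: float
    qw: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.t) or self.t < 0:
            raise ValueError(f"timestamp must be finite and non-negative, got {self.t!r}")

    @property
    def vec(self) -> np.ndarray:
        """Components as a (4,) array in (qx, qy, qz, qw) order."""
        return np.array([self.qx, self.qy, self.qz, self.qw], dtype=float)

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.vec))


@dataclass(frozen=True)
class EulerAngles:
    """Yaw/pitch/roll in degrees for one intrinsic Y–Z–X factorization.

    Canonical ranges: yaw, roll in (−180, 180]; pitch in [−90, 90].
    """

    yaw: float
    pitch: float
    roll: float


@dataclass
class EulerTrace:
    """Uniform-rate yaw/pitch/roll time series for one session segment."""

    t0: float
    rate: float
    yaw: np.ndarray
    pitch: np.ndarray
    roll: np.ndarray

    def __post_init__(self) -> None:
        self.yaw = np.asarray(self.yaw, dtype=float)
        self.pitch = np.asarray(self.pitch, dtype=float)
        self.roll = np.asarray(self.roll, dtype=float)
        n = len(self.yaw)
        if len(self.pitch) != n or len(self.roll) != n:
            raise ValueError("yaw, pitch and roll must have equal length")
        if n < 2:
            raise ValueError("a trace needs at least 2 samples")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    def __len__(self) -> int:
        return len(self.yaw)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.rate

    @property
    def duration(self) -> float:
        return (len(self) - 1) / self.rate

    def channel(self, name: str) -> np.ndarray:
        if name not in ("yaw", "pitch", "roll"):
            raise KeyError(name)
        return getattr(self, name)

    def trimmed(self, n_edge: int) -> "EulerTrace":
        """Drop ``n_edge`` samples at both ends (filter edge policy)."""
        if n_edge <= 0:
            return self
        if len(self) - 2 * n_edge < 2:
            raise ValueError("trace too short to trim edges")
        sl = slice(n_edge, len(self) - n_edge)
        return EulerTrace(
            t0=self.t0 + n_edge / self.rate,
            rate=self.rate,
            yaw=self.yaw[sl],
            pitch=self.pitch[sl],
            roll=self.roll[sl],
        )


@dataclass
class OrientationRecording:
    """An ordered quaternion stream plus acquisition metadata.

    ``quats`` is an (n, 4) scalar-last array; ``t`` the matching timestamps
    in seconds (strictly increasing).  ``nominal_rate`` is the sensor's
    advertised sampling rate F_S (50 Hz for the headset), which the true
    timestamps only approximate.
    """

    t: np.ndarray
    quats: np.ndarray
    nominal_rate: float = 50.0
    participant: str = ""
    session: int = 0
    segment: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.quats = np.asarray(self.quats, dtype=float)
        if self.quats.ndim != 2 or self.quats.shape[1] != 4:
            raise ValueError("quats must be an (n, 4) array, scalar-last")
        if len(self.t) != len(self.quats):
            raise ValueError("t and quats must have equal length")
        if self.nominal_rate <= 0:
            raise ValueError("nominal_rate must be positive")
        if len(self.t) >= 2:
            dt = np.diff(self.t)
            if np.any(dt < 0):
                raise ValueError("timestamps must be increasing")
            if np.any(dt == 0):
                k = int(np.flatnonzero(dt == 0)[0])
                raise ValueError(f"duplicate timestamp at sample {k}")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def samples(self) -> list[QuaternionSample]:
        return [
            QuaternionSample(float(ti), *map(float, q))
            for ti, q in zip(self.t, self.quats)
        ]


# ---------------------------------------------------------------------------
# quaternion algebra
# ---------------------------------------------------------------------------


def _normalize_array(q: np.ndarray, index: int | None = None) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    norm = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(norm == 0) or not np.all(np.isfinite(norm)):
        bad = "" if index is None else f" at sample {index}"
        raise ValueError(f"cannot normalize all-zero or non-finite quaternion{bad}")
    out = q / norm
    # q and -q encode the same rotation; pin the sign so outputs are unique
    flip = out[..., 3:4] < 0
    return np.where(flip, -out, out)


def normalize_quaternion(q: QuaternionSample) -> QuaternionSample:
    """Rescale to unit norm and pin the sign convention ``qw >= 0``."""
    v = _normalize_array(q.vec)
    return QuaternionSample(q.t, *map(float, v))


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrices, shape (..., 3, 3), from scalar-last unit quats."""
    x, y, z, w = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    m = np.empty(q.shape[:-1] + (3, 3), dtype=float)
    m[..., 0, 0] = 1 - 2 * (y * y + z * z)
    m[..., 0, 1] = 2 * (x * y - z * w)
    m[..., 0, 2] = 2 * (x * z + y * w)
    m[..., 1, 0] = 2 * (x * y + z * w)
    m[..., 1, 1] = 1 - 2 * (x * x + z * z)
    m[..., 1, 2] = 2 * (y * z - x * w)
    m[..., 2, 0] = 2 * (x * z - y * w)
    m[..., 2, 1] = 2 * (y * z + x * w)
    m[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return m


def quat_array_to_euler_yzx(quats: np.ndarray) -> np.ndarray:
    """Vectorized YZX Euler extraction; returns (..., 3) degrees.

    For R = Ry(yaw)·Rz(pitch)·Rx(roll):

        R[1,0] = sin(pitch)
        yaw  = atan2(−R[2,0], R[0,0])
        roll = atan2(−R[1,2], R[1,1])

    Near |pitch| = 90° the yaw/roll pair degenerates (gimbal lock); the
    convention here sets roll := 0 and absorbs the residual rotation into
    yaw, computed from the still well-conditioned first matrix row.
    """
    quats = np.asarray(quats, dtype=float)
    norm = np.linalg.norm(quats, axis=-1)
    if np.any(np.abs(norm - 1.0) > UNIT_NORM_TOL):
        raise ValueError(
            "quaternion norm deviates from 1 by more than "
            f"{UNIT_NORM_TOL}; normalize first (normalize_quaternion)"
        )
    m = _quat_to_matrix(quats / norm[..., None])

    pitch = np.degrees(np.arcsin(np.clip(m[..., 1, 0], -1.0, 1.0)))
    yaw = np.degrees(np.arctan2(-m[..., 2, 0], m[..., 0, 0]))
    roll = np.degrees(np.arctan2(-m[..., 1, 2], m[..., 1, 1]))

    locked = np.abs(pitch) >= 90.0 - GIMBAL_MARGIN_DEG
    if np.any(locked):
        # pitch=+90: R[0,2]=sin(yaw+roll), R[0,1]=−cos(yaw+roll)
        # pitch=−90: R[0,2]=sin(yaw−roll), R[0,1]= cos(yaw−roll)
        up = locked & (pitch > 0)
        dn = locked & (pitch <= 0)
        yaw = np.where(up, np.degrees(np.arctan2(m[..., 0, 2], -m[..., 0, 1])), yaw)
        yaw = np.where(dn, np.degrees(np.arctan2(m[..., 0, 2], m[..., 0, 1])), yaw)
        roll = np.where(locked, 0.0, roll)

    # canonical half-open ranges: map −180 to +180
    yaw = np.where(yaw <= -180.0, yaw + 360.0, yaw)
    roll = np.where(roll <= -180.0, roll + 360.0, roll)
    return np.stack([yaw, pitch, roll], axis=-1)


def quat_to_euler_yzx(q: QuaternionSample) -> EulerAngles:
    """Convert one unit quaternion to yaw/pitch/roll (degrees, YZX)."""
    e = quat_array_to_euler_yzx(q.vec)
    return EulerAngles(float(e[0]), float(e[1]), float(e[2]))


def _quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ax, ay, az, aw = a[..., 0], a[..., 1], a[..., 2], a[..., 3]
    bx, by, bz, bw = b[..., 0], b[..., 1], b[..., 2], b[..., 3]
    return np.stack(
        [
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
            aw * bw - ax * bx - ay * by - az * bz,
        ],
        axis=-1,
    )


def euler_array_to_quat_yzx(euler_deg: np.ndarray) -> np.ndarray:
    """Compose unit quaternions from (..., 3) yaw/pitch/roll degrees.

    Intrinsic Y→Z→X corresponds to the fixed-frame product qY ⊗ qZ ⊗ qX.
    Angles outside the canonical ranges are accepted (they wrap).
    """
    e = np.radians(np.asarray(euler_deg, dtype=float))
    half = e / 2.0
    cy, cp, cr = np.cos(half[..., 0]), np.cos(half[..., 1]), np.cos(half[..., 2])
    sy, sp, sr = np.sin(half[..., 0]), np.sin(half[..., 1]), np.sin(half[..., 2])
    zeros = np.zeros_like(cy)
    qy = np.stack([zeros, sy, zeros, cy], axis=-1)
    qz = np.stack([zeros, zeros, sp, cp], axis=-1)
    qx = np.stack([sr, zeros, zeros, cr], axis=-1)
    return _normalize_array(_quat_multiply(_quat_multiply(qy, qz), qx))


def euler_yzx_to_quat(e: EulerAngles, t: float = 0.0) -> QuaternionSample:
    """Inverse of :func:`quat_to_euler_yzx` (up to quaternion sign)."""
    for name in ("yaw", "pitch", "roll"):
        if not np.isfinite(getattr(e, name)):
            raise ValueError(f"{name} must be finite")
    q = euler_array_to_quat_yzx(np.array([e.yaw, e.pitch, e.roll]))
    return QuaternionSample(t, *map(float, q))


# ---------------------------------------------------------------------------
# recording → uniform trace
# ---------------------------------------------------------------------------


def to_euler_trace(rec: OrientationRecording) -> EulerTrace:
    """Convert a quaternion recording to a uniform-rate Euler trace.

    Per-sample YZX conversion, then per-channel unwrapping (no consecutive
    jump may exceed 180°, so genuine tracking glitches survive as steps for
    the conditioning stage), then linear interpolation onto a uniform grid
    at the nominal rate, anchored at the first timestamp.
    """
    if len(rec) < 2:
        raise ValueError("recording needs at least 2 samples")
    duration = rec.t[-1] - rec.t[0]
    if duration < 2.0 / rec.nominal_rate:
        raise ValueError(
            f"recording spans {duration:.4f} s, shorter than 2 sample periods "
            f"at {rec.nominal_rate} Hz"
        )
    euler = quat_array_to_euler_yzx(_normalize_array(rec.quats))
    unwrapped = np.column_stack(
        [np.unwrap(euler[:, k], period=360.0) for k in range(3)]
    )
    n = int(round(duration * rec.nominal_rate)) + 1
    grid = rec.t[0] + np.arange(n) / rec.nominal_rate
    channels = [np.interp(grid, rec.t, unwrapped[:, k]) for k in range(3)]
    return EulerTrace(
        t0=float(rec.t[0]),
        rate=float(rec.nominal_rate),
        yaw=channels[0],
        pitch=channels[1],
        roll=channels[2],
    )


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------


def write_recording(rec: OrientationRecording, csv_path: str | Path) -> Path:
    """Write ``t,qx,qy,qz,qw`` CSV plus a JSON metadata sidecar."""
    csv_path = Path(csv_path)
    df = pd.DataFrame(
        np.column_stack([rec.t, rec.quats]), columns=RECORDING_COLUMNS
    )
    df.to_csv(csv_path, index=False, float_format="%.9g")
    sidecar = csv_path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "participant": rec.participant,
                "session": rec.session,
                "segment": rec.segment,
                "rate_hz": rec.nominal_rate,
            },
            sort_keys=True,
        )
        + "\n"
    )
    return csv_path


def read_recording(csv_path: str | Path) -> OrientationRecording:
    """Read a recording CSV (and its sidecar, when present)."""
    csv_path = Path(csv_path)
    try:
        df = pd.read_csv(csv_path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"malformed recording CSV {csv_path}: {exc}") from exc
    if list(df.columns) != RECORDING_COLUMNS:
        raise ValueError(
            f"{csv_path}: expected columns {RECORDING_COLUMNS}, got {list(df.columns)}"
        )
    bad = ~np.isfinite(df.to_numpy(dtype=float)).all(axis=1)
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2  # header is line 1
        raise ValueError(f"{csv_path}: non-numeric or non-finite value at line {line}")
    meta = {"participant": "", "session": 0, "segment": "", "rate_hz": 50.0}
    sidecar = csv_path.with_suffix(".json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    return OrientationRecording(
        t=df["t"].to_numpy(),
        quats=df[["qx", "qy", "qz", "qw"]].to_numpy(),
        nominal_rate=float(meta["rate_hz"]),
        participant=str(meta["participant"]),
        session=int(meta["session"]),
        segment=str(meta["segment"]),
    )
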