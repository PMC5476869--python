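import numpy as np
import pytest

from mindmotion.kinematics import EulerTrace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sinusoid_trace():
    """80 s of clean multi-tone motion at 50 Hz: 0.4 Hz yaw (10°),
    0.25 Hz pitch (4°), 0.15 Hz roll (6°)."""
    t = np.arange(4000) / 50.0
    return EulerTrace(
        t0=0.0,
        rate=50.0,
        yaw=10.0 * np.sin(2 * np.pi * 0.4 * t),
        pitch=4.0 * np.sin(2 * np.pi * 0.25 * t),
        roll=6.0 * np.sin(2 * np.pi * 0.15 * t),
    )


def random_unit_quats(rng, n):
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return np.where(q[:, 3:] < 0, -q, q)
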