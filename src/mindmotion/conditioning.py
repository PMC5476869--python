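"""Signal conditioning for Euler traces: low-pass filtering and repair of
tracking discontinuities.

The preprocessing chain applied to every head-motion trace before any metric
or spectrum is computed:

1. zero-phase Butterworth low-pass (default 2 Hz, order 4) — removes sensor
   noise well above the sub-hertz band where head motion lives;
2. wavelet discontinuity detection — level-1 Haar detail coefficients,
   computed with the undecimated (stationary) transform so a step is seen at
   every shift, thresholded at a multiple of their median absolute deviation;
3. step removal — the jump at each flagged sample is subtracted from all
   later samples and a short window around it is re-interpolated.

Discontinuities arise from tracking re-references (the headset snapping its
yaw origin) and residual wrap artifacts; they are steps, not spikes of the
underlying motion, so step subtraction is the appropriate repair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal

from .kinematics import EulerTrace

__all__ = [
    "FilterSpec",
    "DiscontinuityReport",
    "lowpass_filter",
    "detect_discontinuities",
    "remove_discontinuities",
    "condition_trace",
    "edge_trim_samples",
]

DEFAULT_CUTOFF_HZ = 2.0
DEFAULT_ORDER = 4
DEFAULT_THRESHOLD_MULT = 8.0


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth low-pass settings; zero-phase runs forward + backward."""

    cutoff_hz: float = DEFAULT_CUTOFF_HZ
    order: int = DEFAULT_ORDER
    zero_phase: bool = True
    kind: str = "butterworth-lowpass"

    def __post_init__(self) -> None:
        if self.kind != "butterworth-lowpass":
            raise ValueError(f"unsupported filter kind {self.kind!r}")
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff_hz must be positive")
        if self.order < 1:
            raise ValueError("order must be a positive integer")


@dataclass
class DiscontinuityReport:
    """Flagged step positions (sample indices) and their signed sizes."""

    indices: list[int] = field(default_factory=list)
    magnitudes: list[float] = field(default_factory=list)
    method: str = "haar-swt-mad"

    def __post_init__(self) -> None:
        if len(self.indices) != len(self.magnitudes):
            raise ValueError("indices and magnitudes must match in length")
        if any(b <= a for a, b in zip(self.indices, self.indices[1:])):
            raise ValueError("indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.indices)


def edge_trim_samples(spec: FilterSpec) -> int:
    """Samples to exclude at each end of a filtered trace (edge transients)."""
    return max(spec.order, 10)


def lowpass_filter(trace: EulerTrace, spec: FilterSpec) -> EulerTrace:
    """Apply the Butterworth low-pass identically to all three channels."""
    nyquist = trace.rate / 2.0
    if spec.cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {spec.cutoff_hz} Hz is at or above the Nyquist limit "
            f"{nyquist} Hz for rate {trace.rate} Hz; such a filter passes "
            "everything and is refused"
        )
    sos = signal.butter(spec.order, spec.cutoff_hz, btype="low", fs=trace.rate, output="sos")
    run = signal.sosfiltfilt if spec.zero_phase else signal.sosfilt
    return EulerTrace(
        t0=trace.t0,
        rate=trace.rate,
        yaw=np.asarray(run(sos, trace.yaw)),
        pitch=np.asarray(run(sos, trace.pitch)),
        roll=np.asarray(run(sos, trace.roll)),
    )


_SWT_PAD = 4  # edge-replication pad; keeps the SWT's periodic wrap-around
# (which couples x[0] with x[-1]) out of the analysed range


def _haar_details(x: np.ndarray) -> np.ndarray:
    """Level-1 Haar detail coefficients at every shift (stationary DWT)."""
    n = len(x)
    # extrapolate the edge slope so padding introduces no artificial kink
    head = x[0] - (x[1] - x[0]) * np.arange(_SWT_PAD, 0, -1)
    tail = x[-1] + (x[-1] - x[-2]) * np.arange(1, _SWT_PAD + 1)
    padded = np.concatenate([head, x, tail])
    if len(padded) % 2:
        padded = np.append(padded, padded[-1])
    (_, details), = pywt.swt(padded, "haar", level=1, norm=False)
    return details[_SWT_PAD : _SWT_PAD + n]


def detect_discontinuities(
    channel: np.ndarray,
    rate: float,
    threshold_mult: float = DEFAULT_THRESHOLD_MULT,
) -> DiscontinuityReport:
    """Flag step discontinuities in one angle channel.

    Local maxima of |level-1 Haar detail| exceeding
    ``threshold_mult × MAD(detail)`` are reported; each peak is refined to
    the largest one-sample difference in its immediate neighbourhood, and
    the reported index ``k`` means the jump occurs between samples ``k−1``
    and ``k``.
    """
    x = np.asarray(channel, dtype=float)
    if len(x) < 8:
        raise ValueError("need at least 8 samples to detect discontinuities")
    if threshold_mult <= 0:
        raise ValueError("threshold_mult must be positive")
    if not np.all(np.isfinite(x)):
        k = int(np.flatnonzero(~np.isfinite(x))[0])
        raise ValueError(f"non-finite sample at index {k}")

    details = _haar_details(x)
    # centre on the median: a constant-slope signal has a large constant
    # detail, and only the deviation from it marks a step
    absd = np.abs(details - np.median(details))
    mad = float(np.median(np.abs(details - np.median(details))))
    threshold = threshold_mult * max(mad, 1e-12)
    peaks, _ = signal.find_peaks(np.concatenate(([0.0], absd, [0.0])), height=threshold)
    peaks -= 1

    diffs = np.diff(x)
    indices: list[int] = []
    magnitudes: list[float] = []
    for p in peaks:
        lo, hi = max(0, p - 1), min(len(diffs), p + 2)
        j = lo + int(np.argmax(np.abs(diffs[lo:hi])))
        k = j + 1  # jump lands between samples j and j+1
        if indices and k <= indices[-1] + 2:
            continue  # same step seen from an adjacent detail peak
        indices.append(k)
        magnitudes.append(_straddle_jump(x, k))
    return DiscontinuityReport(indices=indices, magnitudes=magnitudes)


def _straddle_window(x: np.ndarray, k: int) -> tuple[int, int]:
    n = len(x)
    return max(k - 2, 0), min(k + 2, n - 1)


def _straddle_jump(x: np.ndarray, k: int) -> float:
    """Signed step size at flagged index ``k``, measured across samples
    ``k−2 .. k+2`` with the local smooth slope subtracted.

    Resampling of jittery timestamps onto the uniform grid can smear a
    physical step over up to two interior samples, so a one-sample
    difference underestimates it; the ±2 straddle brackets the smear on
    both sides and recovers the full size.
    """
    lo, hi = _straddle_window(x, k)
    lo_w, hi_w = max(0, k - 12), min(len(x) - 1, k + 12)
    d = np.diff(x[lo_w : hi_w + 1])
    keep = np.ones(len(d), dtype=bool)
    keep[max(0, lo - 1 - lo_w) : min(len(d), hi + 1 - lo_w)] = False
    slope = float(np.median(d[keep])) if keep.any() else 0.0
    return float(x[hi] - x[lo] - (hi - lo) * slope)


def remove_discontinuities(
    channel: np.ndarray, report: DiscontinuityReport
) -> np.ndarray:
    """Subtract each flagged step from all later samples and smooth locally.

    The step size is re-measured on the evolving signal with
    :func:`_straddle_jump` (robust to steps split across two samples by
    resampling), subtracted from everything after the step, and a short
    window around each flagged index is then linearly re-interpolated
    between its clean neighbours; overlapping windows are merged.  The
    input is not modified.
    """
    x = np.asarray(channel, dtype=float).copy()
    n = len(x)
    for k in report.indices:
        if not 0 < k < n:
            raise ValueError(f"discontinuity index {k} outside channel of length {n}")
    for k in report.indices:
        jump = _straddle_jump(x, k)
        x[_straddle_window(x, k)[1] :] -= jump

    if report.indices:
        windows: list[list[int]] = []
        for k in report.indices:
            lo, hi = max(k - 2, 1), min(k + 1, n - 2)
            if windows and lo <= windows[-1][1] + 1:
                windows[-1][1] = max(windows[-1][1], hi)
            else:
                windows.append([lo, hi])
        for lo, hi in windows:
            a, b = lo - 1, hi + 1
            x[lo : hi + 1] = np.interp(np.arange(lo, hi + 1), [a, b], [x[a], x[b]])
    return x


def condition_trace(
    trace: EulerTrace,
    filter_spec: FilterSpec | None = None,
    threshold_mult: float = DEFAULT_THRESHOLD_MULT,
    trim_edges: bool = True,
) -> tuple[EulerTrace, dict[str, DiscontinuityReport]]:
    """Full conditioning chain: repair discontinuities, filter, trim edges.

    Discontinuities are repaired *before* filtering (a zero-phase filter
    smears a step across many samples, hiding it from the detector).
    Returns the conditioned trace and the per-channel reports.
    """
    spec = filter_spec or FilterSpec()
    reports: dict[str, DiscontinuityReport] = {}
    repaired: dict[str, np.ndarray] = {}
    for name in ("yaw", "pitch", "roll"):
        rep = detect_discontinuities(trace.channel(name), trace.rate, threshold_mult)
        reports[name] = rep
        repaired[name] = remove_discontinuities(trace.channel(name), rep)
    clean = EulerTrace(t0=trace.t0, rate=trace.rate, **repaired)
    filtered = lowpass_filter(clean, spec)
    if trim_edges:
        filtered = filtered.trimmed(edge_trim_samples(spec))
    return filtered, reports
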