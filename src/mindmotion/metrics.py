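"""Per-segment motion summaries: per-axis excursion ranges, the yaw–roll
motion-curve area, and percent change between matched segments.

The motion-curve area condenses how far the head wandered in the horizontal
rotation (yaw) / tilt (roll) plane over a segment.  It is computed as the
area of the convex hull of the (yaw, roll) point cloud: deterministic,
parameter-free, monotone under added excursions.  A 95% covariance-ellipse
area is available as an alternative estimator for sensitivity checks.
Percent change is signed, negative meaning the later segment was calmer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import chi2

from .kinematics import EulerTrace

__all__ = [
    "MotionSummary",
    "AreaChange",
    "motion_range",
    "yaw_roll_curve_area",
    "covariance_ellipse_area",
    "percent_area_change",
    "summarize_trace",
]


@dataclass
class MotionSummary:
    """Time-domain summary of one conditioned session segment."""

    segment: str
    range_yaw: float
    range_pitch: float
    range_roll: float
    curve_area: float
    duration: float


@dataclass
class AreaChange:
    """Motion-curve area of a matched segment pair and the signed change."""

    segment_pair: tuple[str, str]
    area_before: float
    area_after: float
    percent_change: float


def motion_range(trace: EulerTrace) -> tuple[float, float, float]:
    """Peak-to-peak excursion (max − min, degrees) per channel."""
    return (
        float(np.ptp(trace.yaw)),
        float(np.ptp(trace.pitch)),
        float(np.ptp(trace.roll)),
    )


def yaw_roll_curve_area(trace: EulerTrace) -> float:
    """Convex-hull area (deg²) of the trajectory in the yaw–roll plane.

    Degenerate point sets (all identical, collinear) have zero area.
    """
    pts = np.column_stack([trace.yaw, trace.roll])
    if len(pts) < 3:
        raise ValueError("need at least 3 samples for a curve area")
    if np.allclose(pts, pts[0]):
        return 0.0
    try:
        hull = ConvexHull(pts)
    except QhullError:  # collinear or otherwise flat
        return 0.0
    return float(hull.volume)  # in 2D, .volume is the enclosed area


def covariance_ellipse_area(trace: EulerTrace, coverage: float = 0.95) -> float:
    """Area (deg²) of the ellipse covering ``coverage`` of a Gaussian fit
    to the yaw–roll cloud — the alias estimator for the motion-curve area."""
    if not 0 < coverage < 1:
        raise ValueError("coverage must be in (0, 1)")
    pts = np.column_stack([trace.yaw, trace.roll])
    cov = np.cov(pts, rowvar=False)
    det = float(np.linalg.det(cov))
    if det <= 0:
        return 0.0
    return float(np.pi * chi2.ppf(coverage, df=2) * np.sqrt(det))


def percent_area_change(area_before: float, area_after: float) -> float:
    """Signed percent change, negative = reduction (100→77 gives −23)."""
    if area_before <= 0:
        raise ValueError("baseline area must be positive")
    return (area_after - area_before) / area_before * 100.0


def summarize_trace(trace: EulerTrace, segment: str = "") -> MotionSummary:
    ry, rp, rr = motion_range(trace)
    return MotionSummary(
        segment=segment,
        range_yaw=ry,
        range_pitch=rp,
        range_roll=rr,
        curve_area=yaw_roll_curve_area(trace),
        duration=trace.duration,
    )
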