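"""Seeded synthetic headset recordings and questionnaire fixtures with known
ground truth.

The study's raw headset recordings were never deposited, so every
head-motion analysis here runs on generated data whose statistical
structure mirrors what a seated mindfulness participant produces:

* slow gaze drift (Gaussian random walk per channel);
* low-frequency scanning of the scene (sub-0.2 Hz yaw sweeps up to ±40°
  for engaged viewers, about half that for patients, with small pitch and
  roll components — the "less than ±10 degrees" regime);
* restless high-frequency motion ("turbulence", a 0.6 Hz component above
  the 0.34/0.44 Hz analysis cut-offs) whose amplitude declines over the
  program for the group/setting combinations that calm down;
* saccade-like steps, timestamp jitter, and tracking re-reference
  artifacts (sudden yaw steps, default 160°, that the conditioning stage
  must detect and remove — a quaternion stream cannot encode steps beyond
  ±180°, so artifact magnitudes live in that range).

Everything is a pure function of (spec, seed): two calls with identical
arguments produce bitwise-identical recordings.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import (
    EulerTrace,
    OrientationRecording,
    euler_array_to_quat_yzx,
    write_recording,
)
from .program import SegmentPlan, default_plan, segment_label
from .psychometrics import ScaleResponse
from .reference_data import STUDY_OUTCOMES

__all__ = [
    "MotionSpec",
    "GroundTruth",
    "StudyFixture",
    "generate_recording",
    "generate_scale_items",
    "make_study_fixture",
    "write_fixture",
]

CHANNELS = ("yaw", "pitch", "roll")

#: Default tracking re-reference step (degrees); must stay within (−180, 180].
WRAP_STEP_DEG = 160.0


@dataclass
class MotionSpec:
    """Recipe for one synthetic orientation recording.

    ``components`` are (channel, freq_hz, amplitude_deg, phase_deg)
    sinusoids; ``saccades`` are (time_s, channel, step_deg) gaze jumps that
    are part of the true motion; ``wrap_artifacts`` are (time_s, step_deg)
    sensor glitches on the yaw channel that the pipeline should repair.
    ``drift_sd`` is the per-sample random-walk step SD in degrees.
    """

    duration: float
    rate: float = 50.0
    drift_sd: float = 0.01
    components: list[tuple[str, float, float, float]] = field(default_factory=list)
    saccades: list[tuple[float, str, float]] = field(default_factory=list)
    wrap_artifacts: list[tuple[float, float]] = field(default_factory=list)
    jitter_sd: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.rate <= 0:
            raise ValueError("duration and rate must be positive")
        nyquist = self.rate / 2.0
        for ch, f, amp, phase in self.components:
            if ch not in CHANNELS:
                raise ValueError(f"unknown channel {ch!r}")
            if f >= nyquist:
                raise ValueError(f"component at {f} Hz is at or above Nyquist ({nyquist} Hz)")
        for _, step in self.wrap_artifacts:
            if not -180.0 < step <= 180.0 or step == 0:
                raise ValueError(
                    "wrap artifact steps must be nonzero and within (−180, 180]: "
                    "an orientation stream cannot encode a larger step"
                )


@dataclass
class GroundTruth:
    """What the generator actually injected, for closed-loop verification."""

    euler_truth: EulerTrace  # true motion on the uniform grid, artifacts excluded
    injected_discontinuity_indices: list[int]
    band_power_truth: dict[str, list[tuple[float, float]]]  # channel -> (freq, A²/2)


@dataclass
class StudyFixture:
    """In-memory bundle: one full eight-session study for eight participants."""

    plan: SegmentPlan
    recordings: dict[tuple[str, int, str], tuple[OrientationRecording, GroundTruth]]
    responses: list[ScaleResponse]
    seed: int


def _channel_signals(spec: MotionSpec, rng: np.random.Generator, n: int):
    """Uniform-grid truth per channel plus closures to evaluate at any t."""
    grid = np.arange(n) / spec.rate
    drift = {ch: np.cumsum(rng.normal(0.0, spec.drift_sd, n)) for ch in CHANNELS}

    def evaluate(ch: str, t: np.ndarray) -> np.ndarray:
        out = np.interp(t, grid, drift[ch])
        for c, f, amp, phase in spec.components:
            if c == ch:
                out = out + amp * np.sin(2 * np.pi * f * t + np.radians(phase))
        for t_s, c, step in spec.saccades:
            if c == ch:
                out = out + step * (t >= t_s)
        return out

    return grid, evaluate


def generate_recording(spec: MotionSpec) -> tuple[OrientationRecording, GroundTruth]:
    """Synthesize one quaternion recording and its ground truth."""
    n = int(round(spec.duration * spec.rate))
    if n < 4:
        raise ValueError("duration too short for the requested rate")
    rng = np.random.default_rng(spec.seed)
    grid, evaluate = _channel_signals(spec, rng, n)

    # truth on the uniform grid (the motion the analysis should recover)
    truth = EulerTrace(
        t0=0.0,
        rate=spec.rate,
        yaw=evaluate("yaw", grid),
        pitch=evaluate("pitch", grid),
        roll=evaluate("roll", grid),
    )

    # jittered acquisition timestamps (strictly increasing by construction)
    max_jitter = 0.45 / spec.rate
    jitter = np.clip(rng.normal(0.0, spec.jitter_sd, n), -max_jitter, max_jitter)
    jitter[0] = abs(jitter[0])
    t = grid + jitter

    euler = np.column_stack([evaluate(ch, t) for ch in CHANNELS])
    indices: list[int] = []
    for t_s, step in spec.wrap_artifacts:
        euler[:, 0] += step * (t >= t_s)
        indices.append(int(np.searchsorted(grid, t_s)))

    quats = euler_array_to_quat_yzx(euler)
    rec = OrientationRecording(t=t, quats=quats, nominal_rate=spec.rate)

    band_truth: dict[str, list[tuple[float, float]]] = {ch: [] for ch in CHANNELS}
    for ch, f, amp, _ in spec.components:
        band_truth[ch].append((f, amp * amp / 2.0))
    return rec, GroundTruth(
        euler_truth=truth,
        injected_discontinuity_indices=sorted(indices),
        band_power_truth=band_truth,
    )


def generate_scale_items(scale: str, target_score: float, seed: int = 0) -> list[int]:
    """A valid random item vector scoring exactly ``target_score``.

    SWLS: five 1–7 items summing to the (integer) target.  MAAS: fifteen
    1–6 items whose mean is within 1/30 of the target, so it rounds to the
    target at one decimal.  MMSE: the total itself.
    """
    rng = np.random.default_rng(seed)
    if scale == "SWLS":
        count, lo, hi = 5, 1, 7
        total = int(round(target_score))
        if total != target_score or not count * lo <= total <= count * hi:
            raise ValueError(f"unachievable SWLS target {target_score!r}")
    elif scale == "MAAS":
        count, lo, hi = 15, 1, 6
        total = int(round(target_score * count))
        if not (lo <= target_score <= hi) or not count * lo <= total <= count * hi:
            raise ValueError(f"unachievable MAAS target {target_score!r}")
    elif scale == "MMSE":
        total = int(round(target_score))
        if total != target_score or not 0 <= total <= 30:
            raise ValueError(f"unachievable MMSE target {target_score!r}")
        return [total]
    else:
        raise ValueError(f"unknown scale {scale!r}")

    items = np.full(count, lo, dtype=int)
    deficit = total - count * lo
    while deficit > 0:
        open_slots = np.flatnonzero(items < hi)
        take = rng.choice(open_slots)
        items[take] += 1
        deficit -= 1
    return [int(v) for v in items]


# ---------------------------------------------------------------------------
# the eight-participant study fixture
# ---------------------------------------------------------------------------

_TURB_FREQ = 0.6  # Hz, above both analysis cut-offs (0.34 / 0.44)

#: gaze sweep (channel, freq, amplitude) per group; patients move about half
#: the employees' range, matching the reported ±40° vs ±20° yaw regimes.
_GAZE = {
    "employee": [("yaw", 0.09, 28.0), ("roll", 0.13, 5.0), ("pitch", 0.21, 4.0)],
    "patient": [("yaw", 0.11, 14.0), ("roll", 0.15, 2.5), ("pitch", 0.19, 3.0)],
}

#: overall gaze scale factors producing the designed motion-curve-area
#: changes in the matched sitting/poem segments (area scales ~quadratically,
#: so the factor is ~sqrt of the target area ratio).
_AREA_FACTORS = {
    ("employee", 6, "fireplace", "sitting"): 0.8775,  # ≈ −23% area vs session 5
    ("patient", 6, "fireplace", "sitting"): 1.0817,  # ≈ +17%
    ("employee", 7, "bonnet", "poem-reading"): 0.5292,  # ≈ −72%
}


def _turbulence_amp(group: str, session: int, environment: str, activity: str) -> float:
    """High-band (0.6 Hz) amplitude schedule, degrees.

    Employees calm down across sessions in the 360-degree videos (dooney,
    bonnet); patients calm down in the rendered VEs and in the sitting
    practices; everything else stays level.
    """
    if group == "employee":
        if environment in ("dooney", "bonnet"):
            return 6.0 * 0.85 ** (session - 1)
        return 3.0
    if activity == "sitting" or environment in ("fireplace", "mountain"):
        return 5.0 * 0.8 ** (session - 1)
    return 2.5


def _segment_spec(
    group: str,
    session: int,
    environment: str,
    activity: str,
    duration: float,
    rate: float,
    seed: int,
    with_artifact: bool,
) -> MotionSpec:
    gaze_scale = _AREA_FACTORS.get((group, session, environment, activity), 1.0)
    rng = np.random.default_rng(seed)
    components = [
        (ch, f, amp * gaze_scale, float(rng.uniform(0, 360)))
        for ch, f, amp in _GAZE[group]
    ]
    turb = _turbulence_amp(group, session, environment, activity)
    components.append(("yaw", _TURB_FREQ, turb, float(rng.uniform(0, 360))))
    components.append(("pitch", 0.71, 0.3 * turb, float(rng.uniform(0, 360))))
    artifacts = [(0.4 * duration, WRAP_STEP_DEG)] if with_artifact else []
    return MotionSpec(
        duration=duration,
        rate=rate,
        components=components,
        wrap_artifacts=artifacts,
        seed=seed,
    )


def _stable_seed(seed: int, *parts: object) -> int:
    return zlib.crc32("/".join(map(str, parts)).encode()) ^ (seed & 0x7FFFFFFF)


def make_study_fixture(
    seed: int,
    segment_duration: float = 30.0,
    rate: float = 50.0,
    plan: SegmentPlan | None = None,
) -> StudyFixture:
    """Build the full eight-participant study with known ground truth.

    Segment recordings are ``segment_duration`` seconds each (a scaled-down
    stand-in for the multi-minute program segments).  Questionnaire
    responses are item vectors generated to reproduce the published
    per-participant scores exactly.  The first session's Dooney Rock body
    scan carries one injected tracking re-reference artifact per
    participant, exercising the repair stage inside a realistic run.
    """
    plan = plan or default_plan()
    participants = [("patient", f"patient{i}") for i in range(1, 5)] + [
        ("employee", f"employee{i}") for i in range(1, 5)
    ]

    recordings: dict[tuple[str, int, str], tuple[OrientationRecording, GroundTruth]] = {}
    for group, pid in participants:
        for session, seg in plan.iter_segments():
            label = segment_label(seg.environment, seg.activity)
            with_artifact = session == 1 and seg.activity == "body-scan"
            spec = _segment_spec(
                group,
                session,
                seg.environment,
                seg.activity,
                segment_duration,
                rate,
                _stable_seed(seed, pid, session, label),
                with_artifact,
            )
            rec, truth = generate_recording(spec)
            rec.participant = pid
            rec.session = session
            rec.segment = label
            recordings[(pid, session, label)] = (rec, truth)

    responses = [
        ScaleResponse(
            participant=row.participant,
            group=row.group,
            timepoint=row.timepoint,
            scale=row.scale,
            items=tuple(
                generate_scale_items(
                    row.scale,
                    row.score,
                    _stable_seed(seed, row.participant, row.scale, row.timepoint),
                )
            ),
        )
        for row in STUDY_OUTCOMES.itertuples()
    ]
    return StudyFixture(plan=plan, recordings=recordings, responses=responses, seed=seed)


def write_fixture(fixture: StudyFixture, out_dir: str | Path) -> Path:
    """Write the fixture as ``participant/sessionNN/segment.csv`` plus
    ``responses.csv`` (item level), the on-disk layout the pipeline reads."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for (pid, session, label), (rec, _) in sorted(fixture.recordings.items()):
        seg_dir = out_dir / pid / f"session{session:02d}"
        seg_dir.mkdir(parents=True, exist_ok=True)
        write_recording(rec, seg_dir / f"{label}.csv")

    rows = []
    for resp in sorted(
        fixture.responses, key=lambda r: (r.participant, r.scale, r.timepoint)
    ):
        for idx, value in enumerate(resp.items, start=1):
            rows.append(
                {
                    "participant": resp.participant,
                    "group": resp.group,
                    "timepoint": resp.timepoint,
                    "scale": resp.scale,
                    "item_index": idx,
                    "value": value,
                }
            )
    pd.DataFrame(rows).to_csv(out_dir / "responses.csv", index=False)
    return out_dir
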