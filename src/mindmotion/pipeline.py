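"""Study orchestration: load recordings, condition, measure, compare, report.

The stages for every session segment, in order: read the quaternion CSV →
convert to a uniform Euler trace → repair discontinuities → zero-phase
low-pass → trim filter edges → time-domain summary (ranges, yaw–roll curve
area) and yaw power spectrum.  Matched segment pairs from the comparison
plan then yield an area change and a high-band spectral verdict per
participant, with the group-specific cut-off frequency.

Reports are deterministic for fixed inputs and configuration (provenance
carries the config hash and package version, never a wall clock), so two
runs of the same study are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .conditioning import FilterSpec, condition_trace
from .kinematics import EulerTrace, read_recording, to_euler_trace
from .metrics import (
    covariance_ellipse_area,
    percent_area_change,
    summarize_trace,
    yaw_roll_curve_area,
)
from .program import Comparison, SegmentRef, default_plan
from .spectral import compare_channels

__all__ = [
    "PipelineConfig",
    "StudyReport",
    "load_config",
    "run_study",
    "write_report",
    "report_json_schema",
]

log = logging.getLogger("mindmotion")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ParticipantCfg(_Strict):
    id: str
    group: str


class FilterCfg(_Strict):
    cutoff_hz: float = 2.0
    order: int = 4
    zero_phase: bool = True


class DiscontinuityCfg(_Strict):
    threshold_mult: float = 8.0


class SpectralCfg(_Strict):
    f_cut: dict[str, float] = Field(
        default_factory=lambda: {"patient": 0.44, "employee": 0.34}
    )
    negligible_frac: float = 0.2


class SegmentRefCfg(_Strict):
    session: int
    environment: str
    activity: str

    def ref(self) -> SegmentRef:
        return SegmentRef(self.session, self.environment, self.activity)


class ComparisonCfg(_Strict):
    name: str
    earlier: SegmentRefCfg
    later: SegmentRefCfg


class PipelineConfig(_Strict):
    data_dir: str = "."
    participants: list[ParticipantCfg]
    filter: FilterCfg = Field(default_factory=FilterCfg)
    discontinuity: DiscontinuityCfg = Field(default_factory=DiscontinuityCfg)
    spectral: SpectralCfg = Field(default_factory=SpectralCfg)
    area_metric: str = "convex_hull"  # or "covariance_ellipse"
    comparisons: list[ComparisonCfg] | None = None
    seed: int | None = None


def load_config(path: str | Path) -> tuple[PipelineConfig, str]:
    """Parse the YAML config; returns (config, sha256 of the file bytes)."""
    path = Path(path)
    raw = path.read_bytes()
    data = yaml.safe_load(raw) or {}
    try:
        cfg = PipelineConfig.model_validate(data)
    except ValidationError as exc:
        valid = ", ".join(sorted(PipelineConfig.model_fields))
        raise ValueError(f"invalid config {path}: {exc}\nvalid top-level keys: {valid}") from exc
    if cfg.area_metric not in ("convex_hull", "covariance_ellipse"):
        raise ValueError(
            f"invalid config {path}: area_metric must be 'convex_hull' or "
            f"'covariance_ellipse', got {cfg.area_metric!r}"
        )
    return cfg, hashlib.sha256(raw).hexdigest()


# ---------------------------------------------------------------------------
# report schema
# ---------------------------------------------------------------------------


class SegmentReport(_Strict):
    session: int
    segment: str
    n_samples: int
    duration: float
    range_yaw: float
    range_pitch: float
    range_roll: float
    curve_area: float
    discontinuities: dict[str, int]


class ComparisonReport(_Strict):
    name: str
    earlier_session: int
    later_session: int
    earlier_segment: str
    later_segment: str
    f_cut: float
    power_earlier: float
    power_later: float
    ratio: float | None  # None encodes the +inf sentinel (zero baseline)
    verdict: str
    area_earlier: float
    area_later: float
    percent_area_change: float | None


class ParticipantReport(_Strict):
    participant: str
    group: str
    segments: list[SegmentReport]
    comparisons: list[ComparisonReport]


class Provenance(_Strict):
    config_sha256: str
    version: str
    seed: int | None


class StudyReport(_Strict):
    provenance: Provenance
    participants: list[ParticipantReport]
    warnings: list[str]
    complete: bool


def report_json_schema() -> dict:
    """JSON schema of the study report (shipped as schemas/report.schema.json)."""
    return StudyReport.model_json_schema()


# ---------------------------------------------------------------------------
# execution
# ---------------------------------------------------------------------------


def _segment_path(data_dir: Path, pid: str, ref: SegmentRef) -> Path:
    return data_dir / pid / f"session{ref.session:02d}" / f"{ref.label}.csv"


def _area(trace: EulerTrace, metric: str) -> float:
    if metric == "covariance_ellipse":
        return covariance_ellipse_area(trace)
    return yaw_roll_curve_area(trace)


def run_study(config_path: str | Path) -> StudyReport:
    """Execute the full analysis described by a YAML config.

    Missing segment files produce a warning and exclude the affected
    comparisons (``complete`` turns false); malformed files raise.
    """
    config_path = Path(config_path)
    cfg, cfg_hash = load_config(config_path)
    data_dir = (config_path.parent / cfg.data_dir).resolve()
    plan = default_plan()
    comparisons: list[Comparison] = (
        [Comparison(c.name, c.earlier.ref(), c.later.ref()) for c in cfg.comparisons]
        if cfg.comparisons is not None
        else list(plan.comparisons)
    )
    fspec = FilterSpec(
        cutoff_hz=cfg.filter.cutoff_hz,
        order=cfg.filter.order,
        zero_phase=cfg.filter.zero_phase,
    )

    warnings: list[str] = []
    participants: list[ParticipantReport] = []
    for pcfg in cfg.participants:
        cache: dict[str, EulerTrace] = {}
        segments: list[SegmentReport] = []
        for session, seg in plan.iter_segments():
            ref = SegmentRef(session, seg.environment, seg.activity)
            path = _segment_path(data_dir, pcfg.id, ref)
            if not path.exists():
                msg = f"{pcfg.id}: missing segment file {path.name} (session {session})"
                warnings.append(msg)
                log.warning(msg)
                continue
            rec = read_recording(path)
            trace = to_euler_trace(rec)
            conditioned, reports = condition_trace(
                trace, fspec, cfg.discontinuity.threshold_mult
            )
            cache[f"{session}:{ref.label}"] = conditioned
            summary = summarize_trace(conditioned, ref.label)
            segments.append(
                SegmentReport(
                    session=session,
                    segment=ref.label,
                    n_samples=len(conditioned),
                    duration=round(conditioned.duration, 6),
                    range_yaw=round(summary.range_yaw, 6),
                    range_pitch=round(summary.range_pitch, 6),
                    range_roll=round(summary.range_roll, 6),
                    curve_area=round(_area(conditioned, cfg.area_metric), 6),
                    discontinuities={ch: len(rep) for ch, rep in reports.items()},
                )
            )

        comp_reports: list[ComparisonReport] = []
        f_cut = cfg.spectral.f_cut.get(pcfg.group)
        if f_cut is None:
            raise ValueError(
                f"no spectral.f_cut configured for group {pcfg.group!r} "
                f"(configured: {sorted(cfg.spectral.f_cut)})"
            )
        for comp in comparisons:
            a = cache.get(f"{comp.earlier.session}:{comp.earlier.label}")
            b = cache.get(f"{comp.later.session}:{comp.later.label}")
            if a is None or b is None:
                msg = f"{pcfg.id}: comparison {comp.name!r} skipped (segment missing)"
                warnings.append(msg)
                log.warning(msg)
                continue
            sc = compare_channels(
                a.yaw, b.yaw, a.rate, f_cut, cfg.spectral.negligible_frac
            )
            area_a = _area(a, cfg.area_metric)
            area_b = _area(b, cfg.area_metric)
            pct = percent_area_change(area_a, area_b) if area_a > 0 else None
            comp_reports.append(
                ComparisonReport(
                    name=comp.name,
                    earlier_session=comp.earlier.session,
                    later_session=comp.later.session,
                    earlier_segment=comp.earlier.label,
                    later_segment=comp.later.label,
                    f_cut=f_cut,
                    power_earlier=round(sc.power_a, 9),
                    power_later=round(sc.power_b, 9),
                    ratio=None if np.isinf(sc.ratio) else round(sc.ratio, 9),
                    verdict=sc.verdict,
                    area_earlier=round(area_a, 6),
                    area_later=round(area_b, 6),
                    percent_area_change=None if pct is None else round(pct, 6),
                )
            )
        participants.append(
            ParticipantReport(
                participant=pcfg.id,
                group=pcfg.group,
                segments=segments,
                comparisons=comp_reports,
            )
        )

    return StudyReport(
        provenance=Provenance(config_sha256=cfg_hash, version=__version__, seed=cfg.seed),
        participants=participants,
        warnings=warnings,
        complete=not warnings,
    )


def write_report(report: StudyReport, out_dir: str | Path) -> Path:
    """Write report.json plus tidy CSV views of segments and comparisons."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = report.model_dump()
    (out_dir / "report.json").write_text(
        json.dumps(payload, sort_keys=True, indent=2) + "\n"
    )

    seg_rows = [
        {"participant": p.participant, "group": p.group, **s.model_dump()}
        for p in report.participants
        for s in p.segments
    ]
    comp_rows = [
        {"participant": p.participant, "group": p.group, **c.model_dump()}
        for p in report.participants
        for c in p.comparisons
    ]
    pd.DataFrame(seg_rows).to_csv(out_dir / "segments.csv", index=False)
    pd.DataFrame(comp_rows).to_csv(out_dir / "comparisons.csv", index=False)
    return out_dir / "report.json"
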