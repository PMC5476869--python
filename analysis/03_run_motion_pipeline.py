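#!/usr/bin/env python
"""Run the head-motion pipeline over the simulated study.

Conditioning chain per segment (quaternions → YZX Euler trace → artifact
repair → 2 Hz zero-phase Butterworth → edge trim), then per-segment motion
summaries, and per-participant cross-session comparisons: yaw band power
above the group cut-off (0.34 Hz employees, 0.44 Hz patients) and the
yaw–roll convex-hull area.

Reads scratch/study/ (from 01_simulate_study.py); writes report.json,
segments.csv and comparisons.csv under results/motion/.
"""

from pathlib import Path

import pandas as pd

from mindmotion.pipeline import run_study, write_report

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    config = ROOT / "scratch" / "study" / "config.yaml"
    if not config.exists():
        raise SystemExit("no simulated study found — run 01_simulate_study.py first")
    report = run_study(config)
    out = ROOT / "results" / "motion"
    path = write_report(report, out)

    seg = pd.read_csv(out / "segments.csv")
    n_art = seg["discontinuities"].apply(eval).apply(lambda d: sum(d.values())).sum()
    print(f"wrote {path}")
    print(f"  {len(seg)} segments conditioned; {n_art} discontinuities repaired")
    print(f"  complete: {report.complete}; warnings: {len(report.warnings)}")
    print("\nper-segment yaw range (deg), group means by session:")
    print(
        seg.assign(group=seg.participant.str.rstrip("1234"))
        .pivot_table(index="session", columns="group", values="range_yaw")
        .round(1)
        .to_string()
    )


if __name__ == "__main__":
    main()
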