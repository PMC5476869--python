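"""The eight-session group mindfulness program: which environment and
activity occupy each segment of each weekly session, and which segment
pairs are compared across sessions.

Four settings exist: two rendered virtual environments (a dark *fireplace*
room and an open *mountain* view) and two 360-degree nature videos
(*dooney* — Dooney Rock lakeshore — and *bonnet* — the River Bonnet).
Segments are labelled ``<activity>@<environment>``.  The default comparison
plan pairs segments with the same environment or the same activity across
sessions: the repeated Dooney Rock body scan (sessions 1 vs 8), the
mountain-view practices (2 vs 3), the sitting practices (5 vs 6, 5 vs 7)
and the River Bonnet poem reading (5 vs 7).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "Segment",
    "SegmentRef",
    "Comparison",
    "SegmentPlan",
    "DEFAULT_PROGRAM",
    "DEFAULT_COMPARISONS",
    "default_plan",
    "segment_label",
]

ENVIRONMENTS = ("fireplace", "mountain", "dooney", "bonnet")


@dataclass(frozen=True)
class Segment:
    environment: str
    activity: str
    minutes: float

    def __post_init__(self) -> None:
        if self.environment not in ENVIRONMENTS:
            raise ValueError(f"unknown environment {self.environment!r}")


def segment_label(environment: str, activity: str) -> str:
    return f"{activity}@{environment}"


@dataclass(frozen=True)
class SegmentRef:
    session: int
    environment: str
    activity: str

    @property
    def label(self) -> str:
        return segment_label(self.environment, self.activity)


@dataclass(frozen=True)
class Comparison:
    """A matched pair of segments from an earlier and a later session."""

    name: str
    earlier: SegmentRef
    later: SegmentRef

    def __post_init__(self) -> None:
        same_env = self.earlier.environment == self.later.environment
        same_act = self.earlier.activity == self.later.activity
        if not (same_env or same_act):
            raise ValueError(
                f"comparison {self.name!r} pairs segments sharing neither "
                "environment nor activity"
            )


@dataclass
class SegmentPlan:
    """Program layout plus the cross-session comparison list."""

    sessions: dict[int, list[Segment]]
    comparisons: list[Comparison] = field(default_factory=list)

    def __post_init__(self) -> None:
        for session, segments in self.sessions.items():
            labels = [segment_label(s.environment, s.activity) for s in segments]
            if len(labels) != len(set(labels)):
                raise ValueError(
                    f"session {session} repeats a segment label; labels must be "
                    "unique within a session"
                )
        for comp in self.comparisons:
            for ref in (comp.earlier, comp.later):
                if not self.has_segment(ref):
                    raise ValueError(
                        f"comparison {comp.name!r} references undefined segment "
                        f"session {ref.session} {ref.label}"
                    )

    def has_segment(self, ref: SegmentRef) -> bool:
        return any(
            s.environment == ref.environment and s.activity == ref.activity
            for s in self.sessions.get(ref.session, [])
        )

    def iter_segments(self):
        for session in sorted(self.sessions):
            for seg in self.sessions[session]:
                yield session, seg


DEFAULT_PROGRAM: dict[int, list[Segment]] = {
    1: [
        Segment("fireplace", "intro", 5),
        Segment("dooney", "stone-in-water", 5),
        Segment("fireplace", "discussion", 3),
        Segment("fireplace", "tasting-raisin", 4),
        Segment("dooney", "body-scan", 15),
    ],
    2: [
        Segment("fireplace", "discussion", 3),
        Segment("mountain", "body-scan", 15),
        Segment("mountain", "thoughts-feelings", 5),
    ],
    3: [
        Segment("fireplace", "seeing-hearing", 3),
        Segment("dooney", "movement", 5),
        Segment("fireplace", "discussion", 3),
        Segment("mountain", "breath-body", 10),
    ],
    4: [
        Segment("fireplace", "discussion", 2),
        Segment("mountain", "breath-body-sound", 8),
        Segment("mountain", "stress-response", 5),
        Segment("mountain", "breathing-space", 3),
        Segment("mountain", "poem-reading", 2),
    ],
    5: [
        Segment("fireplace", "sitting", 10),
        Segment("bonnet", "exploring-difficulty", 5),
        Segment("bonnet", "poem-reading", 2),
        Segment("bonnet", "discussion", 3),
    ],
    6: [
        Segment("fireplace", "sitting", 10),
        Segment("mountain", "poem-reading", 2),
        Segment("mountain", "moods-thoughts", 5),
        Segment("mountain", "abc-model", 5),
    ],
    7: [
        Segment("dooney", "sitting", 10),
        Segment("fireplace", "discussion", 3),
        Segment("bonnet", "breathing-space", 3),
        Segment("bonnet", "nurturing-depleting", 5),
        Segment("bonnet", "poem-reading", 2),
    ],
    8: [
        Segment("dooney", "body-scan", 15),
        Segment("fireplace", "discussion", 5),
        Segment("mountain", "stone-in-pond", 5),
    ],
}

DEFAULT_COMPARISONS: list[Comparison] = [
    Comparison(
        "body-scan-dooney-s1-vs-s8",
        SegmentRef(1, "dooney", "body-scan"),
        SegmentRef(8, "dooney", "body-scan"),
    ),
    Comparison(
        "mountain-s2-vs-s3",
        SegmentRef(2, "mountain", "body-scan"),
        SegmentRef(3, "mountain", "breath-body"),
    ),
    Comparison(
        "sitting-s5-vs-s6",
        SegmentRef(5, "fireplace", "sitting"),
        SegmentRef(6, "fireplace", "sitting"),
    ),
    Comparison(
        "sitting-s5-vs-s7",
        SegmentRef(5, "fireplace", "sitting"),
        SegmentRef(7, "dooney", "sitting"),
    ),
    Comparison(
        "poem-bonnet-s5-vs-s7",
        SegmentRef(5, "bonnet", "poem-reading"),
        SegmentRef(7, "bonnet", "poem-reading"),
    ),
]


def default_plan() -> SegmentPlan:
    return SegmentPlan(
        sessions={k: list(v) for k, v in DEFAULT_PROGRAM.items()},
        comparisons=list(DEFAULT_COMPARISONS),
    )
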