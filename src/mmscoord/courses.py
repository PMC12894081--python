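"""Course geometry for simulated mobility-scooter drives.

A course is an ordered list of segments -- straights, constant-curvature
arcs, slalom stretches and slopes -- mirroring the four scenarios used in
outdoor driving evaluation: quarter turn, left curving, slalom driving
and an up/down slope.  Dimensions not fixed by the study protocol
(turn radii, slope grade) are package defaults, declared here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: Default slalom geometry: obstacle interval and path width, metres.
SLALOM_INTERVAL_M = 2.4
SLALOM_WIDTH_M = 1.2

#: Kinematic bicycle wheelbase, metres (typical four-wheel scooter).
DEFAULT_WHEELBASE_M = 0.8

SEGMENT_KINDS = ("straight", "arc", "slalom", "slope")

COURSE_NAMES = ("quarter_turn", "left_curving", "slalom", "up_down_slope",
                "full_circuit")


@dataclass(frozen=True)
class Segment:
    """One course element.

    kind : 'straight' | 'arc' | 'slalom' | 'slope'
    length : arc length along the path, m (> 0)
    curvature : signed path curvature for arcs, 1/m; positive = leftward
    grade : signed slope, percent rise over run
    slalom_interval : obstacle spacing for slalom segments, m
    slalom_width : lateral path width for slalom segments, m
    """

    kind: str
    length: float
    curvature: float = 0.0
    grade: float = 0.0
    slalom_interval: float = SLALOM_INTERVAL_M
    slalom_width: float = SLALOM_WIDTH_M

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.length <= 0:
            raise ValueError("segment length must be > 0")
        if abs(self.curvature) >= 1.0 / DEFAULT_WHEELBASE_M:
            raise ValueError(
                f"|curvature| must be < 1/wheelbase = {1.0 / DEFAULT_WHEELBASE_M} 1/m"
            )
        if self.kind == "slalom" and (self.slalom_interval <= 0 or self.slalom_width <= 0):
            raise ValueError("slalom interval and width must be > 0")


@dataclass(frozen=True)
class CourseSpec:
    """Named, ordered sequence of segments."""

    name: str
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("course must contain at least one segment")
        object.__setattr__(self, "segments", tuple(self.segments))

    @property
    def length(self) -> float:
        return sum(s.length for s in self.segments)


def _quarter_turn_segments(radius: float = 2.0) -> tuple[Segment, ...]:
    # one 90 deg left arc bounded by straights
    return (
        Segment("straight", 5.0),
        Segment("arc", math.pi / 2 * radius, curvature=1.0 / radius),
        Segment("straight", 5.0),
    )


def _left_curving_segments(radius: float = 4.0) -> tuple[Segment, ...]:
    # gentler, longer left arc (90 deg at twice the quarter-turn radius)
    return (
        Segment("straight", 3.0),
        Segment("arc", math.pi / 2 * radius, curvature=1.0 / radius),
        Segment("straight", 3.0),
    )


def _slalom_segments(n_gates: int = 6) -> tuple[Segment, ...]:
    return (
        Segment("straight", 3.0),
        Segment("slalom", n_gates * SLALOM_INTERVAL_M),
        Segment("straight", 3.0),
    )


def _up_down_slope_segments(grade: float = 5.0, ramp: float = 6.0) -> tuple[Segment, ...]:
    return (
        Segment("straight", 3.0),
        Segment("slope", ramp, grade=grade),
        Segment("slope", ramp, grade=-grade),
        Segment("straight", 3.0),
    )


def build_course(name: str) -> CourseSpec:
    """Return the parameterised course for one of the driving scenarios.

    ``full_circuit`` concatenates the four scenarios joined by short
    straight connectors.  An unknown name raises ``ValueError`` listing
    the valid names.
    """
    builders = {
        "quarter_turn": _quarter_turn_segments,
        "left_curving": _left_curving_segments,
        "slalom": _slalom_segments,
        "up_down_slope": _up_down_slope_segments,
    }
    if name in builders:
        return CourseSpec(name, builders[name]())
    if name == "full_circuit":
        connector = Segment("straight", 3.0)
        segs: list[Segment] = []
        for i, part in enumerate(("quarter_turn", "left_curving", "slalom",
                                  "up_down_slope")):
            if i:
                segs.append(connector)
            segs.extend(builders[part]())
        return CourseSpec("full_circuit", tuple(segs))
    raise ValueError(
        f"unknown course {name!r}; valid names: {', '.join(COURSE_NAMES)}"
    )
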