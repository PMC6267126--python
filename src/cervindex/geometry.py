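"""Landmark geometry for sagittal cervical-spine radiographs.

All constructions live in a 2-D sagittal plane with +x pointing anterior,
+y pointing superior, units millimetres.  Landmarks are digitized vertebral
corner points, endplate endpoints and spinal-canal point pairs for C2-C7;
from these we derive, per motion segment and view, the five radiographic
measurements the index method is built on:

* anterior / posterior intervertebral space heights (A, B),
* central height of the inferior vertebral body (C),
* angular displacement between adjacent endplates,
* signed horizontal displacement of the upper vertebra (anterolisthesis > 0),
* sagittal diameter of the spinal canal.

The digitization protocol repeats every measurement up to three times;
repeats are averaged first and the average is then rounded once --
lengths to the nearest 0.01 mm, angles to the nearest degree, ties away
from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "LEVELS",
    "SEGMENTS",
    "VIEWS",
    "GROUPS",
    "GeometryError",
    "IncompleteSegmentError",
    "Point",
    "CanalCandidate",
    "VertebraLandmarks",
    "ViewAnnotation",
    "SegmentMeasurement",
    "anterior_space_height",
    "posterior_space_height",
    "central_height",
    "angular_displacement",
    "signed_angular_displacement",
    "horizontal_displacement",
    "canal_sagittal_diameter",
    "round_half_away",
    "average_repeats",
    "measure_segment",
    "measure_view",
    "segment_levels",
]

LEVELS: tuple[str, ...] = ("C2", "C3", "C4", "C5", "C6", "C7")
SEGMENTS: tuple[str, ...] = ("C2/C3", "C3/C4", "C4/C5", "C5/C6", "C6/C7")
VIEWS: tuple[str, ...] = ("neutral", "flexion", "extension")
GROUPS: tuple[str, ...] = ("I", "II", "III")

#: protocol rounding increments
LENGTH_INCREMENT = 0.01  # mm
ANGLE_INCREMENT = 1.0  # degrees


class GeometryError(ValueError):
    """Corrupt or degenerate landmark geometry."""


class IncompleteSegmentError(GeometryError):
    """A landmark required for a segment measurement is missing."""


@dataclass(frozen=True)
class Point:
    """A 2-D sagittal-plane point in mm (+x anterior, +y superior)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise GeometryError(f"non-finite point coordinates ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


def _dist(p: Point, q: Point) -> float:
    return math.hypot(p.x - q.x, p.y - q.y)


@dataclass(frozen=True)
class CanalCandidate:
    """One candidate point pair for the sagittal canal diameter.

    ``body_point`` sits on the posterior vertebral-body surface,
    ``canal_point`` on the spinolaminar line (or, for osteophyte-aware
    candidates, the innermost canal point clear of the osteophyte).
    """

    body_point: Point
    canal_point: Point
    osteophyte_aware: bool = False

    @property
    def length(self) -> float:
        return _dist(self.body_point, self.canal_point)


@dataclass
class VertebraLandmarks:
    """Digitized landmarks of one vertebra in one view.

    Corner points may be ``None`` when the digitizer could not place them;
    any measurement that needs a missing corner raises
    :class:`IncompleteSegmentError` so the segment can be flagged rather
    than silently defaulted.
    """

    level: str
    anterosuperior: Optional[Point] = None
    anteroinferior: Optional[Point] = None
    posterosuperior: Optional[Point] = None
    posteroinferior: Optional[Point] = None
    canal_candidates: tuple[CanalCandidate, ...] = ()
    osteophyte_flag: bool = False

    def corner(self, name: str) -> Point:
        p = getattr(self, name)
        if p is None:
            raise IncompleteSegmentError(f"{self.level}: missing {name} corner")
        return p

    @property
    def corners(self) -> dict[str, Optional[Point]]:
        return {
            "anterosuperior": self.anterosuperior,
            "anteroinferior": self.anteroinferior,
            "posterosuperior": self.posterosuperior,
            "posteroinferior": self.posteroinferior,
        }

    def has_all_corners(self) -> bool:
        return all(v is not None for v in self.corners.values())


@dataclass
class ViewAnnotation:
    """All vertebra landmarks of one subject, view and repeat digitization."""

    subject_id: str
    group: str
    view: str
    repeat_id: int
    vertebrae: dict[str, VertebraLandmarks] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise ValueError(f"unknown view {self.view!r}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if not 1 <= int(self.repeat_id) <= 3:
            raise ValueError(f"repeat_id must be 1..3, got {self.repeat_id}")


@dataclass
class SegmentMeasurement:
    """Protocol-rounded measurements for one motion segment in one view.

    ``A``/``B`` are the anterior/posterior intervertebral space heights,
    ``C`` the central height of the inferior vertebra; the canal diameter
    is that of the inferior vertebra ("corresponding" canal).  Incomplete
    segments carry NaNs with ``complete=False``.
    """

    segment: str
    A: float = math.nan
    B: float = math.nan
    C: float = math.nan
    angular_displacement: float = math.nan
    horizontal_displacement: float = math.nan
    canal_diameter: float = math.nan
    complete: bool = True


# ---------------------------------------------------------------------------
# elementary measurements (single repeat, unrounded)
# ---------------------------------------------------------------------------

def anterior_space_height(upper: VertebraLandmarks, lower: VertebraLandmarks) -> float:
    """Height A of the anterior intervertebral space (mm)."""
    return _dist(upper.corner("anteroinferior"), lower.corner("anterosuperior"))


def posterior_space_height(upper: VertebraLandmarks, lower: VertebraLandmarks) -> float:
    """Height B of the posterior intervertebral space (mm)."""
    return _dist(upper.corner("posteroinferior"), lower.corner("posterosuperior"))


def central_height(v: VertebraLandmarks) -> float:
    """Central vertebral body height: distance between endplate midpoints."""
    s_mid = _midpoint(v.corner("anterosuperior"), v.corner("posterosuperior"))
    i_mid = _midpoint(v.corner("anteroinferior"), v.corner("posteroinferior"))
    h = _dist(s_mid, i_mid)
    if h <= 0.0:
        raise GeometryError(f"{v.level}: degenerate vertebra (zero central height)")
    return h


def _midpoint(p: Point, q: Point) -> Point:
    return Point((p.x + q.x) / 2.0, (p.y + q.y) / 2.0)


def _endplate_direction(a: Point, b: Point, label: str) -> tuple[float, float]:
    dx, dy = b.x - a.x, b.y - a.y
    n = math.hypot(dx, dy)
    if n == 0.0:
        raise GeometryError(f"zero-length endplate segment ({label})")
    return dx / n, dy / n


def signed_angular_displacement(
    upper: VertebraLandmarks,
    lower: VertebraLandmarks,
    convention: str = "shared_disc",
) -> float:
    """Signed angle (degrees, in (-90, 90]) between adjacent endplate lines.

    ``shared_disc`` compares the inferior endplate of the upper vertebra
    with the superior endplate of the lower one (the two plates bounding
    the shared disc); ``inferior_inferior`` compares the two inferior
    endplates (a segmental Cobb convention).  Positive means the upper
    plate is rotated towards extension (anterior opening) relative to the
    lower plate.
    """
    u = _endplate_direction(
        upper.corner("posteroinferior"), upper.corner("anteroinferior"),
        f"{upper.level} inferior endplate",
    )
    if convention == "shared_disc":
        l = _endplate_direction(
            lower.corner("posterosuperior"), lower.corner("anterosuperior"),
            f"{lower.level} superior endplate",
        )
    elif convention == "inferior_inferior":
        l = _endplate_direction(
            lower.corner("posteroinferior"), lower.corner("anteroinferior"),
            f"{lower.level} inferior endplate",
        )
    else:
        raise ValueError(f"unknown endplate convention {convention!r}")
    cross = l[0] * u[1] - l[1] * u[0]
    ang = math.degrees(math.atan2(cross, l[0] * u[0] + l[1] * u[1]))
    # lines, not rays: fold to (-90, 90]
    if ang > 90.0:
        ang -= 180.0
    elif ang <= -90.0:
        ang += 180.0
    return ang


def angular_displacement(
    upper: VertebraLandmarks,
    lower: VertebraLandmarks,
    convention: str = "shared_disc",
) -> float:
    """Unsigned acute angle in [0, 90] degrees between adjacent endplates."""
    return abs(signed_angular_displacement(upper, lower, convention))


def horizontal_displacement(upper: VertebraLandmarks, lower: VertebraLandmarks) -> float:
    """Signed horizontal (sagittal-translation) displacement in mm.

    Perpendicular distance from the posteroinferior corner of the upper
    vertebra to the posterior-margin line of the lower vertebra (through
    its posterosuperior and posteroinferior corners).  Positive when the
    corner lies anterior to the line (anterolisthesis), negative posterior
    (retrolisthesis).

    "Anterior" is resolved in the image frame (+x): the convention is
    stable as long as the vertebral chain stays within 90 degrees of the
    upright orientation a lateral radiograph is acquired in, and mirroring
    the film flips the sign.
    """
    ps = lower.corner("posterosuperior")
    pi = lower.corner("posteroinferior")
    dx, dy = pi.x - ps.x, pi.y - ps.y
    nrm = math.hypot(dx, dy)
    if nrm == 0.0:
        raise GeometryError(f"{lower.level}: coincident posterior corners")
    dx, dy = dx / nrm, dy / nrm
    # unit normal oriented towards anatomical anterior (+x where possible)
    nx, ny = -dy, dx
    if nx < 0.0 or (nx == 0.0 and ny < 0.0):
        nx, ny = -nx, -ny
    p = upper.corner("posteroinferior")
    return (p.x - ps.x) * nx + (p.y - ps.y) * ny


def canal_sagittal_diameter(v: VertebraLandmarks) -> float:
    """Smallest sagittal canal diameter (mm) over the candidate point pairs.

    When the vertebra is osteophyte-flagged, only osteophyte-aware
    candidate pairs (digitized clear of posterior-margin osteophytes or
    ligament calcification) are admissible.
    """
    candidates = v.canal_candidates
    if v.osteophyte_flag:
        candidates = tuple(c for c in candidates if c.osteophyte_aware)
        if not candidates:
            raise GeometryError(
                f"{v.level}: osteophyte flag set but no osteophyte-aware canal pair"
            )
    if not candidates:
        raise IncompleteSegmentError(f"{v.level}: no canal candidate pairs")
    return min(c.length for c in candidates)


# ---------------------------------------------------------------------------
# repeat averaging and protocol rounding
# ---------------------------------------------------------------------------

def round_half_away(x: float, increment: float) -> float:
    """Round to the nearest multiple of ``increment``, ties away from zero.

    The digitization protocol records averaged lengths to 0.01 mm and
    averaged angles to 1 degree.  A tiny tolerance absorbs binary
    floating-point representation of decimal inputs (e.g. 4.005) so that
    intended ties round away from zero.
    """
    if increment <= 0:
        raise ValueError("increment must be positive")
    q = abs(x) / increment
    return math.copysign(math.floor(q + 0.5 + 1e-7) * increment, x)


def average_repeats(values: Sequence[float], kind: str) -> float:
    """Average up to three repeat measurements, then round once.

    ``kind`` is ``"length"`` (0.01 mm grid) or ``"angle"`` (1 degree grid).
    """
    if len(values) == 0:
        raise ValueError("no repeat measurements to average")
    if len(values) > 3:
        raise ValueError("at most 3 repeat digitizations allowed")
    if not all(math.isfinite(v) for v in values):
        raise ValueError("non-finite measurement in repeats")
    mean = sum(values) / len(values)
    if kind == "length":
        return round_half_away(mean, LENGTH_INCREMENT)
    if kind == "angle":
        return round_half_away(mean, ANGLE_INCREMENT)
    raise ValueError(f"unknown measurement kind {kind!r}")


# ---------------------------------------------------------------------------
# per-segment / per-view measurement
# ---------------------------------------------------------------------------

def segment_levels(segment: str) -> tuple[str, str]:
    """Split 'C4/C5' into its (upper, lower) vertebra levels."""
    upper, lower = segment.split("/")
    return upper, lower


def measure_segment(
    upper: VertebraLandmarks,
    lower: VertebraLandmarks,
    angle_convention: str = "shared_disc",
) -> SegmentMeasurement:
    """Raw (unrounded) single-repeat measurements for one motion segment."""
    return SegmentMeasurement(
        segment=f"{upper.level}/{lower.level}",
        A=anterior_space_height(upper, lower),
        B=posterior_space_height(upper, lower),
        C=central_height(lower),
        angular_displacement=angular_displacement(upper, lower, angle_convention),
        horizontal_displacement=horizontal_displacement(upper, lower),
        canal_diameter=canal_sagittal_diameter(lower),
    )


def measure_view(
    repeats: Sequence[ViewAnnotation],
    angle_convention: str = "shared_disc",
) -> dict[str, SegmentMeasurement]:
    """Protocol measurements for one subject-view from its repeat digitizations.

    Each of the five C2/C3..C6/C7 segments is measured on every repeat;
    the repeats are averaged and rounded per protocol.  A missing landmark
    invalidates only the affected segment, which is returned with NaNs and
    ``complete=False``.
    """
    if not repeats:
        raise ValueError("no repeat annotations supplied")
    key = {(r.subject_id, r.view) for r in repeats}
    if len(key) != 1:
        raise ValueError(f"repeats mix subjects/views: {sorted(key)}")

    out: dict[str, SegmentMeasurement] = {}
    for seg in SEGMENTS:
        up_level, lo_level = segment_levels(seg)
        per_repeat: list[SegmentMeasurement] = []
        incomplete = False
        for rep in repeats:
            up = rep.vertebrae.get(up_level)
            lo = rep.vertebrae.get(lo_level)
            if up is None or lo is None:
                incomplete = True
                break
            try:
                per_repeat.append(measure_segment(up, lo, angle_convention))
            except IncompleteSegmentError:
                incomplete = True
                break
        if incomplete or not per_repeat:
            out[seg] = SegmentMeasurement(segment=seg, complete=False)
            continue
        out[seg] = SegmentMeasurement(
            segment=seg,
            A=average_repeats([m.A for m in per_repeat], "length"),
            B=average_repeats([m.B for m in per_repeat], "length"),
            C=average_repeats([m.C for m in per_repeat], "length"),
            angular_displacement=average_repeats(
                [m.angular_displacement for m in per_repeat], "angle"
            ),
            horizontal_displacement=average_repeats(
                [m.horizontal_displacement for m in per_repeat], "length"
            ),
            canal_diameter=average_repeats(
                [m.canal_diameter for m in per_repeat], "length"
            ),
        )
    return out
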