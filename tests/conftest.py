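"""Shared fixtures: simple analytic geometries and small synthetic cohorts."""

from __future__ import annotations

import math

import numpy as np
import pytest

from cervindex.geometry import (
    LEVELS,
    SEGMENTS,
    VIEWS,
    CanalCandidate,
    Point,
    VertebraLandmarks,
    ViewAnnotation,
)
from cervindex.simulate import (
    GeneratorConfig,
    SubjectParameters,
    default_config,
    generate_cohort,
)


def rect_vertebra(
    level: str,
    x0: float,
    y0: float,
    width: float = 15.0,
    height: float = 10.0,
    canal: float = 13.0,
) -> VertebraLandmarks:
    """Axis-aligned rectangular vertebra with posterior wall at x = x0."""
    return VertebraLandmarks(
        level=level,
        posteroinferior=Point(x0, y0),
        posterosuperior=Point(x0, y0 + height),
        anteroinferior=Point(x0 + width, y0),
        anterosuperior=Point(x0 + width, y0 + height),
        canal_candidates=(
            CanalCandidate(Point(x0, y0 + height / 2), Point(x0 - canal, y0 + height / 2)),
        ),
    )


def transform_annotation(
    ann: ViewAnnotation,
    angle_deg: float = 0.0,
    dx: float = 0.0,
    dy: float = 0.0,
    scale: float = 1.0,
    reflect_x: bool = False,
) -> ViewAnnotation:
    """Apply scale, reflection about the y-axis, rotation and translation."""
    th = math.radians(angle_deg)
    c, s = math.cos(th), math.sin(th)

    def tp(p: Point) -> Point:
        x, y = p.x * scale, p.y * scale
        if reflect_x:
            x = -x
        return Point(c * x - s * y + dx, s * x + c * y + dy)

    vertebrae = {}
    for level, v in ann.vertebrae.items():
        vertebrae[level] = VertebraLandmarks(
            level=v.level,
            anterosuperior=tp(v.anterosuperior) if v.anterosuperior else None,
            anteroinferior=tp(v.anteroinferior) if v.anteroinferior else None,
            posterosuperior=tp(v.posterosuperior) if v.posterosuperior else None,
            posteroinferior=tp(v.posteroinferior) if v.posteroinferior else None,
            canal_candidates=tuple(
                CanalCandidate(tp(cc.body_point), tp(cc.canal_point), cc.osteophyte_aware)
                for cc in v.canal_candidates
            ),
            osteophyte_flag=v.osteophyte_flag,
        )
    return ViewAnnotation(
        subject_id=ann.subject_id,
        group=ann.group,
        view=ann.view,
        repeat_id=ann.repeat_id,
        vertebrae=vertebrae,
    )


def flat_subject_params(
    sci: float = 0.0,
    hdi_flexion: float = 0.0,
    hdi_extension: float = 0.0,
    height: float = 15.0,
    canal: float = 13.0,
    disc: float = 6.0,
) -> SubjectParameters:
    """Uniform per-segment targets for deterministic round-trip checks."""
    return SubjectParameters(
        heights={lv: height for lv in LEVELS},
        canals={lv: canal for lv in LEVELS},
        base_width=16.0,
        disc_height=disc,
        sci={v: {s: sci for s in SEGMENTS} for v in VIEWS},
        hdi={
            "neutral": {s: 0.0 for s in SEGMENTS},
            "flexion": {s: hdi_flexion for s in SEGMENTS},
            "extension": {s: hdi_extension for s in SEGMENTS},
        },
        signs={
            "neutral": {s: 1 for s in SEGMENTS},
            "flexion": {s: 1 for s in SEGMENTS},
            "extension": {s: -1 for s in SEGMENTS},
        },
    )


def small_config(n: int = 6, seed: int | None = None) -> GeneratorConfig:
    """Default study targets on a reduced cohort for fast tests."""
    cfg = default_config(seed=seed)
    for g in cfg.groups.values():
        g.n_subjects = n
    return cfg


@pytest.fixture(scope="session")
def default_cohort():
    """Full 62/59/62 default cohort, seed 1 (shared; treat as read-only)."""
    return generate_cohort(default_config(), seed=1)


@pytest.fixture(scope="session")
def default_cohort_tables(default_cohort):
    from cervindex.pipeline import compute_indices, measure_cohort

    meas = measure_cohort(default_cohort.annotations)
    seg, subj = compute_indices(meas)
    return meas, seg, subj
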