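"""Synthetic landmark cohorts with controlled index distributions.

The generator inverts the measurement constructions: given target
segmental curvature indices and horizontal displacement indices per view,
it builds a C2-C7 chain of quadrilateral vertebral bodies stacked along a
curve so that, measured with the landmark pipeline at zero noise, every
index equals its injected value exactly (up to protocol rounding).  Group
defaults emulate a three-group clinical cohort (62 neurological-deficit
patients, 59 neck-pain-only patients, 62 healthy controls) whose
curvature, range-of-motion and displacement indices follow the published
group distributions; anatomy priors (vertebral height ~15 mm, canal
~13.5 mm) are generic adult cervical values and are nuisance parameters,
since the indices are size-free.

Exactness of the inverse construction
-------------------------------------
For a segment with inferior central height ``C``, disc height ``D`` and
targets ``sci`` and ``hdi`` (with listhesis sign ``s`` and canal ``c``),
the anterior/posterior space heights are set to ``A = D + sci*C/2`` and
``B = D - sci*C/2`` and the translation to ``t = s*hdi*c``.  The upper
vertebra's inferior corners are placed at

    PI_up = PS_low + t*u + sqrt(B^2 - t^2)*v
    AI_up = AS_low + t*u + sqrt(A^2 - t^2)*v

in the lower vertebra's orthonormal endplate frame (u anterior, v
superior), so the measured corner distances are exactly A and B and the
measured perpendicular offset exactly t.  Stochastic draws are clipped to
the feasible region (|t| < B, positive disc heights); deterministic
infeasible targets raise :class:`InfeasibleTargetError` naming the
segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import (
    GROUPS,
    LEVELS,
    SEGMENTS,
    VIEWS,
    CanalCandidate,
    Point,
    VertebraLandmarks,
    ViewAnnotation,
    segment_levels,
)

__all__ = [
    "InfeasibleTargetError",
    "GroupTargets",
    "GeneratorConfig",
    "SubjectParameters",
    "SyntheticCohort",
    "default_config",
    "build_annotations",
    "generate_subject",
    "generate_cohort",
]


class InfeasibleTargetError(ValueError):
    """Requested index targets cannot be realised as a valid vertebral chain."""


@dataclass
class GroupTargets:
    """Index-scale target distributions for one subject group.

    Tuples are (mean, SD).  ``mhdi`` and ``hdi_neutral`` are truncated at
    zero when drawn; the extension-view curvature follows from the
    flexion curvature plus the range-of-motion draw.
    """

    n_subjects: int
    cci_neutral: tuple[float, float]
    cci_flexion: tuple[float, float]
    rom: tuple[float, float]
    mhdi: dict[str, tuple[float, float]]
    hdi_neutral: tuple[float, float]


@dataclass
class GeneratorConfig:
    """Cohort-level generator settings; anatomy is in mm, noise per landmark."""

    groups: dict[str, GroupTargets]
    vertebral_height: tuple[float, float] = (15.0, 1.0)
    vertebral_width: tuple[float, float] = (16.0, 1.2)
    canal_diameter: tuple[float, float] = (13.5, 1.1)
    disc_height: float = 6.0
    sci_segment_sd: float = 0.05
    landmark_noise_sd: float = 0.2
    repeats: int = 3
    global_rotation_sd_deg: float = 3.0
    flexion_sign: int = +1  # anterolisthesis in flexion
    extension_sign: int = -1  # retrolisthesis in extension
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.repeats < 1 or self.repeats > 3:
            raise ValueError("repeats must be 1..3")
        for name in ("vertebral_height", "vertebral_width", "canal_diameter"):
            mean, sd = getattr(self, name)
            if mean <= 0 or sd < 0:
                raise ValueError(f"{name} needs positive mean and non-negative SD")
        if self.disc_height <= 0:
            raise ValueError("disc_height must be positive")
        if self.landmark_noise_sd < 0 or self.sci_segment_sd < 0:
            raise ValueError("noise SDs must be non-negative")


def default_config(seed: Optional[int] = None) -> GeneratorConfig:
    """Three-group study-condition defaults on the index scale.

    Curvature and ROM targets carry the published group medians/means and
    spreads (spreads recovered from quartiles as IQR/1.349 where only
    quartiles are published); per-segment MHDI targets carry the published
    per-segment means and SDs.  Neutral-view HDI levels are chosen so that
    at the displaced-segment convention tau = 0.10 neutral incidences fall
    in the reported ~18-23% band.
    """
    groups = {
        "I": GroupTargets(
            n_subjects=62,
            cci_neutral=(0.72, 0.36),
            cci_flexion=(-0.06, 0.28),
            rom=(1.19, 0.42),
            mhdi={
                "C2/C3": (0.24, 0.12),
                "C3/C4": (0.33, 0.23),
                "C4/C5": (0.35, 0.14),
                "C5/C6": (0.32, 0.19),
                "C6/C7": (0.33, 0.19),
            },
            hdi_neutral=(0.06, 0.05),
        ),
        "II": GroupTargets(
            n_subjects=59,
            cci_neutral=(0.72, 0.44),
            cci_flexion=(-0.12, 0.17),
            rom=(1.59, 0.49),
            mhdi={
                "C2/C3": (0.20, 0.07),
                "C3/C4": (0.25, 0.10),
                "C4/C5": (0.25, 0.09),
                "C5/C6": (0.20, 0.10),
                "C6/C7": (0.17, 0.08),
            },
            hdi_neutral=(0.05, 0.05),
        ),
        "III": GroupTargets(
            n_subjects=62,
            cci_neutral=(0.82, 0.31),
            cci_flexion=(-0.27, 0.16),
            rom=(1.73, 0.40),
            mhdi={
                "C2/C3": (0.20, 0.07),
                "C3/C4": (0.23, 0.09),
                "C4/C5": (0.24, 0.13),
                "C5/C6": (0.18, 0.09),
                "C6/C7": (0.18, 0.07),
            },
            hdi_neutral=(0.05, 0.05),
        ),
    }
    return GeneratorConfig(groups=groups, seed=seed)


@dataclass
class SubjectParameters:
    """Fully resolved, per-subject geometric and index parameters."""

    heights: dict[str, float]  # central height per level (mm)
    canals: dict[str, float]  # canal diameter per level (mm)
    base_width: float  # endplate width of the C7 base (mm)
    disc_height: float  # mean disc-space height (mm)
    sci: dict[str, dict[str, float]]  # view -> segment -> target SCI
    hdi: dict[str, dict[str, float]]  # view -> segment -> target HDI (>= 0)
    signs: dict[str, dict[str, int]]  # view -> segment -> listhesis sign
    global_angles: dict[str, float] = field(default_factory=dict)  # radians per view


def _rot90(v: np.ndarray) -> np.ndarray:
    return np.array([-v[1], v[0]])


def _build_view_chain(params: SubjectParameters, view: str) -> dict[str, dict]:
    """Clean (noise-free) landmark coordinates for one view.

    Returns level -> {corner name -> (2,) array, 'canal': (body, lamina)}.
    """
    ang = params.global_angles.get(view, 0.0)
    u = np.array([math.cos(ang), math.sin(ang)])
    v = _rot90(u)
    w = params.base_width
    out: dict[str, dict] = {}

    # base vertebra C7: axis-aligned rectangle in its own frame
    h7 = params.heights["C7"]
    pi = np.zeros(2)
    corners = {
        "posteroinferior": pi,
        "posterosuperior": pi + h7 * v,
        "anteroinferior": pi + w * u,
        "anterosuperior": pi + w * u + h7 * v,
    }
    out["C7"] = corners

    for seg in reversed(SEGMENTS):  # C6/C7 first, then upwards to C2/C3
        upper_level, lower_level = segment_levels(seg)
        low = out[lower_level]
        ps, a_s = low["posterosuperior"], low["anterosuperior"]
        ulow = a_s - ps
        ulow = ulow / np.linalg.norm(ulow)
        vlow = _rot90(ulow)

        c_low = params.heights[lower_level]
        sci = params.sci[view][seg]
        a_h = params.disc_height + sci * c_low / 2.0
        b_h = params.disc_height - sci * c_low / 2.0
        if a_h <= 0 or b_h <= 0:
            raise InfeasibleTargetError(
                f"{seg} ({view}): curvature target {sci:+.3f} implies a "
                f"non-positive disc-space height"
            )
        t = params.signs[view][seg] * params.hdi[view][seg] * params.canals[lower_level]
        if abs(t) >= b_h or abs(t) >= a_h:
            raise InfeasibleTargetError(
                f"{seg} ({view}): displacement {t:+.2f} mm exceeds the "
                f"disc-space height; displacement target infeasible"
            )
        pi_up = ps + t * ulow + math.sqrt(b_h**2 - t**2) * vlow
        ai_up = a_s + t * ulow + math.sqrt(a_h**2 - t**2) * vlow
        e = ai_up - pi_up
        e = e / np.linalg.norm(e)
        m = _rot90(e)
        h_up = params.heights[upper_level]
        out[upper_level] = {
            "posteroinferior": pi_up,
            "anteroinferior": ai_up,
            "posterosuperior": pi_up + h_up * m,
            "anterosuperior": ai_up + h_up * m,
        }

    # canal candidate pair per level: posterior body midpoint to the
    # spinolaminar point, straight posterior in the vertebra's own frame
    for level in LEVELS:
        corners = out[level]
        e = corners["anteroinferior"] - corners["posteroinferior"]
        e = e / np.linalg.norm(e)
        bp = (corners["posterosuperior"] + corners["posteroinferior"]) / 2.0
        out[level]["canal"] = (bp, bp - params.canals[level] * e)
    return out


def build_annotations(
    params: SubjectParameters,
    subject_id: str,
    group: str,
    noise_sd: float = 0.0,
    repeats: int = 1,
    rng: Optional[np.random.Generator] = None,
) -> list[ViewAnnotation]:
    """Materialise a subject's landmark annotations (one per view x repeat).

    Independent isotropic Gaussian digitization noise of SD ``noise_sd``
    is added to every landmark of every repeat; ``noise_sd = 0`` yields
    exact geometry for round-trip checks.
    """
    if noise_sd > 0 and rng is None:
        raise ValueError("an explicit rng is required for noisy generation")
    annotations = []
    for view in VIEWS:
        chain = _build_view_chain(params, view)
        for rep in range(1, repeats + 1):
            vertebrae = {}
            for level in LEVELS:
                pts = chain[level]

                def jitter(p: np.ndarray) -> Point:
                    if noise_sd > 0:
                        p = p + rng.normal(0.0, noise_sd, size=2)
                    return Point(float(p[0]), float(p[1]))

                bp, lp = pts["canal"]
                vertebrae[level] = VertebraLandmarks(
                    level=level,
                    anterosuperior=jitter(pts["anterosuperior"]),
                    anteroinferior=jitter(pts["anteroinferior"]),
                    posterosuperior=jitter(pts["posterosuperior"]),
                    posteroinferior=jitter(pts["posteroinferior"]),
                    canal_candidates=(CanalCandidate(jitter(bp), jitter(lp)),),
                )
            annotations.append(
                ViewAnnotation(
                    subject_id=subject_id,
                    group=group,
                    view=view,
                    repeat_id=rep,
                    vertebrae=vertebrae,
                )
            )
    return annotations


# ---------------------------------------------------------------------------
# stochastic subject and cohort generation
# ---------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, low: float = 0.0) -> float:
    """Normal(mean, sd) conditioned on >= low, by rejection."""
    if sd == 0:
        return max(mean, low)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= low:
            return x
    return low


def _draw_parameters(
    config: GeneratorConfig, group: str, rng: np.random.Generator
) -> SubjectParameters:
    targets = config.groups[group]
    hm, hs = config.vertebral_height
    wm, ws = config.vertebral_width
    cm, cs = config.canal_diameter
    heights = {lv: max(hm / 2.0, rng.normal(hm, hs)) for lv in LEVELS}
    canals = {lv: max(cm / 2.0, rng.normal(cm, cs)) for lv in LEVELS}
    base_width = max(wm / 2.0, rng.normal(wm, ws))

    cci = {
        "neutral": rng.normal(*targets.cci_neutral),
        "flexion": rng.normal(*targets.cci_flexion),
    }
    cci["extension"] = cci["flexion"] + rng.normal(*targets.rom)

    sci: dict[str, dict[str, float]] = {}
    for view in VIEWS:
        jit = rng.normal(0.0, config.sci_segment_sd, size=len(SEGMENTS))
        jit -= jit.mean()  # per-segment spread that preserves the CCI sum
        per = {}
        for seg, j in zip(SEGMENTS, jit):
            s = cci[view] / len(SEGMENTS) + j
            c_low = heights[segment_levels(seg)[1]]
            s_max = 2.0 * 0.85 * config.disc_height / c_low  # keep disc heights positive
            per[seg] = float(np.clip(s, -s_max, s_max))
        sci[view] = per

    hdi: dict[str, dict[str, float]] = {v: {} for v in VIEWS}
    signs: dict[str, dict[str, int]] = {v: {} for v in VIEWS}
    for seg in SEGMENTS:
        lower = segment_levels(seg)[1]
        c_low = heights[lower]
        canal = canals[lower]
        mhdi = _truncated_normal(rng, *targets.mhdi[seg])
        split = rng.uniform(0.25, 0.75)
        per_view = {
            "flexion": mhdi * split,
            "extension": mhdi * (1.0 - split),
            "neutral": _truncated_normal(rng, *targets.hdi_neutral),
        }
        signs["flexion"][seg] = config.flexion_sign
        signs["extension"][seg] = config.extension_sign
        signs["neutral"][seg] = int(rng.choice([-1, 1]))
        for view in VIEWS:
            s = sci[view][seg]
            b_h = config.disc_height - s * c_low / 2.0
            a_h = config.disc_height + s * c_low / 2.0
            hdi_max = 0.9 * min(a_h, b_h) / canal  # feasible listhesis bound
            hdi[view][seg] = float(min(per_view[view], hdi_max))

    angles = {
        v: math.radians(rng.normal(0.0, config.global_rotation_sd_deg)) for v in VIEWS
    }
    return SubjectParameters(
        heights=heights,
        canals=canals,
        base_width=base_width,
        disc_height=config.disc_height,
        sci=sci,
        hdi=hdi,
        signs=signs,
        global_angles=angles,
    )


def generate_subject(
    config: GeneratorConfig,
    group: str,
    subject_id: str,
    rng: np.random.Generator,
) -> tuple[list[ViewAnnotation], pd.DataFrame]:
    """One subject's annotations plus its segment-level ground-truth rows.

    The truth rows record the values actually injected into the geometry
    (after feasibility clipping of extreme draws), so measurement-pipeline
    recovery can be checked exactly.
    """
    params = _draw_parameters(config, group, rng)
    annotations = build_annotations(
        params,
        subject_id=subject_id,
        group=group,
        noise_sd=config.landmark_noise_sd,
        repeats=config.repeats,
        rng=rng,
    )
    rows = []
    for seg in SEGMENTS:
        rows.append(
            {
                "subject_id": subject_id,
                "group": group,
                "segment": seg,
                **{f"sci_{v}": params.sci[v][seg] for v in VIEWS},
                **{f"hdi_{v}": params.hdi[v][seg] for v in VIEWS},
                "mhdi": params.hdi["flexion"][seg] + params.hdi["extension"][seg],
            }
        )
    return annotations, pd.DataFrame(rows)


@dataclass
class SyntheticCohort:
    """A generated cohort: landmark annotations plus the injected truth table."""

    annotations: list[ViewAnnotation]
    truth: pd.DataFrame
    config: GeneratorConfig

    @property
    def n_subjects(self) -> int:
        return self.truth["subject_id"].nunique()


def generate_cohort(config: GeneratorConfig, seed: Optional[int] = None) -> SyntheticCohort:
    """Generate the full multi-group cohort.

    The root seed (argument overrides ``config.seed``) feeds hierarchical
    per-subject random streams, so the same subject index always receives
    the same stream regardless of how many subjects are generated: cohorts
    are extensible without reshuffling existing subjects.
    """
    root = seed if seed is not None else config.seed
    if root is None:
        raise ValueError("a seed is required for stochastic cohort generation")
    annotations: list[ViewAnnotation] = []
    truth_frames = []
    for g_idx, group in enumerate(GROUPS):
        if group not in config.groups:
            continue
        for s_idx in range(config.groups[group].n_subjects):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=(int(root), g_idx, s_idx))
            )
            subject_id = f"{group}-{s_idx + 1:03d}"
            ann, truth = generate_subject(config, group, subject_id, rng)
            annotations.extend(ann)
            truth_frames.append(truth)
    truth = pd.concat(truth_frames, ignore_index=True) if truth_frames else pd.DataFrame()
    return SyntheticCohort(annotations=annotations, truth=truth, config=config)
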