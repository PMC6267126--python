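"""Dimensionless radiographic indices of cervical curvature and displacement.

Because every index is a ratio of two lengths measured on the same film,
the indices are invariant to radiographic magnification and to individual
vertebral-body size -- the central idea of the index method.

Definitions (per motion segment and view):

* segmental curvature index  SCI = (A - B) / C
* cervical curvature index   CCI = sum of the five SCIs (C2/C3..C6/C7)
* range-of-motion index      ROM = CCI(extension) - CCI(flexion)
* horizontal displacement index  HDI = |displacement| / canal diameter
* maximum horizontal displacement index  MHDI = HDI(flexion) + HDI(extension)
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import SEGMENTS, VIEWS

__all__ = [
    "segmental_curvature_index",
    "cervical_curvature_index",
    "rom_index",
    "horizontal_displacement_index",
    "max_horizontal_displacement_index",
    "segment_index_table",
    "subject_index_table",
]


def segmental_curvature_index(A: float, B: float, C: float) -> float:
    """(A - B) / C: positive for a lordotic disc wedge, negative kyphotic."""
    if not C > 0:
        raise ValueError(f"central height C must be positive, got {C}")
    return (A - B) / C


def cervical_curvature_index(segments: Mapping[str, float] | Sequence[float]) -> float:
    """Sum of the five segmental curvature indices of one view.

    Accepts either the five values in order C2/C3..C6/C7 or a mapping from
    segment name to value; all five segments must be present and finite.
    """
    if isinstance(segments, Mapping):
        missing = [s for s in SEGMENTS if s not in segments]
        if missing:
            raise ValueError(f"incomplete segment set, missing {missing}")
        values = [float(segments[s]) for s in SEGMENTS]
    else:
        values = [float(v) for v in segments]
        if len(values) != len(SEGMENTS):
            raise ValueError(f"expected {len(SEGMENTS)} segments, got {len(values)}")
    if not all(math.isfinite(v) for v in values):
        raise ValueError("non-finite segmental curvature index")
    return float(sum(values))


def rom_index(cci_extension: float, cci_flexion: float) -> float:
    """Full-flexion-to-full-extension range of motion on the index scale.

    Oriented extension minus flexion so that a normally mobile spine
    yields a positive value.
    """
    if not (math.isfinite(cci_extension) and math.isfinite(cci_flexion)):
        raise ValueError("both view indices must be finite")
    return cci_extension - cci_flexion


def horizontal_displacement_index(displacement: float, canal_diameter: float) -> float:
    """|displacement| / canal diameter; direction of listhesis is discarded."""
    if not canal_diameter > 0:
        raise ValueError(f"canal diameter must be positive, got {canal_diameter}")
    return abs(displacement) / canal_diameter


def max_horizontal_displacement_index(hdi_flexion: float, hdi_extension: float) -> float:
    """Flexion HDI plus extension HDI for one segment (total dynamic excursion)."""
    if hdi_flexion < 0 or hdi_extension < 0:
        raise ValueError("HDI values must be non-negative")
    return hdi_flexion + hdi_extension


# ---------------------------------------------------------------------------
# tidy cohort tables
# ---------------------------------------------------------------------------

def segment_index_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per subject x segment indices from a tidy measurement table.

    ``measurements`` has one row per (subject_id, group, view, segment)
    with columns A, B, C, horizontal_displacement, canal_diameter,
    angular_displacement and a boolean ``complete``.  Returns one row per
    (subject_id, group, segment) with sci_<view>, hdi_<view>, mhdi and the
    mean angular displacement over the flexion/extension views; values not
    computable from complete measurements are NaN.
    """
    rows = []
    for (subject, group, segment), sub in measurements.groupby(
        ["subject_id", "group", "segment"], sort=False, observed=True
    ):
        rec: dict = {"subject_id": subject, "group": group, "segment": segment}
        byview = {r.view: r for r in sub.itertuples()}
        for view in VIEWS:
            r = byview.get(view)
            ok = r is not None and bool(r.complete)
            rec[f"sci_{view}"] = (
                segmental_curvature_index(r.A, r.B, r.C) if ok else np.nan
            )
            rec[f"hdi_{view}"] = (
                horizontal_displacement_index(r.horizontal_displacement, r.canal_diameter)
                if ok
                else np.nan
            )
            rec[f"angular_{view}"] = r.angular_displacement if ok else np.nan
        hf, he = rec["hdi_flexion"], rec["hdi_extension"]
        rec["mhdi"] = (
            max_horizontal_displacement_index(hf, he)
            if math.isfinite(hf) and math.isfinite(he)
            else np.nan
        )
        rows.append(rec)
    cols = (
        ["subject_id", "group", "segment"]
        + [f"sci_{v}" for v in VIEWS]
        + [f"hdi_{v}" for v in VIEWS]
        + [f"angular_{v}" for v in VIEWS]
        + ["mhdi"]
    )
    return pd.DataFrame(rows, columns=cols)


def subject_index_table(segment_indices: pd.DataFrame) -> pd.DataFrame:
    """Per-subject curvature indices and ROM from the segment-level table.

    A view's CCI is emitted only when all five segments are complete in
    that view; the ROM index only when both dynamic views have a CCI.
    """
    rows = []
    for (subject, group), sub in segment_indices.groupby(
        ["subject_id", "group"], sort=False, observed=True
    ):
        rec: dict = {"subject_id": subject, "group": group}
        for view in VIEWS:
            vals = sub.set_index("segment")[f"sci_{view}"]
            try:
                rec[f"cci_{view}"] = cervical_curvature_index(vals.to_dict())
            except ValueError:
                rec[f"cci_{view}"] = np.nan
        ce, cf = rec["cci_extension"], rec["cci_flexion"]
        rec["rom_index"] = (
            rom_index(ce, cf) if math.isfinite(ce) and math.isfinite(cf) else np.nan
        )
        rows.append(rec)
    cols = ["subject_id", "group"] + [f"cci_{v}" for v in VIEWS] + ["rom_index"]
    return pd.DataFrame(rows, columns=cols)
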