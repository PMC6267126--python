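"""Threshold rules on displacement indices: instability and displacement counts.

The decision rule for segmental instability is MHDI >= 0.30 (inclusive).
Two auxiliary tabulations support the group comparisons: the number of
segments whose MHDI reaches each of the nested categories >=0.20 / >=0.25
/ >=0.30, and the incidence of "horizontally displaced" segment-views at
a configurable per-view HDI cutoff ``tau_displaced``.  The displaced-
segment cutoff is not part of the instability rule and has no published
value; it defaults to 0.10 and must be read as a convention, not a
clinical threshold.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import GROUPS, SEGMENTS

__all__ = [
    "INSTABILITY_THRESHOLD",
    "DEFAULT_CATEGORY_THRESHOLDS",
    "DEFAULT_TAU_DISPLACED",
    "classify_instability",
    "segment_classifications",
    "threshold_exceedance_counts",
    "displaced_segment_incidence",
]

INSTABILITY_THRESHOLD = 0.30
DEFAULT_CATEGORY_THRESHOLDS: tuple[float, ...] = (0.20, 0.25, 0.30)
DEFAULT_TAU_DISPLACED = 0.10


def classify_instability(mhdi: float, threshold: float = INSTABILITY_THRESHOLD) -> bool:
    """True iff the maximum horizontal displacement index reaches the threshold."""
    if mhdi < 0 or not math.isfinite(mhdi):
        raise ValueError(f"MHDI must be a finite non-negative value, got {mhdi}")
    return mhdi >= threshold


def segment_classifications(
    segment_indices: pd.DataFrame,
    thresholds: Sequence[float] = DEFAULT_CATEGORY_THRESHOLDS,
    tau_displaced: float = DEFAULT_TAU_DISPLACED,
) -> pd.DataFrame:
    """Per-segment boolean classification flags.

    Adds, for each row of the segment index table, one ``ge_<t>`` column
    per category threshold, the ``unstable`` flag (MHDI >= 0.30), and the
    displaced flags for the neutral view and for either dynamic view.
    """
    if tau_displaced < 0:
        raise ValueError("tau_displaced must be non-negative")
    thresholds = tuple(sorted(thresholds))
    out = segment_indices[["subject_id", "group", "segment", "mhdi"]].copy()
    for t in thresholds:
        out[_ge_col(t)] = segment_indices["mhdi"] >= t
    out["unstable"] = segment_indices["mhdi"] >= INSTABILITY_THRESHOLD
    out["displaced_neutral"] = segment_indices["hdi_neutral"] >= tau_displaced
    out["displaced_flexext"] = (
        (segment_indices["hdi_flexion"] >= tau_displaced)
        | (segment_indices["hdi_extension"] >= tau_displaced)
    )
    return out


def _ge_col(threshold: float) -> str:
    return f"ge_{threshold:.2f}".replace("0.", "0")


def threshold_exceedance_counts(
    segment_indices: pd.DataFrame,
    thresholds: Sequence[float] = DEFAULT_CATEGORY_THRESHOLDS,
) -> pd.DataFrame:
    """Segments per group whose MHDI reaches each category threshold.

    Returns a group x threshold table of counts; counts are monotone
    non-increasing along increasing thresholds because the categories are
    nested.
    """
    thresholds = tuple(sorted(thresholds))
    groups = [g for g in GROUPS if g in set(segment_indices["group"])]
    data = {}
    for t in thresholds:
        counts = []
        for g in groups:
            m = segment_indices.loc[segment_indices["group"] == g, "mhdi"]
            counts.append(int((m >= t).sum()))
        data[f">={t:.2f}"] = counts
    return pd.DataFrame(data, index=pd.Index(groups, name="group"))


def displaced_segment_incidence(
    segment_indices: pd.DataFrame,
    tau_displaced: float = DEFAULT_TAU_DISPLACED,
) -> pd.DataFrame:
    """Per-group displaced-segment counts and incidences, by view type.

    A segment-view counts as displaced when its HDI >= ``tau_displaced``.
    Denominators are exact trial counts: subjects x 5 segments for the
    neutral view and subjects x 5 segments x 2 views for the combined
    flexion-extension assessment (each dynamic view is one trial).
    """
    if tau_displaced < 0:
        raise ValueError("tau_displaced must be non-negative")
    groups = [g for g in GROUPS if g in set(segment_indices["group"])]
    rows = []
    for g in groups:
        sub = segment_indices[segment_indices["group"] == g]
        n_subjects = sub["subject_id"].nunique()
        denom_neutral = n_subjects * len(SEGMENTS)
        denom_flexext = n_subjects * len(SEGMENTS) * 2
        count_neutral = int((sub["hdi_neutral"] >= tau_displaced).sum())
        count_flexext = int(
            (sub["hdi_flexion"] >= tau_displaced).sum()
            + (sub["hdi_extension"] >= tau_displaced).sum()
        )
        rows.append(
            {
                "group": g,
                "n_subjects": n_subjects,
                "neutral_count": count_neutral,
                "neutral_denominator": denom_neutral,
                "neutral_incidence_pct": 100.0 * count_neutral / denom_neutral,
                "flexext_count": count_flexext,
                "flexext_denominator": denom_flexext,
                "flexext_incidence_pct": 100.0 * count_flexext / denom_flexext,
            }
        )
    return pd.DataFrame(rows).set_index("group")
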