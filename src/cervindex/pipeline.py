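"""Cohort-level orchestration: measure -> indices -> classify -> compare.

Each stage consumes and produces tidy pandas tables so intermediate
results can be written to disk and the analysis re-run from any stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import classify as _classify
from . import stats as _stats
from .geometry import GROUPS, SEGMENTS, VIEWS, ViewAnnotation, measure_view
from .indices import segment_index_table, subject_index_table

__all__ = [
    "measure_cohort",
    "compute_indices",
    "CohortResults",
    "compare_groups",
]

MEASUREMENT_COLUMNS = [
    "subject_id",
    "group",
    "view",
    "segment",
    "A",
    "B",
    "C",
    "angular_displacement",
    "horizontal_displacement",
    "canal_diameter",
    "complete",
]


def measure_cohort(
    annotations: Sequence[ViewAnnotation],
    angle_convention: str = "shared_disc",
) -> pd.DataFrame:
    """Protocol measurements for every subject-view in a cohort.

    Repeat digitizations of the same subject-view are grouped, averaged
    and rounded per protocol; the result is one row per
    (subject, view, segment).
    """
    by_view: dict[tuple[str, str], list[ViewAnnotation]] = {}
    order: list[tuple[str, str]] = []
    meta: dict[tuple[str, str], str] = {}
    for ann in annotations:
        key = (ann.subject_id, ann.view)
        if key not in by_view:
            by_view[key] = []
            order.append(key)
            meta[key] = ann.group
        by_view[key].append(ann)

    rows = []
    for key in order:
        subject, view = key
        measured = measure_view(by_view[key], angle_convention=angle_convention)
        for seg in SEGMENTS:
            m = measured[seg]
            rows.append(
                {
                    "subject_id": subject,
                    "group": meta[key],
                    "view": view,
                    "segment": seg,
                    "A": m.A,
                    "B": m.B,
                    "C": m.C,
                    "angular_displacement": m.angular_displacement,
                    "horizontal_displacement": m.horizontal_displacement,
                    "canal_diameter": m.canal_diameter,
                    "complete": m.complete,
                }
            )
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def compute_indices(measurements: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment-level and subject-level index tables from measurements."""
    seg = segment_index_table(measurements)
    subj = subject_index_table(seg)
    return seg, subj


@dataclass
class CohortResults:
    """Full comparison output for one cohort.

    Tables mirror the clinical reporting layouts: per-view curvature
    summaries with rank tests, ROM means with ANOVA/SNK, per-segment MHDI
    group comparisons, within-group segment comparisons, displaced-segment
    incidence with chi-square tests, and nested threshold-exceedance
    counts.
    """

    curvature_summary: pd.DataFrame
    curvature_tests: dict[str, _stats.StatResult]
    curvature_posthoc: dict[str, _stats.PosthocResult]
    rom_summary: pd.DataFrame
    rom_test: Optional[_stats.StatResult]
    rom_posthoc: Optional[_stats.PosthocResult]
    mhdi_by_segment: pd.DataFrame
    mhdi_tests: dict[str, _stats.StatResult]
    mhdi_posthoc: dict[str, _stats.PosthocResult]
    within_group_tests: dict[str, _stats.StatResult]
    incidence: pd.DataFrame
    incidence_tests: dict[str, _stats.StatResult]
    incidence_posthoc: dict[str, dict[frozenset, _stats.StatResult]]
    exceedance: pd.DataFrame
    exceedance_tests: dict[str, _stats.StatResult]
    correlation: Optional[_stats.StatResult]
    classifications: pd.DataFrame
    tau_displaced: float
    alpha: float


def _groups_present(df: pd.DataFrame) -> list[str]:
    present = set(df["group"])
    return [g for g in GROUPS if g in present]


def compare_groups(
    segment_indices: pd.DataFrame,
    subject_indices: pd.DataFrame,
    tau_displaced: float = _classify.DEFAULT_TAU_DISPLACED,
    thresholds: Sequence[float] = _classify.DEFAULT_CATEGORY_THRESHOLDS,
    alpha: float = 0.05,
) -> CohortResults:
    """Run the full group-comparison battery on cohort index tables."""
    groups = _groups_present(subject_indices)
    multi = len(groups) >= 2

    # --- curvature indices per view: median summaries + rank tests -------
    curv_rows = []
    curv_tests: dict[str, _stats.StatResult] = {}
    curv_posthoc: dict[str, _stats.PosthocResult] = {}
    for g in groups:
        sub = subject_indices[subject_indices["group"] == g]
        curv_rows.append(
            {
                "group": g,
                **{
                    view: _stats.summarize(sub[f"cci_{view}"], "median_quartiles")
                    for view in VIEWS
                },
            }
        )
    curvature_summary = pd.DataFrame(curv_rows).set_index("group")
    if multi:
        for view in VIEWS:
            samples = [
                subject_indices.loc[
                    subject_indices["group"] == g, f"cci_{view}"
                ].dropna()
                for g in groups
            ]
            curv_tests[view] = _stats.kruskal_wallis(samples)
            curv_posthoc[view] = _stats.kruskal_wallis_posthoc(
                samples, labels=groups, alpha=alpha
            )

    # --- ROM index: mean summaries + ANOVA/SNK ---------------------------
    rom_rows = []
    for g in groups:
        sub = subject_indices.loc[subject_indices["group"] == g, "rom_index"].dropna()
        rom_rows.append(
            {"group": g, "rom": _stats.summarize(sub, "mean_sd"), "n": int(sub.size)}
        )
    rom_summary = pd.DataFrame(rom_rows).set_index("group")
    rom_test = rom_posthoc = None
    if multi:
        samples = [
            subject_indices.loc[subject_indices["group"] == g, "rom_index"].dropna()
            for g in groups
        ]
        rom_test = _stats.one_way_anova(samples)
        rom_posthoc = _stats.snk_test(samples, labels=groups, alpha=alpha)

    # --- MHDI per segment between groups: means + ANOVA/SNK --------------
    mhdi_rows = []
    mhdi_tests: dict[str, _stats.StatResult] = {}
    mhdi_posthoc: dict[str, _stats.PosthocResult] = {}
    for seg in SEGMENTS:
        seg_df = segment_indices[segment_indices["segment"] == seg]
        row: dict = {"segment": seg}
        for g in groups:
            row[g] = _stats.summarize(
                seg_df.loc[seg_df["group"] == g, "mhdi"].dropna(), "mean_sd"
            )
        if multi:
            samples = [
                seg_df.loc[seg_df["group"] == g, "mhdi"].dropna() for g in groups
            ]
            res = _stats.one_way_anova(samples)
            mhdi_tests[seg] = res
            mhdi_posthoc[seg] = _stats.snk_test(samples, labels=groups, alpha=alpha)
            row["F"] = res.statistic
            row["p"] = res.pvalue
        mhdi_rows.append(row)
    mhdi_by_segment = pd.DataFrame(mhdi_rows).set_index("segment")

    # --- MHDI across segments within each group (rank tests) -------------
    within_tests: dict[str, _stats.StatResult] = {}
    for g in groups:
        sub = segment_indices[segment_indices["group"] == g]
        samples = [
            sub.loc[sub["segment"] == seg, "mhdi"].dropna() for seg in SEGMENTS
        ]
        if all(s.size >= 1 for s in samples):
            within_tests[g] = _stats.kruskal_wallis(samples)

    # --- displaced-segment incidence + chi-square -------------------------
    incidence = _classify.displaced_segment_incidence(segment_indices, tau_displaced)
    incidence_tests: dict[str, _stats.StatResult] = {}
    incidence_posthoc: dict[str, dict[frozenset, _stats.StatResult]] = {}
    if multi:
        for kind in ("neutral", "flexext"):
            table = np.column_stack(
                [
                    incidence[f"{kind}_count"].to_numpy(),
                    incidence[f"{kind}_denominator"].to_numpy()
                    - incidence[f"{kind}_count"].to_numpy(),
                ]
            )
            incidence_tests[kind] = _stats.pearson_chi_square(table)
            if len(groups) >= 3:
                incidence_posthoc[kind] = _stats.partitioned_chi_square(
                    table, alpha=alpha, row_labels=groups
                )

    # --- nested threshold-exceedance counts + chi-square ------------------
    exceedance = _classify.threshold_exceedance_counts(segment_indices, thresholds)
    exceedance_tests: dict[str, _stats.StatResult] = {}
    if multi:
        denom = {
            g: int(
                segment_indices.loc[segment_indices["group"] == g, "subject_id"].nunique()
            )
            * len(SEGMENTS)
            for g in groups
        }
        for col in exceedance.columns:
            counts = exceedance[col].to_numpy()
            table = np.column_stack(
                [counts, np.array([denom[g] for g in exceedance.index]) - counts]
            )
            if np.all(table.sum(axis=0) > 0):
                exceedance_tests[col] = _stats.pearson_chi_square(table)

    # --- angular vs horizontal displacement correlation -------------------
    corr = None
    dyn = segment_indices[
        ["angular_flexion", "angular_extension", "hdi_flexion", "hdi_extension"]
    ]
    ang = pd.concat([dyn["angular_flexion"], dyn["angular_extension"]])
    hdi = pd.concat([dyn["hdi_flexion"], dyn["hdi_extension"]])
    try:
        corr = _stats.pearson_correlation(ang, hdi)
    except ValueError:
        corr = None

    classifications = _classify.segment_classifications(
        segment_indices, thresholds=thresholds, tau_displaced=tau_displaced
    )

    return CohortResults(
        curvature_summary=curvature_summary,
        curvature_tests=curv_tests,
        curvature_posthoc=curv_posthoc,
        rom_summary=rom_summary,
        rom_test=rom_test,
        rom_posthoc=rom_posthoc,
        mhdi_by_segment=mhdi_by_segment,
        mhdi_tests=mhdi_tests,
        mhdi_posthoc=mhdi_posthoc,
        within_group_tests=within_tests,
        incidence=incidence,
        incidence_tests=incidence_tests,
        incidence_posthoc=incidence_posthoc,
        exceedance=exceedance,
        exceedance_tests=exceedance_tests,
        correlation=corr,
        classifications=classifications,
        tau_displaced=tau_displaced,
        alpha=alpha,
    )
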