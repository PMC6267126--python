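"""Landmark file formats, run configuration and report writing.

The landmark interchange format is a tidy UTF-8 CSV (or an equivalent
nested JSON) with one row per digitized point:

    subject_id,group,view,repeat_id,vertebra,landmark_name,x_mm,y_mm

``landmark_name`` is a controlled vocabulary: the four corner points
(``corner_anterosuperior`` etc.), numbered canal point pairs
(``canal_body_point_1`` / ``canal_lamina_point_1``, ...) and the
``osteophyte_flag`` pseudo-landmark (x_mm 0/1, y_mm ignored).  When the
osteophyte flag is set, the canal pairs supplied for that vertebra are by
convention the osteophyte-aware ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from .geometry import (
    GROUPS,
    LEVELS,
    SEGMENTS,
    VIEWS,
    CanalCandidate,
    Point,
    VertebraLandmarks,
    ViewAnnotation,
)
from .pipeline import CohortResults
from .simulate import GeneratorConfig, GroupTargets, default_config
from .stats import PosthocResult, StatResult

__all__ = [
    "LandmarkSchemaError",
    "RunConfig",
    "CORNER_NAMES",
    "read_landmarks",
    "write_landmarks",
    "read_landmarks_json",
    "write_landmarks_json",
    "write_report",
]

CORNER_NAMES = {
    "corner_anterosuperior": "anterosuperior",
    "corner_anteroinferior": "anteroinferior",
    "corner_posterosuperior": "posterosuperior",
    "corner_posteroinferior": "posteroinferior",
}
_CANAL_RE = re.compile(r"^canal_(body|lamina)_point_(\d+)$")

LANDMARK_COLUMNS = [
    "subject_id",
    "group",
    "view",
    "repeat_id",
    "vertebra",
    "landmark_name",
    "x_mm",
    "y_mm",
]


class LandmarkSchemaError(ValueError):
    """A landmark file violates the interchange schema."""


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Analysis settings: thresholds, conventions, and the generator block."""

    thresholds: tuple[float, ...] = _classify.DEFAULT_CATEGORY_THRESHOLDS
    tau_displaced: float = _classify.DEFAULT_TAU_DISPLACED
    alpha: float = 0.05
    angle_convention: str = "shared_disc"
    quartile_method: str = "linear"
    generator: GeneratorConfig = dataclasses.field(default_factory=default_config)

    def __post_init__(self) -> None:
        self.thresholds = tuple(sorted(float(t) for t in self.thresholds))
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.tau_displaced < 0:
            raise ValueError("tau_displaced must be non-negative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        gen = d.pop("generator", None)
        if gen is not None:
            groups = {
                name: GroupTargets(**_tupled(g)) for name, g in gen.pop("groups").items()
            }
            gen = GeneratorConfig(groups=groups, **_tupled(gen))
        else:
            gen = default_config()
        return cls(generator=gen, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(_listed(self.to_dict()), fh, sort_keys=True)

    def digest(self) -> str:
        payload = json.dumps(_listed(self.to_dict()), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _tupled(d: dict) -> dict:
    """YAML round-trip: lists representing (mean, SD) pairs back to tuples."""
    out = {}
    for k, v in d.items():
        if isinstance(v, list) and len(v) == 2 and all(
            isinstance(x, (int, float)) for x in v
        ):
            out[k] = tuple(v)
        elif isinstance(v, dict):
            out[k] = {
                kk: tuple(vv) if isinstance(vv, list) else vv for kk, vv in v.items()
            }
        else:
            out[k] = v
    return out


def _listed(obj):
    if isinstance(obj, dict):
        return {k: _listed(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listed(v) for v in obj]
    if isinstance(obj, list):
        return [_listed(v) for v in obj]
    return obj


# ---------------------------------------------------------------------------
# landmark files
# ---------------------------------------------------------------------------

def _landmark_rows(annotations: Iterable[ViewAnnotation]) -> pd.DataFrame:
    rows = []
    for ann in annotations:
        for level in LEVELS:
            v = ann.vertebrae.get(level)
            if v is None:
                continue
            base = {
                "subject_id": ann.subject_id,
                "group": ann.group,
                "view": ann.view,
                "repeat_id": ann.repeat_id,
                "vertebra": level,
            }
            for fname, attr in CORNER_NAMES.items():
                p = getattr(v, attr)
                if p is not None:
                    rows.append({**base, "landmark_name": fname, "x_mm": p.x, "y_mm": p.y})
            for k, cand in enumerate(v.canal_candidates, start=1):
                rows.append(
                    {
                        **base,
                        "landmark_name": f"canal_body_point_{k}",
                        "x_mm": cand.body_point.x,
                        "y_mm": cand.body_point.y,
                    }
                )
                rows.append(
                    {
                        **base,
                        "landmark_name": f"canal_lamina_point_{k}",
                        "x_mm": cand.canal_point.x,
                        "y_mm": cand.canal_point.y,
                    }
                )
            if v.osteophyte_flag:
                rows.append({**base, "landmark_name": "osteophyte_flag", "x_mm": 1.0, "y_mm": 0.0})
    return pd.DataFrame(rows, columns=LANDMARK_COLUMNS)


def write_landmarks(annotations: Iterable[ViewAnnotation], path: str | Path) -> None:
    """Write annotations as the tidy landmark CSV (full float precision)."""
    df = _landmark_rows(annotations)
    # shortest round-trip representation so read-back is bit-exact
    for col in ("x_mm", "y_mm"):
        df[col] = df[col].map(repr)
    df.to_csv(path, index=False)


def _parse_rows(df: pd.DataFrame, source: str) -> list[ViewAnnotation]:
    missing = [c for c in LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise LandmarkSchemaError(f"{source}: missing columns {missing}")

    seen: set[tuple] = set()
    store: dict[tuple, dict] = {}
    order: list[tuple] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        name = str(row.landmark_name)
        if str(row.view) not in VIEWS:
            raise LandmarkSchemaError(f"{source} row {i}: unknown view {row.view!r}")
        if str(row.group) not in GROUPS:
            raise LandmarkSchemaError(f"{source} row {i}: unknown group {row.group!r}")
        if str(row.vertebra) not in LEVELS:
            raise LandmarkSchemaError(f"{source} row {i}: unknown vertebra {row.vertebra!r}")
        if not (
            name in CORNER_NAMES or _CANAL_RE.match(name) or name == "osteophyte_flag"
        ):
            raise LandmarkSchemaError(f"{source} row {i}: unknown landmark_name {name!r}")
        try:
            x, y = float(row.x_mm), float(row.y_mm)
        except (TypeError, ValueError):
            raise LandmarkSchemaError(f"{source} row {i}: non-numeric coordinates")
        if not (np.isfinite(x) and np.isfinite(y)):
            raise LandmarkSchemaError(f"{source} row {i}: non-finite coordinates")
        key = (str(row.subject_id), str(row.view), int(row.repeat_id), str(row.vertebra), name)
        if key in seen:
            raise LandmarkSchemaError(f"{source} row {i}: duplicate landmark {key}")
        seen.add(key)
        vkey = key[:4]
        if vkey not in store:
            store[vkey] = {
                "group": str(row.group),
                "corners": {},
                "canal": {},
                "osteophyte": False,
            }
            order.append(vkey)
        if store[vkey]["group"] != str(row.group):
            raise LandmarkSchemaError(f"{source} row {i}: conflicting group label")
        if name in CORNER_NAMES:
            store[vkey]["corners"][CORNER_NAMES[name]] = Point(x, y)
        elif name == "osteophyte_flag":
            store[vkey]["osteophyte"] = bool(x)
        else:
            kind, idx = _CANAL_RE.match(name).groups()
            store[vkey]["canal"].setdefault(int(idx), {})[kind] = Point(x, y)

    views: dict[tuple, ViewAnnotation] = {}
    view_order: list[tuple] = []
    for vkey in order:
        subject, view, repeat, level = vkey
        rec = store[vkey]
        candidates = []
        for idx in sorted(rec["canal"]):
            pair = rec["canal"][idx]
            if "body" not in pair or "lamina" not in pair:
                raise LandmarkSchemaError(
                    f"{source}: {subject}/{view}/rep{repeat}/{level} canal pair "
                    f"{idx} incomplete"
                )
            candidates.append(
                CanalCandidate(
                    pair["body"], pair["lamina"], osteophyte_aware=rec["osteophyte"]
                )
            )
        landmarks = VertebraLandmarks(
            level=level,
            canal_candidates=tuple(candidates),
            osteophyte_flag=rec["osteophyte"],
            **rec["corners"],
        )
        akey = (subject, view, repeat)
        if akey not in views:
            views[akey] = ViewAnnotation(
                subject_id=subject,
                group=rec["group"],
                view=view,
                repeat_id=repeat,
            )
            view_order.append(akey)
        views[akey].vertebrae[level] = landmarks
    return [views[k] for k in view_order]


def read_landmarks(path: str | Path) -> list[ViewAnnotation]:
    """Read and validate a landmark CSV into view annotations."""
    path = Path(path)
    df = pd.read_csv(
        path,
        dtype={"subject_id": str, "group": str, "view": str,
               "vertebra": str, "landmark_name": str},
        float_precision="round_trip",
    )
    return _parse_rows(df, source=path.name)


def write_landmarks_json(annotations: Iterable[ViewAnnotation], path: str | Path) -> None:
    """JSON mirror of the landmark CSV (records orientation)."""
    df = _landmark_rows(annotations)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(df.to_dict(orient="records"), fh, indent=1)


def read_landmarks_json(path: str | Path) -> list[ViewAnnotation]:
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        records = json.load(fh)
    df = pd.DataFrame(records, columns=LANDMARK_COLUMNS)
    return _parse_rows(df, source=path.name)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _stat_to_dict(res: Optional[StatResult]) -> Optional[dict]:
    if res is None:
        return None
    return {
        "statistic": res.statistic,
        "kind": res.kind,
        "df": list(res.df),
        "pvalue": res.pvalue,
        "alpha": res.alpha,
        "significant": bool(res.significant),
    }


def _posthoc_to_dict(res: Optional[PosthocResult]) -> Optional[dict]:
    if res is None:
        return None
    return {
        "alpha": res.alpha,
        "significant_pairs": sorted("|".join(sorted(p)) for p in res.significant_pairs),
        "homogeneous_subsets": [list(s) for s in res.homogeneous_subsets],
    }


def write_report(
    results: CohortResults,
    segment_indices: pd.DataFrame,
    subject_indices: pd.DataFrame,
    out_dir: str | Path,
    config: Optional[RunConfig] = None,
    seed: Optional[int] = None,
    make_plot: bool = False,
) -> list[Path]:
    """Write the analysis report bundle; returns the files written.

    Emits per-subject and per-segment index CSVs, the group summary CSVs,
    incidence and exceedance CSVs, a stats JSON and a run log carrying the
    configuration digest and seed.  Optionally renders the angular-vs-
    horizontal-displacement scatter.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _csv(df: pd.DataFrame, name: str, index: bool = True) -> None:
        p = out / name
        df.to_csv(p, index=index)
        written.append(p)

    _csv(subject_indices, "subject_indices.csv", index=False)
    _csv(segment_indices, "segment_indices.csv", index=False)
    _csv(results.classifications, "classifications.csv", index=False)
    _csv(results.curvature_summary, "curvature_summary.csv")
    _csv(results.rom_summary, "rom_summary.csv")
    _csv(results.mhdi_by_segment, "mhdi_by_segment.csv")
    _csv(results.incidence, "incidence.csv")
    _csv(results.exceedance, "exceedance.csv")

    stats_payload = {
        "curvature": {
            v: {
                "test": _stat_to_dict(results.curvature_tests.get(v)),
                "posthoc": _posthoc_to_dict(results.curvature_posthoc.get(v)),
            }
            for v in VIEWS
        },
        "rom": {
            "test": _stat_to_dict(results.rom_test),
            "posthoc": _posthoc_to_dict(results.rom_posthoc),
        },
        "mhdi_by_segment": {
            s: {
                "test": _stat_to_dict(results.mhdi_tests.get(s)),
                "posthoc": _posthoc_to_dict(results.mhdi_posthoc.get(s)),
            }
            for s in SEGMENTS
        },
        "within_group": {
            g: _stat_to_dict(r) for g, r in results.within_group_tests.items()
        },
        "incidence": {
            k: {
                "test": _stat_to_dict(results.incidence_tests.get(k)),
                "pairwise": {
                    "|".join(sorted(pair)): _stat_to_dict(r)
                    for pair, r in results.incidence_posthoc.get(k, {}).items()
                },
            }
            for k in ("neutral", "flexext")
        },
        "exceedance": {
            k: _stat_to_dict(r) for k, r in results.exceedance_tests.items()
        },
        "correlation_angular_vs_hdi": _stat_to_dict(results.correlation),
        "tau_displaced": results.tau_displaced,
        "alpha": results.alpha,
    }
    p = out / "stats.json"
    with open(p, "w", encoding="utf-8") as fh:
        json.dump(stats_payload, fh, indent=1, sort_keys=True)
    written.append(p)

    log = out / "run_log.txt"
    cfg = config if config is not None else RunConfig()
    with open(log, "w", encoding="utf-8") as fh:
        fh.write("cervindex analysis report\n")
        fh.write(f"config_digest: {cfg.digest()}\n")
        fh.write(f"seed: {seed}\n")
        fh.write(f"tau_displaced: {results.tau_displaced}\n")
        fh.write(f"n_subjects: {subject_indices['subject_id'].nunique()}\n")
    written.append(log)

    if make_plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        ang = pd.concat(
            [segment_indices["angular_flexion"], segment_indices["angular_extension"]]
        )
        hdi = pd.concat(
            [segment_indices["hdi_flexion"], segment_indices["hdi_extension"]]
        )
        ax.scatter(ang, hdi, s=8, alpha=0.5)
        ax.set_xlabel("angular displacement (degrees)")
        ax.set_ylabel("horizontal displacement index")
        if results.correlation is not None:
            ax.set_title(
                f"r = {results.correlation.statistic:.4f}, "
                f"p = {results.correlation.pvalue:.4f}"
            )
        fig.tight_layout()
        p = out / "correlation_scatter.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
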