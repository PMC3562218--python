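"""File formats, run configuration, and the end-to-end analysis report.

Three plain-text inputs describe a cohort:

* **annotation CSV** — one row per cilium with landmark pixels, frame-index
  time-points and acquisition metadata (``patient_id, cilium_id, fps,
  pixel_size_um, x0, y0, x1, y1, x2, y2, t1..t5, cycle_observed``);
* **edge CSV** — one row per scored epithelial area (``patient_id, area_id,
  beating_score, pattern_label, dyskinesia_score``);
* **clinical TSV** — gold-standard evidence per patient (``patient_id,
  no_n_nl_min, tem_pct_abnormal, same_defect`` plus optional
  ``defect_label`` and ``group``).

Files are UTF-8 with mandatory headers and '.' decimal separators; pixel
coordinates and frame indices in files, micrometres and seconds in memory.
:func:`run_full_analysis` joins the three tables into per-patient summaries,
nonparametric group statistics, a patient-level ROC with named cutoffs, and
three-zone calls for the gold-standard-inconclusive patients.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .diagnostics import (
    GoldStandardInput,
    classify_three_zone,
    gold_standard_classify,
    kruskal_wallis,
    mann_whitney,
    roc_curve,
)
from .errors import ConfigurationError, ConsistencyError, ParseError
from .kinematics import AcquisitionMeta, BeatCycleAnnotation, BeatCycleParameters, Point2D
from .scoring import EdgeObservation, PatientRecord, PatientSummary, summarize_patient

logger = logging.getLogger("ciliabeat")

ANNOTATION_COLUMNS = [
    "patient_id", "cilium_id", "fps", "pixel_size_um",
    "x0", "y0", "x1", "y1", "x2", "y2",
    "t1", "t2", "t3", "t4", "t5", "cycle_observed",
]
EDGE_COLUMNS = [
    "patient_id", "area_id", "beating_score", "pattern_label", "dyskinesia_score",
]
CLINICAL_COLUMNS = ["patient_id", "no_n_nl_min", "tem_pct_abnormal", "same_defect"]

#: Default named cutoffs (um) for the weighted distance travelled per second:
#: balanced / 100%-sensitivity / 100%-specificity.
DEFAULT_CUTOFF_BALANCED = 24.0
DEFAULT_CUTOFF_SENS100 = 51.0
DEFAULT_CUTOFF_SPEC100 = 10.0


@dataclass
class RunConfig:
    """Configuration of a full-pipeline run.

    The three cutoffs apply to the mean weighted distance travelled per
    second and must satisfy ``spec100 < balanced < sens100``.
    """

    annotations: Path | None = None
    edges: Path | None = None
    clinical: Path | None = None
    fps: float = 355.0
    pixel_size: float = 0.13
    orientation: str = "lower"
    cutoff_balanced: float = DEFAULT_CUTOFF_BALANCED
    cutoff_sens100: float = DEFAULT_CUTOFF_SENS100
    cutoff_spec100: float = DEFAULT_CUTOFF_SPEC100
    seed: int = 0
    outdir: Path = field(default_factory=lambda: Path("."))
    verbose: bool = False

    def __post_init__(self):
        if not (self.cutoff_spec100 < self.cutoff_balanced < self.cutoff_sens100):
            raise ConfigurationError(
                "cutoffs must satisfy spec100 < balanced < sens100, got "
                f"{self.cutoff_spec100} / {self.cutoff_balanced} / {self.cutoff_sens100}"
            )
        if self.orientation not in ("lower", "higher"):
            raise ConfigurationError(f"unknown orientation {self.orientation!r}")

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a JSON config file; keyword overrides lose to file values.

        Precedence is file > explicit flags > defaults, so a config file
        pins a run completely.
        """
        with open(path, "r", encoding="utf-8") as fh:
            data = json.load(fh)
        merged = {**overrides, **data}
        for key in ("annotations", "edges", "clinical", "outdir"):
            if key in merged and merged[key] is not None:
                merged[key] = Path(merged[key])
        return cls(**merged)

    def config_hash(self) -> str:
        payload = {
            k: str(v) for k, v in sorted(self.__dict__.items())
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:12]


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path: Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")


def _parse_bool(value: Any) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("true", "1", "yes", "y"):
        return True
    if s in ("false", "0", "no", "n"):
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean")


def read_annotations(path: str | Path) -> list[BeatCycleAnnotation]:
    """Read cilium annotations, converting pixels to um and frames to seconds.

    Every validation failure names the offending row (1-based, excluding the
    header) and field.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ANNOTATION_COLUMNS, path)
    out: list[BeatCycleAnnotation] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            fps = float(row.fps)
            px = float(row.pixel_size_um)
            meta = AcquisitionMeta(fps=fps, pixel_size=px)
            pts = [
                Point2D(float(getattr(row, f"x{k}")) * px,
                        float(getattr(row, f"y{k}")) * px)
                for k in range(3)
            ]
            ts = [float(getattr(row, f"t{k}")) / fps for k in range(1, 6)]
            if any(not math.isfinite(t) for t in ts):
                raise ValueError("non-finite time-point")
            ann = BeatCycleAnnotation(
                patient_id=str(row.patient_id),
                cilium_id=str(row.cilium_id),
                P0=pts[0], P1=pts[1], P2=pts[2],
                t1=ts[0], t2=ts[1], t3=ts[2], t4=ts[3], t5=ts[4],
                cycle_observed=_parse_bool(row.cycle_observed),
                meta=meta,
            )
        except Exception as exc:
            raise ParseError(f"{path}: row {i}: {exc}", row=i) from exc
        out.append(ann)
    return out


def write_annotations(annotations: Sequence[BeatCycleAnnotation], path: str | Path) -> None:
    """Write annotations back to CSV in file units (pixels, frame indices)."""
    rows = []
    for a in annotations:
        px = a.meta.pixel_size
        fps = a.meta.fps
        rows.append({
            "patient_id": a.patient_id,
            "cilium_id": a.cilium_id,
            "fps": fps,
            "pixel_size_um": px,
            "x0": a.P0.x / px, "y0": a.P0.y / px,
            "x1": a.P1.x / px, "y1": a.P1.y / px,
            "x2": a.P2.x / px, "y2": a.P2.y / px,
            "t1": a.t1 * fps, "t2": a.t2 * fps, "t3": a.t3 * fps,
            "t4": a.t4 * fps, "t5": a.t5 * fps,
            "cycle_observed": a.cycle_observed,
        })
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)


def read_edges(path: str | Path) -> list[EdgeObservation]:
    """Read per-area edge observations."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, EDGE_COLUMNS, path)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(
                EdgeObservation(
                    patient_id=str(row.patient_id),
                    area_id=int(row.area_id),
                    beating_score=float(row.beating_score),
                    pattern_label=str(row.pattern_label),
                    dyskinesia_score=float(row.dyskinesia_score),
                )
            )
        except Exception as exc:
            raise ParseError(f"{path}: row {i}: {exc}", row=i) from exc
    return out


def write_edges(edges: Sequence[EdgeObservation], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": e.patient_id,
                "area_id": e.area_id,
                "beating_score": e.beating_score,
                "pattern_label": e.pattern_label,
                "dyskinesia_score": e.dyskinesia_score,
            }
            for e in edges
        ],
        columns=EDGE_COLUMNS,
    ).to_csv(path, index=False)


def read_clinical(path: str | Path) -> list[GoldStandardInput]:
    """Read the per-patient clinical (gold standard) TSV."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, CLINICAL_COLUMNS, path)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(
                GoldStandardInput(
                    patient_id=str(row.patient_id),
                    no_n=float(row.no_n_nl_min),
                    tem_pct_abnormal=float(row.tem_pct_abnormal),
                    same_defect=_parse_bool(row.same_defect),
                )
            )
        except Exception as exc:
            raise ParseError(f"{path}: row {i}: {exc}", row=i) from exc
    return out


def write_clinical(inputs: Sequence[GoldStandardInput], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": g.patient_id,
                "no_n_nl_min": g.no_n,
                "tem_pct_abnormal": g.tem_pct_abnormal,
                "same_defect": g.same_defect,
            }
            for g in inputs
        ],
        columns=CLINICAL_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def records_from_tables(
    annotations: Sequence[BeatCycleAnnotation], edges: Sequence[EdgeObservation]
) -> list[PatientRecord]:
    """Group annotations and edges into per-patient records (sorted ids)."""
    by_patient: dict[str, PatientRecord] = {}
    for e in edges:
        by_patient.setdefault(e.patient_id, PatientRecord(e.patient_id)).edges.append(e)
    for a in annotations:
        by_patient.setdefault(a.patient_id, PatientRecord(a.patient_id)).cilia.append(a)
    records = [by_patient[pid] for pid in sorted(by_patient)]
    # canonical within-patient order makes reports byte-identical under
    # input row shuffles (float summation order matters at the last ulp)
    for r in records:
        r.edges.sort(key=lambda e: e.area_id)
        r.cilia.sort(key=lambda a: a.cilium_id)
    return records


def summary_table(summaries: Sequence[PatientSummary]) -> pd.DataFrame:
    """Per-patient summary in the reference-table layout (percentages,
    dyskinesia score, weighted distance and area)."""
    return pd.DataFrame(
        [
            {
                "patient_id": s.patient_id,
                "pct_abnormal_total": s.pct_abnormal_pattern,
                "pct_virtually_immotile": s.pct_virtually_immotile,
                "pct_stiff": s.pct_stiff,
                "pct_circular": s.pct_circular,
                "dyskinesia_score": s.mean_dyskinesia,
                "weighted_dist_um_per_s": s.mean_weighted_dist_per_s,
                "weighted_area_um2_per_s": s.mean_weighted_area_per_s,
            }
            for s in summaries
        ]
    )


def run_full_analysis(
    config: RunConfig,
    annotations: Sequence[BeatCycleAnnotation] | None = None,
    edges: Sequence[EdgeObservation] | None = None,
    clinical: Sequence[GoldStandardInput] | None = None,
) -> dict[str, Any]:
    """Run the whole pipeline and return a JSON-serialisable report.

    Inputs may be passed directly or read from the paths in ``config``. The
    report contains per-patient summaries, gold-standard groups,
    Mann–Whitney statistics per kinematic parameter (PCD vs non-PCD),
    a Kruskal–Wallis test of the weighted distance across all three groups,
    the patient-level ROC of the mean weighted distance with named cutoffs,
    and three-zone calls for the inconclusive patients. Output is
    deterministic given identical inputs.
    """
    if annotations is None:
        if config.annotations is None:
            raise ConfigurationError("no annotation input provided")
        annotations = read_annotations(config.annotations)
        logger.info("annotations %s sha256:%s", config.annotations,
                    file_checksum(config.annotations))
    if edges is None:
        if config.edges is None:
            raise ConfigurationError("no edge input provided")
        edges = read_edges(config.edges)
        logger.info("edges %s sha256:%s", config.edges, file_checksum(config.edges))
    if clinical is None:
        if config.clinical is None:
            raise ConfigurationError("no clinical input provided")
        clinical = read_clinical(config.clinical)
        logger.info("clinical %s sha256:%s", config.clinical,
                    file_checksum(config.clinical))

    records = records_from_tables(annotations, edges)
    record_ids = {r.patient_id for r in records}
    clinical_ids = {g.patient_id for g in clinical}
    orphans = sorted(record_ids ^ clinical_ids)
    if orphans:
        raise ConsistencyError(
            f"patient ids do not match across files: {orphans}", orphans=orphans
        )

    summaries = {r.patient_id: summarize_patient(r) for r in records}
    groups = {g.patient_id: gold_standard_classify(g) for g in clinical}

    pcd_ids = sorted(p for p, g in groups.items() if g == "PCD")
    non_ids = sorted(p for p, g in groups.items() if g == "non_PCD")
    inc_ids = sorted(p for p, g in groups.items() if g == "inconclusive")

    stats_block: dict[str, Any] = {}
    if pcd_ids and non_ids:
        for name in BeatCycleParameters.FIELD_NAMES:
            a = [summaries[p].param_means[name] for p in pcd_ids]
            b = [summaries[p].param_means[name] for p in non_ids]
            u, pval = mann_whitney(a, b)
            stats_block[name] = {"U": u, "p": pval}

    wdist = {p: summaries[p].mean_weighted_dist_per_s for p in summaries}
    kw_block = None
    if pcd_ids and non_ids and inc_ids:
        h, pval = kruskal_wallis(
            [
                [wdist[p] for p in pcd_ids],
                [wdist[p] for p in non_ids],
                [wdist[p] for p in inc_ids],
            ]
        )
        kw_block = {"H": h, "p": pval}

    roc_block = None
    if pcd_ids and non_ids:
        roc = roc_curve(
            [wdist[p] for p in pcd_ids],
            [wdist[p] for p in non_ids],
            orientation=config.orientation,
        )
        roc_block = {
            "auc": roc.auc,
            "cutoff_balanced": roc.cutoff_balanced,
            "cutoff_sens100": roc.cutoff_sens100,
            "cutoff_spec100": roc.cutoff_spec100,
        }

    zones = {
        p: classify_three_zone(
            wdist[p], config.cutoff_spec100, config.cutoff_sens100, patient_id=p
        ).zone
        for p in inc_ids
    }

    logger.info(
        "run config %s seed %d: %d patients (%d PCD / %d non-PCD / %d inconclusive)",
        config.config_hash(), config.seed, len(records),
        len(pcd_ids), len(non_ids), len(inc_ids),
    )
    return {
        "summaries": summary_table(list(summaries.values())).to_dict(orient="records"),
        "gold_standard": groups,
        "mann_whitney": stats_block,
        "kruskal_wallis": kw_block,
        "roc": roc_block,
        "cutoffs": {
            "balanced": config.cutoff_balanced,
            "sens100": config.cutoff_sens100,
            "spec100": config.cutoff_spec100,
        },
        "zones": zones,
    }
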