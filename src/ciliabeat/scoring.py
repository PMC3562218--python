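"""Edge-level scoring and per-patient aggregation.

Twenty distinct areas of intact ciliated epithelial edge are recorded per
patient. Each area receives:

* a *beating score* — 1 when a majority of cilia beat, 0.5 when about half
  beat, 0 when a minority beat;
* a qualitative *beat-pattern label* — normal, virtually immotile, stiff, or
  circular (assigned by a human observer, never computed here);
* a *ciliary dyskinesia score* in [0, 3] — 0 for coordinated normal beating,
  1–3 grading the extent of dyskinetic beating along the edge.

The fraction of beating ciliated edges (sum of scores / number of areas)
weights the per-cilium distance and area rates; pattern labels are reduced to
per-patient percentages and dyskinesia scores to a per-patient mean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import InsufficientDataError, InvalidLabelError, InvalidScoreError
from .kinematics import BeatCycleAnnotation, BeatCycleParameters, compute_all

__all__ = [
    "PATTERN_LABELS",
    "BEATING_SCORES",
    "EdgeObservation",
    "PatientRecord",
    "PatientSummary",
    "beating_fraction",
    "pattern_percentages",
    "mean_dyskinesia",
    "summarize_patient",
]

PATTERN_LABELS = ("normal", "virtually_immotile", "stiff", "circular")
BEATING_SCORES = (0.0, 0.5, 1.0)
NOMINAL_N_EDGES = 20
NOMINAL_N_CILIA = 10


@dataclass(frozen=True)
class EdgeObservation:
    """One scored epithelial area (nominally 1 of 20 per patient)."""

    patient_id: str
    area_id: int
    beating_score: float
    pattern_label: str
    dyskinesia_score: float

    def __post_init__(self):
        if self.beating_score not in BEATING_SCORES:
            raise InvalidScoreError(
                f"beating_score must be one of {BEATING_SCORES}, got {self.beating_score}"
            )
        if self.pattern_label not in PATTERN_LABELS:
            raise InvalidLabelError(
                f"unknown pattern label {self.pattern_label!r}; expected one of {PATTERN_LABELS}"
            )
        if not (0.0 <= self.dyskinesia_score <= 3.0):
            raise InvalidScoreError(
                f"dyskinesia_score must lie in [0, 3], got {self.dyskinesia_score}"
            )


@dataclass
class PatientRecord:
    """All raw observations for one patient: edges plus annotated cilia."""

    patient_id: str
    edges: list[EdgeObservation] = field(default_factory=list)
    cilia: list[BeatCycleAnnotation] = field(default_factory=list)


@dataclass
class PatientSummary:
    """Aggregated per-patient results.

    ``param_means`` / ``param_sds`` map each of the 12 kinematic parameter
    names to its mean and sample (n-1) standard deviation over the patient's
    cilia; the weighted rates are computed per cilium with the patient's own
    beating fraction before averaging.
    """

    patient_id: str
    n_edges: int
    n_cilia: int
    beating_fraction: float
    pct_normal: float
    pct_abnormal_pattern: float
    pct_virtually_immotile: float
    pct_stiff: float
    pct_circular: float
    mean_dyskinesia: float
    param_means: dict[str, float]
    param_sds: dict[str, float]

    @property
    def mean_weighted_dist_per_s(self) -> float:
        return self.param_means["weighted_dist_per_s"]

    @property
    def mean_weighted_area_per_s(self) -> float:
        return self.param_means["weighted_area_per_s"]


def _require_edges(edges: Sequence[EdgeObservation], what: str) -> None:
    if len(edges) == 0:
        raise InsufficientDataError(f"cannot compute {what} from an empty edge list")


def beating_fraction(edges: Sequence[EdgeObservation]) -> float:
    """Fraction of beating ciliated edges: sum of beating scores / n edges.

    Emits a warning when the number of edges differs from the nominal 20.
    """
    _require_edges(edges, "beating fraction")
    if len(edges) != NOMINAL_N_EDGES:
        warnings.warn(
            f"expected {NOMINAL_N_EDGES} edge observations, got {len(edges)}",
            stacklevel=2,
        )
    return sum(e.beating_score for e in edges) / len(edges)


def pattern_percentages(edges: Sequence[EdgeObservation]) -> dict[str, float]:
    """Percentage of edges per beat-pattern label (sums to 100)."""
    _require_edges(edges, "pattern percentages")
    counts = {label: 0 for label in PATTERN_LABELS}
    for e in edges:
        counts[e.pattern_label] += 1
    return {label: 100.0 * n / len(edges) for label, n in counts.items()}


def mean_dyskinesia(edges: Sequence[EdgeObservation]) -> float:
    """Arithmetic mean of the per-edge ciliary dyskinesia scores."""
    _require_edges(edges, "mean dyskinesia score")
    return float(np.mean([e.dyskinesia_score for e in edges]))


def _sample_sd(values: np.ndarray) -> float:
    # sample (n-1) SD; a single observation has undefined spread -> 0, and
    # identical values give exactly 0 (mean rounding would leak ~1e-17)
    if values.size < 2 or np.all(values == values[0]):
        return 0.0
    return float(np.std(values, ddof=1))


def summarize_patient(record: PatientRecord) -> PatientSummary:
    """Aggregate a patient's edge observations and cilium annotations.

    The beating fraction is computed first, then every cilium's 12 parameters
    (weighted rates using that fraction), then per-parameter mean and sample
    SD over the cilia.
    """
    if not record.edges or not record.cilia:
        raise InsufficientDataError(
            f"patient {record.patient_id}: need at least one edge observation "
            "and one cilium annotation"
        )
    if len(record.cilia) != NOMINAL_N_CILIA:
        warnings.warn(
            f"patient {record.patient_id}: expected {NOMINAL_N_CILIA} cilia, "
            f"got {len(record.cilia)}",
            stacklevel=2,
        )
    frac = beating_fraction(record.edges)
    pct = pattern_percentages(record.edges)
    per_cilium = [compute_all(ann, fraction=frac) for ann in record.cilia]

    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for name in BeatCycleParameters.FIELD_NAMES:
        vals = np.array([getattr(p, name) for p in per_cilium], dtype=float)
        means[name] = float(vals.mean())
        sds[name] = _sample_sd(vals)

    return PatientSummary(
        patient_id=record.patient_id,
        n_edges=len(record.edges),
        n_cilia=len(record.cilia),
        beating_fraction=frac,
        pct_normal=pct["normal"],
        pct_abnormal_pattern=100.0 - pct["normal"],
        pct_virtually_immotile=pct["virtually_immotile"],
        pct_stiff=pct["stiff"],
        pct_circular=pct["circular"],
        mean_dyskinesia=mean_dyskinesia(record.edges),
        param_means=means,
        param_sds=sds,
    )
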