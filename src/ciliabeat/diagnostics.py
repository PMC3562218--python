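"""Gold-standard grouping, ROC analysis, and three-zone diagnostic calls.

The diagnostic reference ("gold standard") combines transmission electron
microscopy (TEM) with nasal nitric-oxide output (NOn, nl/min):

* **PCD** — more than 90% ultrastructurally abnormal cilia, all sharing the
  same defect, with NOn below 100 nl/min;
* **non-PCD** — fewer than 20% abnormal cilia with NOn at or above
  100 nl/min;
* **inconclusive** — any discordant TEM/NOn combination.

A kinematic screening parameter (typically the weighted distance travelled
per second, where *low* values indicate PCD) is evaluated against this
reference with an empirical ROC curve. Three named cutoffs are extracted:

* ``cutoff_spec100`` — the 100%-specificity cutoff: values below it occur in
  no reference-negative subject, so falling under it *supports* PCD;
* ``cutoff_sens100`` — the 100%-sensitivity cutoff: values above it occur in
  no reference-positive subject, so exceeding it argues *against* PCD;
* ``cutoff_balanced`` — the Youden-index maximiser (max sensitivity +
  specificity − 1).

Patients whose gold standard is inconclusive are then placed in one of three
zones: ``pcd_supported`` below the 100%-specificity cutoff, ``pcd_excluded``
above the 100%-sensitivity cutoff, ``indeterminate`` in between.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, InsufficientDataError, UndefinedRateError

__all__ = [
    "GoldStandardInput",
    "RocResult",
    "ZoneClassification",
    "gold_standard_classify",
    "roc_curve",
    "sens_spec_at",
    "find_named_cutoffs",
    "classify_three_zone",
    "mann_whitney",
    "kruskal_wallis",
]

Orientation = Literal["lower", "higher"]

# TEM / NOn decision limits of the reference standard
TEM_PCD_MIN_PCT = 90.0     # > 90% abnormal cilia required for PCD
TEM_NONPCD_MAX_PCT = 20.0  # < 20% abnormal cilia required for non-PCD
NO_N_CUTOFF = 100.0        # nl/min


@dataclass(frozen=True)
class GoldStandardInput:
    """TEM + nasal-NO evidence for one patient.

    ``same_defect`` is True when all abnormal cilia share a single
    ultrastructural defect (heterogeneous phenotypes are False).
    """

    patient_id: str
    no_n: float                # nasal NO output, nl/min
    tem_pct_abnormal: float    # % abnormal cilia on TEM
    same_defect: bool = False

    def __post_init__(self):
        if self.no_n < 0:
            raise ConfigurationError(f"NOn must be >= 0, got {self.no_n}")
        if not (0.0 <= self.tem_pct_abnormal <= 100.0):
            raise ConfigurationError(
                f"TEM % abnormal must lie in [0, 100], got {self.tem_pct_abnormal}"
            )


def gold_standard_classify(g: GoldStandardInput) -> str:
    """Assign ``'PCD'``, ``'non_PCD'`` or ``'inconclusive'`` from TEM + NOn."""
    if g.tem_pct_abnormal > TEM_PCD_MIN_PCT and g.same_defect and g.no_n < NO_N_CUTOFF:
        return "PCD"
    if g.tem_pct_abnormal < TEM_NONPCD_MAX_PCT and g.no_n >= NO_N_CUTOFF:
        return "non_PCD"
    return "inconclusive"


@dataclass
class RocResult:
    """Empirical ROC curve with AUC and named cutoffs.

    ``thresholds`` are in sweep order (the direction along which both rates
    are non-decreasing). With ``orientation='lower'`` a subject is called
    positive when its value is strictly below the threshold.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    orientation: Orientation
    cutoff_balanced: float
    cutoff_sens100: float
    cutoff_spec100: float


def _rates_at(
    pos: np.ndarray, neg: np.ndarray, thresholds: np.ndarray, orientation: Orientation
) -> tuple[np.ndarray, np.ndarray]:
    t = thresholds[:, None]
    if orientation == "lower":
        tpr = (pos[None, :] < t).mean(axis=1)
        fpr = (neg[None, :] < t).mean(axis=1)
    else:
        tpr = (pos[None, :] > t).mean(axis=1)
        fpr = (neg[None, :] > t).mean(axis=1)
    return tpr, fpr


def _auc_rank(pos: np.ndarray, neg: np.ndarray, orientation: Orientation) -> float:
    # AUC = P(pos more extreme than neg) + 0.5*P(tie), via midranks;
    # identical to the tie-corrected Mann-Whitney U / (n1*n2).
    pooled = np.concatenate([pos, neg])
    ranks = stats.rankdata(pooled)
    r_pos = ranks[: pos.size].sum()
    n1, n2 = pos.size, neg.size
    u_pos_greater = r_pos - n1 * (n1 + 1) / 2.0  # pairs with pos > neg (+0.5 ties)
    auc_higher = u_pos_greater / (n1 * n2)
    return float(1.0 - auc_higher) if orientation == "lower" else float(auc_higher)


def roc_curve(
    pos_values: Sequence[float],
    neg_values: Sequence[float],
    orientation: Orientation = "lower",
) -> RocResult:
    """Empirical ROC of a continuous marker against binary reference groups.

    ``pos_values`` are the marker values of reference-positive (PCD)
    subjects, ``neg_values`` those of reference-negative subjects. With the
    default ``orientation='lower'``, lower marker values indicate disease.

    Thresholds are swept over every observed value and the point immediately
    above it, so each step of the empirical curve is represented on both
    sides. The AUC is tie-corrected and equals the Mann–Whitney U statistic
    divided by ``n1 * n2``.
    """
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise InsufficientDataError("ROC requires at least one value in each group")

    uniq = np.unique(np.concatenate([pos, neg]))
    # each observed value and the representable number just above it
    cand = np.unique(np.concatenate([uniq, np.nextafter(uniq, np.inf)]))
    if orientation == "higher":
        # sweep downward so rates grow along the sweep
        cand = np.concatenate([[np.nextafter(uniq[0], -np.inf)], cand])[::-1]
    tpr, fpr = _rates_at(pos, neg, cand, orientation)

    auc = _auc_rank(pos, neg, orientation)
    result = RocResult(
        thresholds=cand,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        orientation=orientation,
        cutoff_balanced=np.nan,
        cutoff_sens100=np.nan,
        cutoff_spec100=np.nan,
    )
    balanced, sens100, spec100 = find_named_cutoffs(result)
    result.cutoff_balanced = balanced
    result.cutoff_sens100 = sens100
    result.cutoff_spec100 = spec100
    return result


def find_named_cutoffs(roc: RocResult) -> tuple[float, float, float]:
    """Extract (balanced, sens100, spec100) cutoffs from an empirical ROC.

    * ``sens100`` — the least extreme threshold attaining sensitivity 1,
      i.e. the one that keeps specificity maximal while missing no positive;
    * ``spec100`` — the least extreme threshold attaining specificity 1,
      i.e. the one that keeps sensitivity maximal while mislabelling no
      negative;
    * ``balanced`` — the Youden maximiser (midpoint of the maximising run).

    When the two groups separate perfectly the two 100% regions overlap and
    the convention ``sens100 >= spec100`` (for lower-indicates-positive)
    would invert; both cutoffs are then collapsed to the centre of the
    separating gap.
    """
    t, tpr, fpr = roc.thresholds, roc.tpr, roc.fpr
    if np.all(tpr == tpr[0]) and np.all(fpr == fpr[0]):
        raise UndefinedRateError("degenerate ROC: rates never change along the sweep")

    sens1 = np.flatnonzero(tpr >= 1.0)
    spec1 = np.flatnonzero(fpr <= 0.0)
    if sens1.size == 0 or spec1.size == 0:
        raise UndefinedRateError("ROC sweep does not reach sensitivity or specificity 1")
    # sweep order is rate-increasing: first index with tpr==1 is the least
    # extreme full-sensitivity threshold; last with fpr==0 the least extreme
    # full-specificity one
    sens100 = float(t[sens1[0]])
    spec100 = float(t[spec1[-1]])

    j = tpr - fpr
    jmax = j.max()
    attain = np.flatnonzero(j >= jmax - 1e-12)
    # midpoint of the first contiguous maximising run
    run_end = attain[0]
    for idx in attain:
        if idx - run_end > 1:
            break
        run_end = idx
    balanced = float((t[attain[0]] + t[run_end]) / 2.0)

    inverted = sens100 < spec100 if roc.orientation == "lower" else sens100 > spec100
    if inverted:  # perfect separation: any threshold in the gap is optimal
        mid = float((sens100 + spec100) / 2.0)
        sens100 = spec100 = mid
    return balanced, sens100, spec100


def sens_spec_at(
    values: Sequence[float],
    labels: Sequence[bool],
    cutoff: float,
    orientation: Orientation = "lower",
) -> tuple[float, float]:
    """Sensitivity and specificity of a threshold on labelled marker values.

    With ``orientation='lower'`` a subject is called positive when its value
    is strictly below the cutoff; values at or above count toward
    specificity. ``labels`` are True for reference-positive subjects.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    if v.shape != lab.shape:
        raise ConfigurationError("values and labels must have equal length")
    if lab.all() or (~lab).all():
        raise UndefinedRateError("sensitivity/specificity need both classes present")
    if orientation == "lower":
        called_pos = v < cutoff
    else:
        called_pos = v > cutoff
    sensitivity = float(called_pos[lab].mean())
    specificity = float((~called_pos)[~lab].mean())
    return sensitivity, specificity


@dataclass(frozen=True)
class ZoneClassification:
    """Three-zone diagnostic call for one patient."""

    patient_id: str
    value: float
    zone: Literal["pcd_supported", "pcd_excluded", "indeterminate"]


def classify_three_zone(
    mean_weighted_dist: float,
    spec100: float,
    sens100: float,
    patient_id: str = "",
) -> ZoneClassification:
    """Place a patient's mean weighted distance into a diagnostic zone.

    Strictly below the 100%-specificity cutoff supports PCD; strictly above
    the 100%-sensitivity cutoff argues against it; anything else (cutoff
    values included) is indeterminate — boundary cases are deliberately left
    open rather than forced into a diagnosis.
    """
    if spec100 > sens100:
        raise ConfigurationError(
            f"inverted cutoffs: spec100={spec100} must not exceed sens100={sens100}"
        )
    if mean_weighted_dist < spec100:
        zone = "pcd_supported"
    elif mean_weighted_dist > sens100:
        zone = "pcd_excluded"
    else:
        zone = "indeterminate"
    return ZoneClassification(patient_id=patient_id, value=mean_weighted_dist, zone=zone)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Mann–Whitney U (pairs of ``a`` exceeding ``b``, ties 0.5) and two-sided p.

    The p-value uses the normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("Mann-Whitney requires two nonempty samples")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) and chi-square p across >= 2 groups."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise InsufficientDataError("Kruskal-Wallis requires >= 2 nonempty groups")
    res = stats.kruskal(*[np.asarray(g, dtype=float) for g in groups])
    return float(res.statistic), float(res.pvalue)
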