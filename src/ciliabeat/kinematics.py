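"""Per-cilium beat-cycle kinematics.

One beating cycle of a cilium followed frame-by-frame on high-speed video is
summarised by three landmark points and five time-points:

* ``P0`` — the base of the cilium;
* ``P1`` / ``P2`` — the tip positions before the power (active) stroke and
  before the recovery stroke, i.e. the two angular extremes of the tip;
* ``t1``/``t2`` — start and arrival of the power stroke;
* ``t3``/``t4`` — start and arrival of the recovery stroke;
* ``t5`` — start of the following cycle.

Twelve kinematic parameters are derived from these eight measurements:
cilium length ``Lc``, beating angle (the angle P1–P0–P2 at the base),
global frequency ``Fg = 1/(t5 - t1)``, the four phase durations
(power-stroke duration ``Dp``, recovery duration ``Dr``, pause after stroke
``Ps``, pause after recovery ``Pr``), the total pause ``Pt = Ps + Pr``, the
distance travelled by the tip per second ``Lc·angle·Fg``, the area swept per
second ``(angle/2)·Lc²·Fg``, and the latter two weighted by the patient's
fraction of beating ciliated edges.

Angles are radians throughout; lengths are micrometres; times are seconds.
Coordinates follow the image convention (origin top-left, y down) but every
formula here is invariant to that choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import DegenerateGeometryError, InvalidAnnotationError, InvalidScoreError

__all__ = [
    "Point2D",
    "AcquisitionMeta",
    "BeatCycleAnnotation",
    "BeatCycleParameters",
    "cilia_length",
    "beating_angle",
    "global_frequency",
    "stroke_timings",
    "distance_per_second",
    "area_per_second",
    "weight_by_beating_fraction",
    "compute_all",
    "frames_to_seconds",
    "seconds_to_frames",
    "pixels_to_um",
    "um_to_pixels",
]


@dataclass(frozen=True)
class Point2D:
    """A point in the image plane, in micrometres."""

    x: float
    y: float

    def __post_init__(self):
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InvalidAnnotationError(f"non-finite coordinates ({self.x}, {self.y})")

    def distance_to(self, other: "Point2D") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


@dataclass(frozen=True)
class AcquisitionMeta:
    """Recording geometry of the high-speed video.

    Defaults match the acquisition protocol the toolkit targets: 355 frames/s,
    1,800 frames per movie, 256 x 192 pixels of (0.13 um)^2 each.
    """

    fps: float = 355.0
    pixel_size: float = 0.13
    n_frames: int = 1800
    width: int = 256
    height: int = 192

    def __post_init__(self):
        if not (self.fps > 0):
            raise InvalidAnnotationError(f"fps must be > 0, got {self.fps}")
        if not (self.pixel_size > 0):
            raise InvalidAnnotationError(f"pixel_size must be > 0, got {self.pixel_size}")


def frames_to_seconds(frame_index: float, fps: float) -> float:
    """Convert a 0-based frame index to seconds."""
    return frame_index / fps


def seconds_to_frames(t: float, fps: float) -> float:
    return t * fps


def pixels_to_um(value_px: float, pixel_size: float) -> float:
    return value_px * pixel_size


def um_to_pixels(value_um: float, pixel_size: float) -> float:
    return value_um / pixel_size


@dataclass(frozen=True)
class BeatCycleAnnotation:
    """The raw measurement of one cilium: landmarks plus cycle time-points.

    Times are seconds (typically integer frame indices divided by ``fps``).
    ``cycle_observed`` is False when no complete cycle could be identified for
    this cilium (tip never returned to its starting extreme); such cilia
    contribute zero frequency / distance / area by convention.
    """

    patient_id: str
    cilium_id: str
    P0: Point2D
    P1: Point2D
    P2: Point2D
    t1: float = 0.0
    t2: float = 0.0
    t3: float = 0.0
    t4: float = 0.0
    t5: float = 0.0
    cycle_observed: bool = True
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)

    def __post_init__(self):
        ts = (self.t1, self.t2, self.t3, self.t4, self.t5)
        if any(not math.isfinite(t) for t in ts):
            raise InvalidAnnotationError(f"non-finite time-point in {ts}")
        if self.cycle_observed:
            if not (self.t1 < self.t2 <= self.t3 < self.t4 <= self.t5):
                raise InvalidAnnotationError(
                    f"time-points must satisfy t1 < t2 <= t3 < t4 <= t5, got {ts}"
                )


@dataclass(frozen=True)
class BeatCycleParameters:
    """The 12 kinematic parameters computed for one cilium."""

    length_Lc: float          # um
    angle: float              # rad, in [0, pi]
    freq_fg: float            # Hz
    dur_power_Dp: float       # s
    dur_recovery_Dr: float    # s
    pause_after_stroke_Ps: float   # s
    pause_after_recovery_Pr: float  # s
    pause_total_Pt: float     # s
    dist_per_s: float         # um
    area_per_s: float         # um^2
    weighted_dist_per_s: float   # um
    weighted_area_per_s: float   # um^2

    FIELD_NAMES = (
        "length_Lc", "angle", "freq_fg", "dur_power_Dp", "dur_recovery_Dr",
        "pause_after_stroke_Ps", "pause_after_recovery_Pr", "pause_total_Pt",
        "dist_per_s", "area_per_s", "weighted_dist_per_s", "weighted_area_per_s",
    )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.FIELD_NAMES}


def _check_finite_points(*points: Point2D) -> None:
    for p in points:
        if not (math.isfinite(p.x) and math.isfinite(p.y)):
            raise InvalidAnnotationError("non-finite landmark coordinates")


def cilia_length(P0: Point2D, P1: Point2D, P2: Point2D) -> float:
    """Cilium length ``Lc = max(|P0P1|, |P0P2|)`` in micrometres.

    The longer of the two base-to-tip arms is used because the shorter one may
    be foreshortened when the tip dips slightly out of the focal plane.
    """
    _check_finite_points(P0, P1, P2)
    return max(P0.distance_to(P1), P0.distance_to(P2))


def beating_angle(P0: Point2D, P1: Point2D, P2: Point2D) -> float:
    """Beating angle P1–P0–P2 in radians, by the law of cosines.

    ``angle = arccos[(|P0P1|² + |P0P2|² − |P1P2|²) / (2·|P0P1|·|P0P2|)]``

    The cosine argument is clamped to [-1, 1] so that collinear landmarks do
    not produce a domain error from rounding.

    Raises
    ------
    DegenerateGeometryError
        If either arm has zero length. Callers handling flagged immotile
        cilia may substitute an angle of 0.
    """
    _check_finite_points(P0, P1, P2)
    a = P0.distance_to(P1)
    b = P0.distance_to(P2)
    if a == 0.0 or b == 0.0:
        raise DegenerateGeometryError(
            "beating angle undefined: tip coincides with base (zero-length arm)"
        )
    c = P1.distance_to(P2)
    cos_arg = (a * a + b * b - c * c) / (2.0 * a * b)
    return math.acos(min(1.0, max(-1.0, cos_arg)))


def global_frequency(t1: float, t5: float) -> float:
    """Global beat frequency ``Fg = 1/(t5 - t1)`` in Hz."""
    if not (t5 > t1):
        raise InvalidAnnotationError(f"need t5 > t1 for frequency, got t1={t1}, t5={t5}")
    return 1.0 / (t5 - t1)


def stroke_timings(
    t1: float, t2: float, t3: float, t4: float, t5: float
) -> tuple[float, float, float, float, float]:
    """Phase durations ``(Dp, Dr, Ps, Pr, Pt)`` in seconds.

    ``Dp = t2 - t1`` (power stroke), ``Dr = t4 - t3`` (recovery),
    ``Ps = t3 - t2`` (pause after stroke), ``Pr = t5 - t4`` (pause after
    recovery), ``Pt = Ps + Pr``. By construction
    ``Dp + Dr + Ps + Pr = t5 - t1``, the full cycle period.
    """
    if not (t1 < t2 <= t3 < t4 <= t5):
        raise InvalidAnnotationError(
            f"time-points must satisfy t1 < t2 <= t3 < t4 <= t5, got {(t1, t2, t3, t4, t5)}"
        )
    Dp = t2 - t1
    Dr = t4 - t3
    Ps = t3 - t2
    Pr = t5 - t4
    return Dp, Dr, Ps, Pr, Ps + Pr


def distance_per_second(Lc: float, angle: float, fg: float) -> float:
    """Distance travelled by the tip per second: ``Lc · angle · Fg`` (um).

    The tip sweeps an arc of radius ``Lc`` subtending ``angle`` once per
    cycle, ``Fg`` cycles per second.
    """
    if Lc < 0 or angle < 0 or fg < 0:
        raise InvalidAnnotationError("distance_per_second inputs must be >= 0")
    return Lc * angle * fg


def area_per_second(Lc: float, angle: float, fg: float) -> float:
    """Area swept by the cilium per second: ``(angle/2) · Lc² · Fg`` (um^2)."""
    if Lc < 0 or angle < 0 or fg < 0:
        raise InvalidAnnotationError("area_per_second inputs must be >= 0")
    return 0.5 * angle * Lc * Lc * fg


def weight_by_beating_fraction(value: float, fraction: float) -> float:
    """Weight a rate by the patient's fraction of beating ciliated edges."""
    if not (0.0 <= fraction <= 1.0):
        raise InvalidScoreError(f"beating fraction must lie in [0, 1], got {fraction}")
    return fraction * value


def compute_all(annotation: BeatCycleAnnotation, fraction: float = 1.0) -> BeatCycleParameters:
    """Compute all 12 kinematic parameters for one annotated cilium.

    ``fraction`` is the patient-level fraction of beating ciliated edges in
    [0, 1] used for the two weighted rates.

    When ``cycle_observed`` is False the frequency, durations, distance and
    area are set to 0 by convention; length and angle are still computed from
    the landmarks when the geometry permits (a tip coincident with the base
    yields angle 0).
    """
    Lc = cilia_length(annotation.P0, annotation.P1, annotation.P2)
    try:
        angle = beating_angle(annotation.P0, annotation.P1, annotation.P2)
    except DegenerateGeometryError:
        if annotation.cycle_observed:
            raise
        angle = 0.0  # immotile cilium whose tip never left the base

    if annotation.cycle_observed:
        fg = global_frequency(annotation.t1, annotation.t5)
        Dp, Dr, Ps, Pr, Pt = stroke_timings(
            annotation.t1, annotation.t2, annotation.t3, annotation.t4, annotation.t5
        )
    else:
        fg = Dp = Dr = Ps = Pr = Pt = 0.0

    dist = distance_per_second(Lc, angle, fg)
    area = area_per_second(Lc, angle, fg)
    return BeatCycleParameters(
        length_Lc=Lc,
        angle=angle,
        freq_fg=fg,
        dur_power_Dp=Dp,
        dur_recovery_Dr=Dr,
        pause_after_stroke_Ps=Ps,
        pause_after_recovery_Pr=Pr,
        pause_total_Pt=Pt,
        dist_per_s=dist,
        area_per_s=area,
        weighted_dist_per_s=weight_by_beating_fraction(dist, fraction),
        weighted_area_per_s=weight_by_beating_fraction(area, fraction),
    )
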