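"""Synthetic beating-cilium generator, renderer, tracker and auto-annotator.

The generative model is the exact counterpart of the measurement model: a
rigid arm of fixed length anchored at a base point whose angular position
follows a plateau–ramp cycle — dwell at the pre-power extreme for the pause
after recovery, linear sweep through the beating angle over the power-stroke
duration, dwell for the pause after stroke, linear sweep back over the
recovery duration. Per-frame Gaussian angular noise models tip-localisation
jitter. The four phase durations sum to the cycle period by construction.

A rendered movie (multi-page grayscale stack, default geometry 355 frames/s
and 256 x 192 pixels of 0.13 um) can be tracked back (:func:`track_tip`) and
auto-annotated (:func:`annotate_cycle`), closing the loop
simulate → render → track → annotate → compute so that every stage of the
kinematic pipeline is testable against known ground truth without patient
video. :func:`simulate_cohort` scales this up to whole synthetic patient
groups with PCD-like and non-PCD-like parameter profiles.

The "circular" beat pattern has no dwell structure; it is represented as tip
motion on an ellipse about the base (a stated convention of this simulator)
and yields no annotatable sweep–dwell cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, GeometryError, TrackingFailureError
from .kinematics import AcquisitionMeta, BeatCycleAnnotation, Point2D
from .scoring import PATTERN_LABELS, EdgeObservation, PatientRecord

__all__ = [
    "BeatModel",
    "TipTrajectory",
    "CohortProfile",
    "NON_PCD_LIKE",
    "PCD_LIKE",
    "simulate_trajectory",
    "annotation_from_model",
    "render_stack",
    "track_tip",
    "annotate_cycle",
    "simulate_cohort",
]

_DUR_TOL = 1e-9


@dataclass(frozen=True)
class BeatModel:
    """Ground-truth kinematics of one synthetic cilium.

    ``base_angle`` orients the pre-power-stroke arm in the image plane; the
    power stroke sweeps the tip from ``base_angle`` to
    ``base_angle + angle_amplitude``. The four phase durations must sum to
    ``1/freq``.
    """

    base: Point2D
    length: float                 # um
    angle_amplitude: float        # rad, in [0, pi]
    freq: float                   # Hz
    dur_power: float              # s
    dur_recovery: float           # s
    pause_after_stroke: float     # s
    pause_after_recovery: float   # s
    pattern: str = "normal"
    angular_noise_sd: float = 0.0  # rad per frame
    base_angle: float = 0.0        # rad
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.angle_amplitude <= math.pi):
            raise ConfigurationError(
                f"angle_amplitude must lie in [0, pi], got {self.angle_amplitude}"
            )
        if self.pattern not in PATTERN_LABELS:
            raise ConfigurationError(f"unknown beat pattern {self.pattern!r}")
        if self.length < 0 or self.angular_noise_sd < 0:
            raise ConfigurationError("length and angular_noise_sd must be >= 0")
        if self.freq > 0:
            total = (
                self.dur_power
                + self.dur_recovery
                + self.pause_after_stroke
                + self.pause_after_recovery
            )
            if abs(total - 1.0 / self.freq) > _DUR_TOL * max(1.0, 1.0 / self.freq):
                raise ConfigurationError(
                    f"phase durations sum to {total:.6g} s but the period is "
                    f"{1.0 / self.freq:.6g} s"
                )
        if any(
            d < 0
            for d in (
                self.dur_power,
                self.dur_recovery,
                self.pause_after_stroke,
                self.pause_after_recovery,
            )
        ):
            raise ConfigurationError("phase durations must be >= 0")

    @classmethod
    def from_phase_fractions(
        cls,
        base: Point2D,
        length: float,
        angle_amplitude: float,
        freq: float,
        frac_power: float = 0.25,
        frac_pause_stroke: float = 0.10,
        frac_recovery: float = 0.45,
        frac_pause_recovery: float = 0.20,
        **kwargs,
    ) -> "BeatModel":
        """Build a model from a frequency plus phase fractions of the period.

        The four fractions are renormalised to sum to 1, so any positive
        weights may be given. The defaults reflect the usual asymmetry of
        mucociliary beating: a fast power stroke and a slower recovery.
        """
        fr = np.array(
            [frac_power, frac_pause_stroke, frac_recovery, frac_pause_recovery],
            dtype=float,
        )
        if (fr < 0).any() or fr.sum() <= 0:
            raise ConfigurationError("phase fractions must be >= 0 with positive sum")
        fr = fr / fr.sum()
        period = 1.0 / freq
        return cls(
            base=base,
            length=length,
            angle_amplitude=angle_amplitude,
            freq=freq,
            dur_power=fr[0] * period,
            pause_after_stroke=fr[1] * period,
            dur_recovery=fr[2] * period,
            pause_after_recovery=fr[3] * period,
            **kwargs,
        )


@dataclass
class TipTrajectory:
    """Per-frame tip positions (um) with the base point and frame rate."""

    positions: np.ndarray  # shape (n_frames, 2)
    fps: float
    base: Point2D

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.positions)) / self.fps


def _phase_angle(model: BeatModel, t_mod: np.ndarray) -> np.ndarray:
    """Angular offset from base_angle at cycle phase t_mod in [0, period)."""
    pr = model.pause_after_recovery
    dp = model.dur_power
    ps = model.pause_after_stroke
    dr = model.dur_recovery
    amp = model.angle_amplitude
    ang = np.empty_like(t_mod)

    in_dwell1 = t_mod < pr
    in_power = (t_mod >= pr) & (t_mod < pr + dp)
    in_dwell2 = (t_mod >= pr + dp) & (t_mod < pr + dp + ps)
    in_recovery = t_mod >= pr + dp + ps

    ang[in_dwell1] = 0.0
    if dp > 0:
        ang[in_power] = amp * (t_mod[in_power] - pr) / dp
    else:
        ang[in_power] = amp
    ang[in_dwell2] = amp
    if dr > 0:
        ang[in_recovery] = amp * (1.0 - (t_mod[in_recovery] - pr - dp - ps) / dr)
    else:
        ang[in_recovery] = 0.0
    return ang


def simulate_trajectory(
    model: BeatModel, duration: float, fps: float = 355.0
) -> TipTrajectory:
    """Sample the tip position of a synthetic cilium at the camera frame rate.

    The cycle starts in the pre-power dwell: the tip sits at the
    pre-power-stroke extreme for ``pause_after_recovery``, sweeps linearly
    through the beating angle over ``dur_power``, dwells for
    ``pause_after_stroke`` and sweeps back over ``dur_recovery``. Per-frame
    Gaussian noise of ``angular_noise_sd`` radians is added to the angular
    position. Deterministic for a fixed ``model.seed``.
    """
    if duration <= 0 or fps <= 0:
        raise ConfigurationError("duration and fps must be > 0")
    n = int(round(duration * fps))
    if n < 1:
        raise ConfigurationError("duration shorter than one frame")
    t = np.arange(n) / fps
    rng = np.random.default_rng(model.seed)

    if model.pattern == "circular":
        # elliptical orbit about the base, no dwell structure
        omega = 2.0 * math.pi * model.freq
        a, b = model.length, 0.5 * model.length
        phase = omega * t
        x_loc = a * np.cos(phase)
        y_loc = b * np.sin(phase)
        c, s = math.cos(model.base_angle), math.sin(model.base_angle)
        xs = model.base.x + c * x_loc - s * y_loc
        ys = model.base.y + s * x_loc + c * y_loc
        if model.angular_noise_sd > 0:
            jitter = rng.normal(0.0, model.angular_noise_sd, size=n)
            xs += -model.length * np.sin(phase + model.base_angle) * jitter
            ys += model.length * np.cos(phase + model.base_angle) * jitter
        return TipTrajectory(np.column_stack([xs, ys]), fps, model.base)

    if model.freq > 0:
        t_mod = np.mod(t, 1.0 / model.freq)
        ang = _phase_angle(model, t_mod)
    else:
        ang = np.zeros(n)
    theta = model.base_angle + ang
    if model.angular_noise_sd > 0:
        theta = theta + rng.normal(0.0, model.angular_noise_sd, size=n)
    xs = model.base.x + model.length * np.cos(theta)
    ys = model.base.y + model.length * np.sin(theta)
    return TipTrajectory(np.column_stack([xs, ys]), fps, model.base)


def annotation_from_model(
    model: BeatModel,
    patient_id: str = "sim",
    cilium_id: str = "c0",
    fps: float = 355.0,
    snap_to_frames: bool = False,
) -> BeatCycleAnnotation:
    """Ground-truth annotation of one cycle, straight from the model.

    ``t1`` is the start of the first power stroke (after the initial
    pre-power dwell), so the annotated cycle is the first complete one of
    the trajectory :func:`simulate_trajectory` would produce. Circular
    models and zero-frequency / zero-amplitude models have no annotatable
    cycle and return ``cycle_observed=False``.
    """
    p0 = model.base
    th1 = model.base_angle
    th2 = model.base_angle + model.angle_amplitude
    p1 = Point2D(p0.x + model.length * math.cos(th1), p0.y + model.length * math.sin(th1))
    p2 = Point2D(p0.x + model.length * math.cos(th2), p0.y + model.length * math.sin(th2))

    observable = (
        model.pattern != "circular"
        and model.freq > 0
        and model.angle_amplitude > 0
        and model.dur_power > 0
        and model.dur_recovery > 0
        and model.length > 0
    )
    if not observable:
        return BeatCycleAnnotation(
            patient_id=patient_id, cilium_id=cilium_id,
            P0=p0, P1=p1, P2=p2, cycle_observed=False,
            meta=AcquisitionMeta(fps=fps),
        )

    t1 = model.pause_after_recovery
    t2 = t1 + model.dur_power
    t3 = t2 + model.pause_after_stroke
    t4 = t3 + model.dur_recovery
    t5 = t4 + model.pause_after_recovery
    ts = [t1, t2, t3, t4, t5]
    if snap_to_frames:
        ts = [round(t * fps) / fps for t in ts]
        if not (ts[0] < ts[1] <= ts[2] < ts[3] <= ts[4]):
            # a phase shorter than one frame collapsed under snapping
            return BeatCycleAnnotation(
                patient_id=patient_id, cilium_id=cilium_id,
                P0=p0, P1=p1, P2=p2, cycle_observed=False,
                meta=AcquisitionMeta(fps=fps),
            )
    return BeatCycleAnnotation(
        patient_id=patient_id, cilium_id=cilium_id,
        P0=p0, P1=p1, P2=p2,
        t1=ts[0], t2=ts[1], t3=ts[2], t4=ts[3], t5=ts[4],
        cycle_observed=True,
        meta=AcquisitionMeta(fps=fps),
    )


def render_stack(
    traj: TipTrajectory,
    meta: AcquisitionMeta | None = None,
    psf_sigma: float = 0.2,
    snr: float = np.inf,
    seed: int = 0,
) -> np.ndarray:
    """Render a trajectory as a grayscale image stack in [0, 1].

    Each frame draws the base-to-tip segment by sub-pixel bilinear splatting
    of densely sampled points, blurs it with a Gaussian point-spread function
    of ``psf_sigma`` micrometres, and adds Gaussian noise with standard
    deviation ``peak/snr``. Returns an array of shape
    ``(n_frames, height, width)``.
    """
    meta = meta or AcquisitionMeta()
    px = meta.pixel_size
    h, w = meta.height, meta.width
    base = np.array([traj.base.x, traj.base.y]) / px
    tips = traj.positions / px
    margin = 1.0
    all_pts = np.vstack([tips, base[None, :]])
    if (
        (all_pts[:, 0] < margin).any()
        or (all_pts[:, 0] > w - 1 - margin).any()
        or (all_pts[:, 1] < margin).any()
        or (all_pts[:, 1] > h - 1 - margin).any()
    ):
        raise GeometryError(
            "cilium leaves the field of view; enlarge the image or move the base"
        )

    rng = np.random.default_rng(seed)
    stack = np.zeros((len(traj), h, w), dtype=np.float64)
    for i, tip in enumerate(tips):
        seg = tip - base
        seg_len = float(np.hypot(*seg))
        n_samples = max(2, int(math.ceil(seg_len / 0.25)) + 1)
        pts = base[None, :] + np.linspace(0.0, 1.0, n_samples)[:, None] * seg[None, :]
        frame = np.zeros((h, w), dtype=np.float64)
        x0 = np.floor(pts[:, 0]).astype(int)
        y0 = np.floor(pts[:, 1]).astype(int)
        fx = pts[:, 0] - x0
        fy = pts[:, 1] - y0
        np.add.at(frame, (y0, x0), (1 - fx) * (1 - fy))
        np.add.at(frame, (y0, x0 + 1), fx * (1 - fy))
        np.add.at(frame, (y0 + 1, x0), (1 - fx) * fy)
        np.add.at(frame, (y0 + 1, x0 + 1), fx * fy)
        if psf_sigma > 0:
            frame = ndimage.gaussian_filter(frame, sigma=psf_sigma / px)
        peak = frame.max()
        if peak > 0:
            frame /= peak
        if np.isfinite(snr) and snr > 0:
            frame = frame + rng.normal(0.0, 1.0 / snr, size=frame.shape)
        stack[i] = np.clip(frame, 0.0, 1.0)
    return stack


def track_tip(
    stack: np.ndarray,
    base: Point2D,
    threshold: float = 0.5,
    meta: AcquisitionMeta | None = None,
) -> TipTrajectory:
    """Recover the tip trajectory from an image stack.

    Per frame, pixels above ``threshold`` times the frame maximum form the
    foreground; the tip estimate is the foreground pixel farthest from the
    base, refined in two steps: the intensity-weighted centroid of its 3x3
    neighbourhood fixes the search radius, and the arm axis (ray from the
    base through the foreground intensity centroid) is walked to the point
    where the ridge profile drops to half its plateau value — for a
    Gaussian point-spread function that crossing sits exactly at the segment
    end. Positions are returned in micrometres.
    """
    meta = meta or AcquisitionMeta()
    px = meta.pixel_size
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise TrackingFailureError("expected a nonempty (frames, height, width) stack")
    h, w = stack.shape[1:]
    bx, by = base.x / px, base.y / px
    yy, xx = np.mgrid[0:h, 0:w]
    dist2 = (xx - bx) ** 2 + (yy - by) ** 2
    step = 0.05  # px, axial profile sampling

    out = np.empty((stack.shape[0], 2), dtype=np.float64)
    for i, frame in enumerate(stack):
        fmax = frame.max()
        fg = frame > threshold * fmax
        if fmax <= 0 or not fg.any():
            raise TrackingFailureError(
                f"no foreground pixels in frame {i}", frame_index=i
            )
        masked = np.where(fg, dist2, -1.0)
        flat = int(np.argmax(masked))
        ty, tx = divmod(flat, w)
        y0, y1 = max(0, ty - 1), min(h, ty + 2)
        x0, x1 = max(0, tx - 1), min(w, tx + 2)
        patch = frame[y0:y1, x0:x1]
        total = patch.sum()
        if total > 0:
            cy = (patch * np.arange(y0, y1)[:, None]).sum() / total
            cx = (patch * np.arange(x0, x1)[None, :]).sum() / total
        else:  # pragma: no cover - fg.any() guarantees mass
            cy, cx = float(ty), float(tx)

        # arm axis from the foreground mass centre (the segment midpoint
        # lies on the axis, so this direction is insensitive to tip noise)
        wts = np.where(fg, frame, 0.0)
        mass = wts.sum()
        mx = (wts * xx).sum() / mass
        my = (wts * yy).sum() / mass
        ux, uy = mx - bx, my - by
        norm = math.hypot(ux, uy)
        if norm < 0.5:  # degenerate blob at the base: keep the centroid fix
            out[i] = (cx * px, cy * px)
            continue
        ux, uy = ux / norm, uy / norm
        s0 = (cx - bx) * ux + (cy - by) * uy
        s = np.arange(max(0.0, s0 - 5.0), s0 + 5.0, step)
        prof = ndimage.map_coordinates(
            frame, np.array([by + uy * s, bx + ux * s]), order=1, mode="nearest"
        )
        ref = prof[0]
        above = np.flatnonzero(prof >= 0.5 * ref)
        if ref <= 0 or above.size == 0:
            out[i] = (cx * px, cy * px)
            continue
        k = int(above[-1])
        if k + 1 < len(prof) and prof[k] > prof[k + 1]:
            s_tip = s[k] + step * (prof[k] - 0.5 * ref) / (prof[k] - prof[k + 1])
        else:
            s_tip = s[k]
        out[i] = ((bx + ux * s_tip) * px, (by + uy * s_tip) * px)
    return TipTrajectory(out, meta.fps, base)


def _runs(signs: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode a sign sequence as (sign, start, end-exclusive)."""
    runs = []
    start = 0
    for i in range(1, len(signs) + 1):
        if i == len(signs) or signs[i] != signs[start]:
            runs.append((int(signs[start]), start, i))
            start = i
    return runs


def annotate_cycle(
    traj: TipTrajectory,
    patient_id: str = "sim",
    cilium_id: str = "c0",
    omega_threshold: float | None = None,
    smooth_window: int = 1,
) -> BeatCycleAnnotation:
    """Auto-annotate the first complete beat cycle of a tip trajectory.

    The tip's angular position about the base is unwrapped, optionally
    smoothed with a ``smooth_window``-frame moving average (use ~5 frames
    for trajectories recovered from images, whose localisation jitter would
    otherwise fragment the sweep/dwell segmentation), and differenced;
    inter-frame steps with |angular velocity| below ``omega_threshold``
    (default: 30% of the maximum observed speed) are dwells. The first
    complete sweep – dwell – counter-sweep – dwell – next-sweep motif gives
    the five time-points; the tip positions at the sweep boundaries give the
    landmark extremes. When no complete cycle is present (constant,
    sub-cycle or circular trajectories) the annotation is returned with
    ``cycle_observed=False``.
    """
    pos = traj.positions
    base = np.array([traj.base.x, traj.base.y])
    rel = pos - base[None, :]
    phi = np.unwrap(np.arctan2(rel[:, 1], rel[:, 0]))
    if smooth_window > 1 and len(phi) >= smooth_window:
        kernel = np.full(smooth_window, 1.0 / smooth_window)
        padded = np.pad(phi, smooth_window // 2, mode="edge")
        phi = np.convolve(padded, kernel, mode="valid")[: len(phi)]
    p0 = traj.base

    def _no_cycle() -> BeatCycleAnnotation:
        return BeatCycleAnnotation(
            patient_id=patient_id, cilium_id=cilium_id,
            P0=p0,
            P1=Point2D(*pos[0]),
            P2=Point2D(*pos[int(np.argmax(np.abs(phi - phi[0])))]),
            cycle_observed=False,
            meta=AcquisitionMeta(fps=traj.fps),
        )

    if len(pos) < 4:
        return _no_cycle()
    omega = np.diff(phi)
    peak = np.abs(omega).max()
    if peak == 0:
        return _no_cycle()
    eps = omega_threshold if omega_threshold is not None else 0.3 * peak
    signs = np.zeros(len(omega), dtype=int)
    signs[omega > eps] = 1
    signs[omega < -eps] = -1
    runs = [r for r in _runs(signs)]

    sweeps = [r for r in runs if r[0] != 0]
    if len(sweeps) < 3:
        return _no_cycle()
    # walk run triples: sweep(s), optional dwell, sweep(-s), optional dwell,
    # sweep(s) -> a complete cycle
    for idx, (s, a1, b1) in enumerate(runs):
        if s == 0:
            continue
        nxt = [r for r in runs[idx + 1:] if r[0] != 0][:2]
        if len(nxt) < 2:
            break
        (s2, a2, b2), (s3, a3, _) = nxt
        if s2 == -s and s3 == s:
            t1f, t2f, t3f, t4f, t5f = a1, b1, a2, b2, a3
            fps = traj.fps
            return BeatCycleAnnotation(
                patient_id=patient_id, cilium_id=cilium_id,
                P0=p0,
                P1=Point2D(*pos[t1f]),
                P2=Point2D(*pos[t3f]),
                t1=t1f / fps, t2=t2f / fps, t3=t3f / fps,
                t4=t4f / fps, t5=t5f / fps,
                cycle_observed=True,
                meta=AcquisitionMeta(fps=fps),
            )
    return _no_cycle()


@dataclass(frozen=True)
class CohortProfile:
    """Group-level parameter distributions for synthetic patients.

    Continuous quantities are drawn from normal distributions given as
    ``(mean, sd)`` and clipped to their physical ranges. ``pattern_probs``
    gives the per-edge probability of each qualitative label;
    ``prob_no_cycle`` is the chance that a selected cilium shows no complete
    cycle within the movie (annotated ``cycle_observed=False``).
    """

    name: str
    length_um: tuple[float, float] = (6.0, 0.5)
    angle_amplitude_rad: tuple[float, float] = (1.55, 0.15)
    freq_hz: tuple[float, float] = (7.0, 1.0)
    beating_fraction: tuple[float, float] = (0.95, 0.05)
    dyskinesia: tuple[float, float] = (0.3, 0.3)
    pattern_probs: dict[str, float] = field(
        default_factory=lambda: {"normal": 0.9, "stiff": 0.1}
    )
    prob_no_cycle: float = 0.0

    def __post_init__(self):
        if abs(sum(self.pattern_probs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("pattern_probs must sum to 1")
        if not set(self.pattern_probs) <= set(PATTERN_LABELS):
            raise ConfigurationError(f"unknown labels in {set(self.pattern_probs)}")
        if not (0.0 <= self.prob_no_cycle <= 1.0):
            raise ConfigurationError("prob_no_cycle must lie in [0, 1]")
        for nm in ("length_um", "angle_amplitude_rad", "freq_hz",
                   "beating_fraction", "dyskinesia"):
            mean, sd = getattr(self, nm)
            if sd < 0:
                raise ConfigurationError(f"{nm} sd must be >= 0")


#: Profile mimicking healthy referred patients: near-full beating edges,
#: wide fast strokes -> weighted distance of order 60 um/s.
NON_PCD_LIKE = CohortProfile(name="non_pcd_like")

#: Profile mimicking confirmed PCD: reduced amplitude and frequency, about
#: half the edges beating, high dyskinesia -> weighted distance of order
#: 2-4 um/s.
PCD_LIKE = CohortProfile(
    name="pcd_like",
    length_um=(5.5, 0.5),
    angle_amplitude_rad=(0.35, 0.10),
    freq_hz=(3.0, 1.0),
    beating_fraction=(0.5, 0.15),
    dyskinesia=(2.5, 0.4),
    pattern_probs={"virtually_immotile": 0.7, "stiff": 0.3},
    prob_no_cycle=0.2,
)

_N_EDGES = 20
_N_CILIA = 10


def simulate_cohort(
    profile: CohortProfile,
    n_patients: int,
    seed: int = 0,
    fps: float = 355.0,
    id_prefix: str | None = None,
) -> list[PatientRecord]:
    """Draw a group of synthetic patients from a parameter profile.

    Each patient receives 20 edge observations (beating score, pattern
    label, dyskinesia score) and 10 cilium annotations derived from
    per-cilium :class:`BeatModel` draws (time-points on the exact model
    grid; no rendering). Fully reproducible for a fixed seed.
    """
    if n_patients < 1:
        raise ConfigurationError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    prefix = id_prefix if id_prefix is not None else profile.name
    labels = list(profile.pattern_probs)
    probs = np.array([profile.pattern_probs[l] for l in labels])

    records: list[PatientRecord] = []
    for i in range(n_patients):
        pid = f"{prefix}_{i + 1:03d}"
        frac = float(np.clip(rng.normal(*profile.beating_fraction), 0.0, 1.0))
        edges = []
        for area in range(1, _N_EDGES + 1):
            # per-edge Bernoulli around the patient fraction keeps the
            # cohort-mean beating fraction at the profile mean
            score = 1.0 if rng.random() < frac else 0.0
            edges.append(
                EdgeObservation(
                    patient_id=pid,
                    area_id=area,
                    beating_score=score,
                    pattern_label=str(rng.choice(labels, p=probs)),
                    dyskinesia_score=float(
                        np.clip(rng.normal(*profile.dyskinesia), 0.0, 3.0)
                    ),
                )
            )
        cilia = []
        for c in range(_N_CILIA):
            model = BeatModel.from_phase_fractions(
                base=Point2D(0.0, 0.0),
                length=float(max(0.5, rng.normal(*profile.length_um))),
                angle_amplitude=float(
                    np.clip(rng.normal(*profile.angle_amplitude_rad), 0.01, math.pi)
                ),
                freq=float(max(0.5, rng.normal(*profile.freq_hz))),
                base_angle=float(rng.uniform(0.0, 2.0 * math.pi)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            ann = annotation_from_model(
                model, patient_id=pid, cilium_id=f"c{c + 1}", fps=fps
            )
            if rng.random() < profile.prob_no_cycle:
                ann = replace(
                    ann, t1=0.0, t2=0.0, t3=0.0, t4=0.0, t5=0.0, cycle_observed=False
                )
            cilia.append(ann)
        records.append(PatientRecord(patient_id=pid, edges=edges, cilia=cilia))
    return records
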