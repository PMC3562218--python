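"""Per-cilium kinematics: formulas, conventions, and geometric invariants."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ciliabeat.errors import (
    DegenerateGeometryError,
    InvalidAnnotationError,
    InvalidScoreError,
)
from ciliabeat.kinematics import (
    BeatCycleAnnotation,
    Point2D,
    area_per_second,
    beating_angle,
    cilia_length,
    compute_all,
    distance_per_second,
    frames_to_seconds,
    global_frequency,
    seconds_to_frames,
    stroke_timings,
    weight_by_beating_fraction,
)

FPS = 355.0

finite = st.floats(-100.0, 100.0, allow_nan=False)
points = st.builds(Point2D, finite, finite)


@pytest.mark.parametrize(
    "p0, p1, p2, expected",
    [
        (Point2D(0, 0), Point2D(5, 0), Point2D(0, 5), 5.0),
        (Point2D(0, 0), Point2D(0, 0), Point2D(0, 0), 0.0),
        (Point2D(0, 0), Point2D(3, 4), Point2D(5, 0), 5.0),
    ],
)
def test_cilia_length_is_longer_arm(p0, p1, p2, expected):
    assert cilia_length(p0, p1, p2) == pytest.approx(expected)


@pytest.mark.parametrize(
    "p0, p1, p2, expected",
    [
        (Point2D(0, 0), Point2D(5, 0), Point2D(0, 5), math.pi / 2),
        (Point2D(0, 0), Point2D(5, 0), Point2D(5, 0), 0.0),
        (Point2D(0, 0), Point2D(5, 0), Point2D(3, 4), math.acos(0.6)),
    ],
)
def test_beating_angle_law_of_cosines(p0, p1, p2, expected):
    assert beating_angle(p0, p1, p2) == pytest.approx(expected, abs=1e-12)


def test_beating_angle_rejects_zero_length_arm():
    with pytest.raises(DegenerateGeometryError):
        beating_angle(Point2D(0, 0), Point2D(0, 0), Point2D(1, 1))


def test_beating_angle_clamps_collinear_rounding():
    # nearly collinear landmarks must not raise a domain error
    p0 = Point2D(0.0, 0.0)
    p1 = Point2D(1.0, 0.0)
    p2 = Point2D(3.0000000000000004, 0.0)
    assert beating_angle(p0, p1, p2) == pytest.approx(0.0, abs=1e-6)


@given(points, points, points, st.floats(0, 2 * math.pi), finite, finite)
def test_beating_angle_rigid_motion_invariant(p0, p1, p2, rot, dx, dy):
    """The beat angle depends only on shape, not pose in the image plane."""
    if p0.distance_to(p1) < 1e-3 or p0.distance_to(p2) < 1e-3:
        return
    c, s = math.cos(rot), math.sin(rot)

    def move(p):
        return Point2D(c * p.x - s * p.y + dx, s * p.x + c * p.y + dy)

    a = beating_angle(p0, p1, p2)
    b = beating_angle(move(p0), move(p1), move(p2))
    assert 0.0 <= a <= math.pi
    assert a == pytest.approx(b, abs=1e-6)


@pytest.mark.parametrize(
    "t1, t5, expected",
    [
        (0.0, 1.0, 1.0),
        (frames_to_seconds(0, FPS), frames_to_seconds(355, FPS), 1.0),
        (frames_to_seconds(0, FPS), frames_to_seconds(142, FPS), 2.5),
    ],
)
def test_global_frequency(t1, t5, expected):
    assert global_frequency(t1, t5) == pytest.approx(expected)


def test_global_frequency_requires_positive_period():
    with pytest.raises(InvalidAnnotationError):
        global_frequency(1.0, 1.0)


def test_stroke_timings_examples():
    Dp, Dr, Ps, Pr, Pt = stroke_timings(0, 0.1, 0.1, 0.3, 0.3)
    assert (Dp, Dr, Ps, Pr, Pt) == pytest.approx((0.1, 0.2, 0.0, 0.0, 0.0))

    frames = (0, 35, 40, 120, 142)
    t = [f / FPS for f in frames]
    Dp, Dr, Ps, Pr, Pt = stroke_timings(*t)
    assert Dp == pytest.approx(35 / FPS)
    assert Ps == pytest.approx(5 / FPS)
    assert Dr == pytest.approx(80 / FPS)
    assert Pr == pytest.approx(22 / FPS)
    assert Pt == pytest.approx(Ps + Pr)


def test_stroke_timings_rejects_misordered_times():
    with pytest.raises(InvalidAnnotationError):
        stroke_timings(0, 0.2, 0.1, 0.3, 0.4)


@given(
    st.lists(st.integers(0, 1800), min_size=5, max_size=5).map(sorted),
)
def test_timing_closure(frames):
    """Dp + Dr + Ps + Pr always equals the full period t5 - t1 = 1/Fg."""
    f1, f2, f3, f4, f5 = frames
    if not (f1 < f2 <= f3 < f4 <= f5):
        return
    t = [f / FPS for f in frames]
    Dp, Dr, Ps, Pr, Pt = stroke_timings(*t)
    period = t[4] - t[0]
    assert Dp + Dr + Ps + Pr == pytest.approx(period, rel=1e-12)
    assert Dp + Dr + Pt == pytest.approx(1.0 / global_frequency(t[0], t[4]), rel=1e-12)


@pytest.mark.parametrize(
    "Lc, angle, fg, dist, area",
    [
        (5.0, math.acos(0.6), 8.0, 37.0918, 92.7296),
        (5.0, 0.9273, 0.0, 0.0, 0.0),
        (1.0, 1.0, 1.0, 1.0, 0.5),
        (2.0, 1.0, 1.0, 2.0, 2.0),
        (5.0, 0.0, 8.0, 0.0, 0.0),
    ],
)
def test_rates(Lc, angle, fg, dist, area):
    assert distance_per_second(Lc, angle, fg) == pytest.approx(dist, abs=1e-3)
    assert area_per_second(Lc, angle, fg) == pytest.approx(area, abs=1e-3)


@given(
    st.floats(0.01, 20), st.floats(0.001, math.pi), st.floats(0.01, 30)
)
def test_rate_relation_and_monotonicity(Lc, angle, fg):
    """dist * Lc == 2 * area; both rates grow with each factor."""
    dist = distance_per_second(Lc, angle, fg)
    area = area_per_second(Lc, angle, fg)
    assert dist * Lc == pytest.approx(2 * area, rel=1e-12)
    assert distance_per_second(Lc * 1.5, angle, fg) >= dist
    assert distance_per_second(Lc, min(math.pi, angle * 1.5), fg) >= dist
    assert distance_per_second(Lc, angle, fg * 1.5) >= dist


def test_weighting():
    assert weight_by_beating_fraction(50.0, 0.5) == 25.0
    assert weight_by_beating_fraction(37.09, 1.0) == 37.09
    assert weight_by_beating_fraction(37.09, 0.0) == 0.0
    with pytest.raises(InvalidScoreError):
        weight_by_beating_fraction(1.0, 1.5)


def _annotation(cycle_observed=True):
    return BeatCycleAnnotation(
        patient_id="p1",
        cilium_id="c1",
        P0=Point2D(0, 0),
        P1=Point2D(5, 0),
        P2=Point2D(3, 4),
        t1=0.0,
        t2=35 / FPS,
        t3=40 / FPS,
        t4=120 / FPS,
        t5=142 / FPS,
        cycle_observed=cycle_observed,
    )


def test_compute_all_composition():
    params = compute_all(_annotation(), fraction=1.0)
    assert params.length_Lc == pytest.approx(5.0)
    assert params.angle == pytest.approx(math.acos(0.6))
    assert params.freq_fg == pytest.approx(2.5)
    assert params.dist_per_s == pytest.approx(5.0 * math.acos(0.6) * 2.5)
    assert params.area_per_s == pytest.approx(0.5 * math.acos(0.6) * 25 * 2.5)
    assert params.pause_total_Pt == pytest.approx(
        params.pause_after_stroke_Ps + params.pause_after_recovery_Pr
    )
    # closure: phases fill the whole period
    total = (
        params.dur_power_Dp
        + params.dur_recovery_Dr
        + params.pause_after_stroke_Ps
        + params.pause_after_recovery_Pr
    )
    assert total == pytest.approx(1.0 / params.freq_fg, rel=1e-12)


def test_compute_all_no_cycle_zeroes_rates():
    ann = BeatCycleAnnotation(
        patient_id="p1", cilium_id="c1",
        P0=Point2D(0, 0), P1=Point2D(5, 0), P2=Point2D(3, 4),
        cycle_observed=False,
    )
    params = compute_all(ann, fraction=0.5)
    assert params.freq_fg == 0.0
    assert params.dist_per_s == 0.0
    assert params.weighted_dist_per_s == 0.0
    assert params.length_Lc == pytest.approx(5.0)  # geometry still measured
    assert params.angle == pytest.approx(math.acos(0.6))


def test_compute_all_zero_fraction_keeps_raw_rate():
    params = compute_all(_annotation(), fraction=0.0)
    assert params.dist_per_s > 0.0
    assert params.weighted_dist_per_s == 0.0


def test_annotation_rejects_bad_ordering():
    with pytest.raises(InvalidAnnotationError):
        BeatCycleAnnotation(
            patient_id="p", cilium_id="c",
            P0=Point2D(0, 0), P1=Point2D(1, 0), P2=Point2D(0, 1),
            t1=0.0, t2=0.2, t3=0.1, t4=0.3, t5=0.4,
        )


@given(st.integers(0, 100_000), st.floats(1.0, 1000.0))
def test_unit_round_trip_frames_seconds(n, fps):
    back = seconds_to_frames(frames_to_seconds(n, fps), fps)
    assert back == pytest.approx(n, rel=4e-16, abs=0)
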