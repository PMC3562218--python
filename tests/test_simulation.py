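"""Simulator, renderer, tracker and auto-annotator round trips."""

import math

import numpy as np
import pytest

from ciliabeat.diagnostics import roc_curve
from ciliabeat.errors import ConfigurationError, GeometryError, TrackingFailureError
from ciliabeat.kinematics import AcquisitionMeta, Point2D, compute_all
from ciliabeat.scoring import summarize_patient
from ciliabeat.simulation import (
    NON_PCD_LIKE,
    PCD_LIKE,
    BeatModel,
    CohortProfile,
    TipTrajectory,
    annotate_cycle,
    annotation_from_model,
    render_stack,
    simulate_cohort,
    simulate_trajectory,
    track_tip,
)

META = AcquisitionMeta()  # 355 fps, 0.13 um pixels, 256 x 192


def test_default_acquisition_geometry():
    assert META.fps == 355.0
    assert META.pixel_size == 0.13
    assert META.n_frames == 1800
    assert (META.width, META.height) == (256, 192)


def test_beat_model_validates_timing_closure():
    with pytest.raises(ConfigurationError):
        BeatModel(
            base=Point2D(0, 0), length=5.0, angle_amplitude=1.0, freq=2.0,
            dur_power=0.1, dur_recovery=0.1, pause_after_stroke=0.1,
            pause_after_recovery=0.1,  # sums to 0.4 but period is 0.5
        )


def test_trajectory_immotile_and_periodic(beat_model):
    still = BeatModel.from_phase_fractions(
        base=beat_model.base, length=5.0, angle_amplitude=0.0, freq=2.0, seed=3
    )
    traj = simulate_trajectory(still, duration=0.5)
    assert np.allclose(traj.positions, traj.positions[0], atol=1e-12)

    # 2.5 Hz is exactly 142 frames at 355 fps: consecutive cycles must agree
    traj = simulate_trajectory(beat_model, duration=0.8)
    assert np.allclose(traj.positions[:142], traj.positions[142:284], atol=1e-9)


def test_trajectory_deterministic_under_seed(beat_model):
    noisy = BeatModel.from_phase_fractions(
        base=beat_model.base, length=5.0, angle_amplitude=1.0, freq=2.0,
        angular_noise_sd=0.02, seed=9,
    )
    t1 = simulate_trajectory(noisy, duration=0.5)
    t2 = simulate_trajectory(noisy, duration=0.5)
    assert np.array_equal(t1.positions, t2.positions)


def test_trajectory_stays_within_reach(beat_model):
    noisy = BeatModel.from_phase_fractions(
        base=beat_model.base, length=5.0, angle_amplitude=1.2, freq=2.0,
        angular_noise_sd=0.05, seed=9,
    )
    traj = simulate_trajectory(noisy, duration=1.0)
    radii = np.linalg.norm(
        traj.positions - np.array([noisy.base.x, noisy.base.y]), axis=1
    )
    assert (radii <= noisy.length + 1e-9).all()  # angular noise keeps |tip-base| fixed


def test_annotate_noise_free_trajectory_recovers_model(beat_model):
    traj = simulate_trajectory(beat_model, duration=1.2)
    ann = annotate_cycle(traj)
    assert ann.cycle_observed
    params = compute_all(ann)
    assert params.freq_fg == pytest.approx(beat_model.freq, abs=0.05)
    assert math.degrees(abs(params.angle - beat_model.angle_amplitude)) < 2.0
    # recovered phase durations close on the recovered period by construction
    total = (
        params.dur_power_Dp + params.dur_recovery_Dr
        + params.pause_after_stroke_Ps + params.pause_after_recovery_Pr
    )
    assert total == pytest.approx(1.0 / params.freq_fg, rel=1e-9)


def test_annotate_constant_trajectory_flags_no_cycle():
    traj = TipTrajectory(np.tile([5.0, 5.0], (100, 1)), 355.0, Point2D(0.0, 0.0))
    assert not annotate_cycle(traj).cycle_observed


def test_annotate_circular_pattern_has_no_cycle(beat_model):
    circ = BeatModel.from_phase_fractions(
        base=beat_model.base, length=3.0, angle_amplitude=1.0, freq=2.0,
        pattern="circular", seed=2,
    )
    traj = simulate_trajectory(circ, duration=1.0)
    assert not annotate_cycle(traj).cycle_observed


def test_annotation_from_model_round_trip(beat_model):
    ann = annotation_from_model(beat_model)
    params = compute_all(ann)
    assert params.freq_fg == pytest.approx(beat_model.freq, rel=1e-12)
    assert params.angle == pytest.approx(beat_model.angle_amplitude, rel=1e-9)
    assert params.length_Lc == pytest.approx(beat_model.length, rel=1e-12)
    assert params.dur_power_Dp == pytest.approx(beat_model.dur_power, rel=1e-12)


def test_render_stack_frame_count_and_range(beat_model):
    traj = simulate_trajectory(beat_model, duration=0.1)
    stack = render_stack(traj, META, snr=20.0, seed=0)
    assert stack.shape == (len(traj), META.height, META.width)
    assert stack.min() >= 0.0 and stack.max() <= 1.0


def test_render_stack_rejects_out_of_view():
    traj = TipTrajectory(np.tile([60.0, 5.0], (3, 1)), 355.0, Point2D(1.0, 1.0))
    with pytest.raises(GeometryError):
        render_stack(traj, META)  # 60 um is past the 256 * 0.13 um field


def test_render_argmax_near_true_tip(beat_model):
    """Noise-free rendering: the farthest bright pixel sits at the tip."""
    traj = simulate_trajectory(beat_model, duration=0.05)
    stack = render_stack(traj, META, psf_sigma=0.2, snr=np.inf)
    base_px = np.array([beat_model.base.x, beat_model.base.y]) / META.pixel_size
    yy, xx = np.mgrid[0 : META.height, 0 : META.width]
    for frame, true_tip in zip(stack, traj.positions):
        fg = frame > 0.3 * frame.max()
        d2 = np.where(fg, (xx - base_px[0]) ** 2 + (yy - base_px[1]) ** 2, -1.0)
        ty, tx = divmod(int(np.argmax(d2)), META.width)
        err = np.hypot(
            tx - true_tip[0] / META.pixel_size, ty - true_tip[1] / META.pixel_size
        )
        assert err <= 1.5  # within about a pixel of the true tip


def test_track_blank_frame_fails_with_frame_index():
    stack = np.zeros((3, 16, 16))
    with pytest.raises(TrackingFailureError) as exc:
        track_tip(stack, Point2D(1.0, 1.0), meta=AcquisitionMeta(width=16, height=16))
    assert exc.value.frame_index == 0


def test_track_round_trip_half_pixel(beat_model):
    traj = simulate_trajectory(beat_model, duration=0.6)
    stack = render_stack(traj, META, psf_sigma=0.2, snr=np.inf)
    tracked = track_tip(stack, beat_model.base, threshold=0.3, meta=META)
    err_px = (
        np.linalg.norm(traj.positions - tracked.positions, axis=1) / META.pixel_size
    )
    assert np.sqrt((err_px**2).mean()) <= 0.5


def test_track_equivariant_under_180_rotation(beat_model):
    traj = simulate_trajectory(beat_model, duration=0.05)
    stack = render_stack(traj, META, psf_sigma=0.2, snr=np.inf)
    rotated = stack[:, ::-1, ::-1].copy()
    w_um = (META.width - 1) * META.pixel_size
    h_um = (META.height - 1) * META.pixel_size
    base_rot = Point2D(w_um - beat_model.base.x, h_um - beat_model.base.y)
    tracked = track_tip(rotated, base_rot, threshold=0.3, meta=META)
    expected = np.column_stack(
        [w_um - traj.positions[:, 0], h_um - traj.positions[:, 1]]
    )
    err_px = np.linalg.norm(expected - tracked.positions, axis=1) / META.pixel_size
    assert err_px.max() <= 1.0


def test_end_to_end_parameter_recovery(beat_model):
    """simulate -> render -> track -> annotate -> compute, noise-free:
    frequency within one frame quantum, angle within 2 degrees, distance
    rate within 5%."""
    traj = simulate_trajectory(beat_model, duration=1.2)
    stack = render_stack(traj, META, psf_sigma=0.2, snr=np.inf)
    tracked = track_tip(stack, beat_model.base, threshold=0.3, meta=META)
    ann = annotate_cycle(tracked, smooth_window=5)
    assert ann.cycle_observed
    params = compute_all(ann)

    true_period = 1.0 / beat_model.freq
    recovered_period = 1.0 / params.freq_fg
    assert abs(recovered_period - true_period) <= 1.0 / META.fps + 1e-12
    assert math.degrees(abs(params.angle - beat_model.angle_amplitude)) <= 2.0
    true_dist = beat_model.length * beat_model.angle_amplitude * beat_model.freq
    assert params.dist_per_s == pytest.approx(true_dist, rel=0.05)


def test_cohort_reproducible_and_separable():
    pcd = simulate_cohort(PCD_LIKE, 20, seed=101)
    non = simulate_cohort(NON_PCD_LIKE, 20, seed=202)
    again = simulate_cohort(PCD_LIKE, 20, seed=101)
    assert [r.patient_id for r in pcd] == [r.patient_id for r in again]
    assert all(
        a.t5 == b.t5 and a.P1 == b.P1
        for ra, rb in zip(pcd, again)
        for a, b in zip(ra.cilia, rb.cilia)
    )
    assert all(len(r.edges) == 20 and len(r.cilia) == 10 for r in pcd + non)

    wd_pcd = [summarize_patient(r).mean_weighted_dist_per_s for r in pcd]
    wd_non = [summarize_patient(r).mean_weighted_dist_per_s for r in non]
    assert roc_curve(wd_pcd, wd_non, orientation="lower").auc > 0.95


def test_cohort_degenerate_profile_matches_means():
    profile = CohortProfile(
        name="fixed",
        length_um=(6.0, 0.0),
        angle_amplitude_rad=(1.5, 0.0),
        freq_hz=(7.0, 0.0),
        beating_fraction=(1.0, 0.0),
        dyskinesia=(1.0, 0.0),
        pattern_probs={"normal": 1.0},
    )
    [record] = simulate_cohort(profile, 1, seed=5)
    summary = summarize_patient(record)
    assert summary.beating_fraction == 1.0
    assert summary.mean_dyskinesia == pytest.approx(1.0)
    assert summary.param_means["freq_fg"] == pytest.approx(7.0)
    assert summary.param_means["length_Lc"] == pytest.approx(6.0)
    assert summary.param_means["angle"] == pytest.approx(1.5)
    assert summary.param_means["dist_per_s"] == pytest.approx(6.0 * 1.5 * 7.0)


def test_cohort_mean_converges_with_n():
    """Group-mean error shrinks roughly like 1/sqrt(n) in patient count."""
    small = simulate_cohort(NON_PCD_LIKE, 5, seed=7)
    large = simulate_cohort(NON_PCD_LIKE, 45, seed=7)
    mu = NON_PCD_LIKE.freq_hz[0]

    def err(records):
        freqs = [summarize_patient(r).param_means["freq_fg"] for r in records]
        return abs(np.mean(freqs) - mu)

    # not strictly monotone per draw, so allow slack over the 3x size ratio
    assert err(large) <= err(small) * 3.0 + 0.05
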