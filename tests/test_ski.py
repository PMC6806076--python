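import numpy as np
import pytest

from skimocap import (
    DataError,
    DegenerateGeometryError,
    MetricConfig,
    PoseSequence,
    barelle_drag_area,
    com_velocity,
    compute_metrics,
    d_vertical,
    detect_outside_leg,
    drag_area,
    fore_aft,
    lean_angle,
    ski_frame,
)
from conftest import make_frame, random_pose, random_rotation


def _standing_pose(skeleton, com_y=0.0):
    """Upright pose over axis-aligned skis, mass shifted laterally by com_y."""
    pos = np.zeros((3, 18))
    for name in skeleton.keypoint_names:
        j = skeleton.index(name)
        if name.startswith(("ankle", "ski")):
            side = 1.0 if name.endswith("_l") else -1.0
            x = {"ski_tail": -0.8, "ski_tip": 1.0}.get(name[:-2], 0.0)
            pos[:, j] = (x, side * 0.15, 0.0)
        else:
            pos[:, j] = (0.0, com_y, 1.0)
    # spread a few points so vectors are non-degenerate
    pos[2, skeleton.index("head")] = 1.6
    pos[2, skeleton.index("neck")] = 1.4
    pos[2, skeleton.index("hip_l")] = pos[2, skeleton.index("hip_r")] = 0.9
    pos[1, skeleton.index("hip_l")] += 0.1
    pos[1, skeleton.index("hip_r")] -= 0.1
    pos[2, skeleton.index("knee_l")] = pos[2, skeleton.index("knee_r")] = 0.45
    return pos


def _sequence(frames_pos, rate=50.0):
    return PoseSequence(positions=np.stack(frames_pos), rate=rate)


def test_outside_leg_constant_com_offset(skeleton):
    """COM displaced toward the left ankle makes the right leg the outside leg."""
    seq = _sequence([_standing_pose(skeleton, com_y=0.2)] * 30)
    labels, switches = detect_outside_leg(seq)
    assert labels == ["right"] * 30
    assert switches == []


def test_outside_leg_switches_at_sign_changes(skeleton):
    frames = [_standing_pose(skeleton, com_y=0.25 if (i // 100) % 2 == 0 else -0.25) for i in range(300)]
    labels, switches = detect_outside_leg(_sequence(frames))
    assert switches == [100, 200]
    assert labels[0] == "right" and labels[150] == "left"


def test_outside_leg_first_frame_tie_raises(skeleton):
    seq = _sequence([_standing_pose(skeleton, com_y=0.0)] * 10)
    with pytest.raises(DataError):
        detect_outside_leg(seq, presmooth_hz=None)


def test_switch_detection_on_noisy_turns(reference_run):
    from skimocap import DegradationModel, degrade

    ref, annotation, _ = reference_run
    mono = degrade(ref, DegradationModel(sigma=0.02, seed=5))
    _, detected = detect_outside_leg(mono)
    for truth in annotation.switch_frames:
        assert min(abs(truth - d) for d in detected) <= 2


def test_ski_frame_axis_aligned(skeleton):
    frame = make_frame(_standing_pose(skeleton))
    sf = ski_frame(frame, "right", skeleton)
    assert np.allclose(sf.x_axis, [1, 0, 0])
    assert np.allclose(sf.z_axis, [0, 0, 1])
    assert np.allclose(sf.y_axis, [0, 1, 0])
    assert np.allclose(sf.origin, [0, -0.15, 0])
    assert np.allclose(sf.mid_origin, [0, 0, 0])


def test_ski_frame_triads_orthonormal_and_equivariant(skeleton, rng):
    pos = _standing_pose(skeleton)
    base = ski_frame(make_frame(pos), "left", skeleton)
    for _ in range(100):
        rot = random_rotation(rng)
        t = rng.normal(scale=3.0, size=3)
        sf = ski_frame(make_frame(rot @ pos + t[:, None]), "left", skeleton)
        for axis, ref_axis in zip(
            (sf.x_axis, sf.y_axis, sf.z_axis), (base.x_axis, base.y_axis, base.z_axis)
        ):
            assert np.allclose(axis, rot @ ref_axis, atol=1e-9)
        triad = np.column_stack([sf.x_axis, sf.y_axis, sf.z_axis])
        assert np.allclose(triad.T @ triad, np.eye(3), atol=1e-9)
        assert np.allclose(np.cross(sf.x_axis, sf.y_axis), sf.z_axis, atol=1e-9)


def test_ski_frame_degenerate_when_ski_parallel_to_ankle_line(skeleton):
    pos = _standing_pose(skeleton)
    # rotate the right ski onto the ankle-to-ankle (y) direction
    for name, y in (("ski_tail_r", -1.0), ("ski_tip_r", 1.0)):
        pos[:, skeleton.index(name)] = (0.0, y, 0.0)
    with pytest.raises(DegenerateGeometryError):
        ski_frame(make_frame(pos), "right", skeleton)


def test_d_vertical_examples_and_oracle(skeleton, rng):
    sf = ski_frame(make_frame(_standing_pose(skeleton)), "right", skeleton)
    assert d_vertical(sf, sf.origin + np.array([0, 0, 1.0])) == pytest.approx(1.0)
    assert d_vertical(sf, sf.origin) == 0.0
    for _ in range(20):
        com = rng.normal(size=3)
        assert d_vertical(sf, com) == pytest.approx(
            float(np.sqrt(((com - sf.origin) ** 2).sum())), abs=1e-12
        )


@pytest.mark.parametrize(
    "offset,expected",
    [
        ((0.0, 0.0, 1.0), 0.0),  # COM straight up the z' axis
        ((1.0, 0.0, 1.0), np.sin(np.radians(45))),  # equal x' and z' parts
        ((-1.0, 0.0, 1.0), -np.sin(np.radians(45))),  # aft is negative
        ((0.5, 2.0, 0.5), np.sin(np.radians(45))),  # y' component ignored
    ],
)
def test_fore_aft_sign_and_projection(skeleton, offset, expected):
    sf = ski_frame(make_frame(_standing_pose(skeleton)), "right", skeleton)
    assert fore_aft(sf, sf.origin + np.array(offset)) == pytest.approx(expected, abs=1e-12)


def test_lean_angle_examples_and_atan2_oracle(skeleton, rng):
    sf = ski_frame(make_frame(_standing_pose(skeleton)), "right", skeleton)
    assert lean_angle(sf, sf.mid_origin + np.array([0, 0, 1.0])) == pytest.approx(0.0)
    assert lean_angle(sf, sf.mid_origin + np.array([0, 0.7, 0.7])) == pytest.approx(45.0)
    for _ in range(50):
        com = sf.mid_origin + rng.normal(size=3)
        v = com - sf.mid_origin
        expected = np.degrees(np.arctan2(abs(v[1]), v[2]))
        assert lean_angle(sf, com) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize(
    "h,w,expected",
    [
        (100.0, 0.5, 0.315),
        (60.0, 0.55, 0.1991),  # tuck posture, ~0.20 m^2
        (26.0 / 3.0, 0.0, 0.0),
    ],
)
def test_barelle_model_arithmetic(h, w, expected):
    assert barelle_drag_area(h, w) == pytest.approx(expected, abs=1e-12)


def test_drag_area_projections(skeleton):
    pos = _standing_pose(skeleton)
    pos[:, skeleton.index("shoulder_l")] = (0, 0.19, 1.0)
    pos[:, skeleton.index("shoulder_r")] = (0, -0.19, 1.0)
    pos[:, skeleton.index("hand_l")] = (0, 0.5, 0.8)
    pos[:, skeleton.index("hand_r")] = (0, -0.5, 0.8)
    frame = make_frame(pos)
    sf = ski_frame(frame, "right", skeleton)
    dp = drag_area(frame, sf, velocity=np.array([10.0, 0, 0]), skeleton=skeleton)
    assert dp.h == pytest.approx(100.0)
    assert dp.w == pytest.approx(1.0)  # span orthogonal to travel
    assert dp.cda == pytest.approx(barelle_drag_area(100.0, 1.0))
    # travelling along the span direction hides the arms entirely
    dp2 = drag_area(frame, sf, velocity=np.array([0, 5.0, 0]), skeleton=skeleton)
    assert dp2.w == pytest.approx(0.0)
    with pytest.raises(DataError):
        drag_area(frame, sf, velocity=np.zeros(3), skeleton=skeleton)


def test_drag_area_polyline_span_no_smaller_than_straight(skeleton):
    pos = _standing_pose(skeleton)
    pos[:, skeleton.index("hand_l")] = (0, 0.5, 0.8)
    pos[:, skeleton.index("hand_r")] = (0, -0.5, 0.8)
    pos[:, skeleton.index("elbow_l")] = (0.2, 0.4, 0.9)
    pos[:, skeleton.index("elbow_r")] = (0.2, -0.4, 0.9)
    pos[:, skeleton.index("shoulder_l")] = (0, 0.19, 1.0)
    pos[:, skeleton.index("shoulder_r")] = (0, -0.19, 1.0)
    frame = make_frame(pos)
    sf = ski_frame(frame, "right", skeleton)
    v = np.array([10.0, 0, 0])
    straight = drag_area(frame, sf, v, skeleton, arm_span_mode="straight")
    poly = drag_area(frame, sf, v, skeleton, arm_span_mode="polyline")
    assert poly.w <= straight.w


def test_com_velocity_constant_and_stationary(skeleton):
    pos0 = _standing_pose(skeleton)
    frames = [pos0 + np.array([i * 1.0, 0, 0])[:, None] for i in range(10)]
    vel = com_velocity(_sequence(frames, rate=50.0))
    assert np.allclose(vel, [[50.0, 0.0, 0.0]] * 10)
    vel0 = com_velocity(_sequence([pos0] * 5))
    assert np.allclose(vel0, 0.0)


def test_com_velocity_exact_on_quadratic_interior(skeleton):
    rate = 50.0
    t = np.arange(20) / rate
    frames = [
        _standing_pose(skeleton) + np.array([3.0 * ti + 2.0 * ti**2, 0, 0])[:, None]
        for ti in t
    ]
    vel = com_velocity(_sequence(frames, rate=rate))
    expected = 3.0 + 4.0 * t
    assert np.allclose(vel[1:-1, 0], expected[1:-1], atol=1e-9)


def test_mirroring_flips_outside_leg_but_not_d_vertical(skeleton):
    """Reflecting the pose about the sagittal x-z plane swaps inside/outside
    and leaves the ankle-COM distance unchanged."""
    pos = _standing_pose(skeleton, com_y=0.2)
    mirrored = pos.copy()
    mirrored[1] = -mirrored[1]
    for joint in ("shoulder", "elbow", "hand", "hip", "knee", "ankle", "ski_tail", "ski_tip"):
        li, ri = skeleton.index(f"{joint}_l"), skeleton.index(f"{joint}_r")
        mirrored[:, [li, ri]] = mirrored[:, [ri, li]]
    seq_a = _sequence([pos] * 10)
    seq_b = _sequence([mirrored] * 10)
    la, _ = detect_outside_leg(seq_a)
    lb, _ = detect_outside_leg(seq_b)
    assert la == ["right"] * 10 and lb == ["left"] * 10
    ma, _ = compute_metrics(seq_a, MetricConfig(detection_presmooth_hz=None), metrics=("d_vertical",))
    mb, _ = compute_metrics(seq_b, MetricConfig(detection_presmooth_hz=None), metrics=("d_vertical",))
    assert np.allclose(ma["d_vertical"].values, mb["d_vertical"].values, atol=1e-12)


def test_compute_metrics_selection_and_fore_aft_units(reference_run):
    seq, _, _ = reference_run
    only_lean, _ = compute_metrics(seq, metrics=("lean_angle",))
    assert set(only_lean) == {"lean_angle"}
    both, _ = compute_metrics(seq, MetricConfig(fore_aft_output="both"))
    assert np.allclose(
        both["fore_aft_m"].values,
        both["fore_aft"].values * both["d_vertical"].values,
        atol=1e-12,
    )


def test_ski_metrics_invariant_under_rigid_motion(reference_run, rng):
    seq, _, _ = reference_run
    short = PoseSequence(positions=seq.positions[:40].copy(), rate=seq.rate)
    base, _ = compute_metrics(short)
    for _ in range(5):
        rot = random_rotation(rng)
        t = rng.normal(scale=20.0, size=3)
        moved = PoseSequence(
            positions=np.einsum("ij,njk->nik", rot, short.positions) + t[None, :, None],
            rate=seq.rate,
        )
        got, _ = compute_metrics(moved)
        for name in ("knee_outside", "hip_inside", "d_vertical", "fore_aft", "lean_angle", "cda"):
            assert np.allclose(got[name].values, base[name].values, atol=1e-6), name
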