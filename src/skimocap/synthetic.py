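"""Synthetic giant-slalom runs with closed-form ground truth.

The generator builds each pose in a canonical skier-local frame (x forward
along the skis, y left, z up, origin at the mid-ankle ground point) from
prescribed articulation schedules, computes every ground-truth metric there
— where the ski-relative triad is the identity, so the formulas are plain
coordinate reads — and only then places the pose on the inclined course by
a per-frame rigid motion.  The analysis pipeline, which must rediscover the
outside leg and rebuild the ski frames in world coordinates, therefore has
an independent ground truth to match (construction plus rigid-motion
equivariance).

The turn oscillator ``s(t) = sin(pi t / T + phase)`` drives everything:
``s > 0`` leans the skier left (left leg inside), the turn switch is the
zero crossing, and one turn cycle lasts ``T = gate_distance / speed``.
The course follows the study setting: three giant-slalom gates, 27 m gate
distance, 8 m gate offset, 26 degree slope, sampled at 50 Hz.

A degradation model turns the reference stream into a "monocular
prediction": a global scale error about the pelvis (monocular scale
ambiguity), per-joint systematic bias, iid Gaussian noise per coordinate,
and optional temporal jitter.  The default noise of 0.06 m per coordinate
on the non-root joints puts the scale-normalized pose error near 0.08 m,
the magnitude typical of monocular reconstruction on snow.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .io import save_pose_sequence
from .sequence import PoseSequence, TurnCycleAnnotation
from .skeleton import DEFAULT_SKELETON, SkeletonDefinition


@dataclass(frozen=True)
class CourseConfig:
    """Giant-slalom course geometry and sampling."""

    gate_distance: float = 27.0  # m along the fall line between gates
    gate_offset: float = 8.0  # m lateral distance between successive gates
    slope_angle: float = 26.0  # degrees of slope inclination
    n_gates: int = 3
    rate: float = 50.0  # Hz
    speed: float = 14.0  # m/s along the fall line

    def __post_init__(self) -> None:
        if min(self.gate_distance, self.gate_offset, self.rate, self.speed) <= 0:
            raise ConfigError("course parameters must be positive")
        if not 0 < self.slope_angle < 90:
            raise ConfigError("slope angle must lie in (0, 90) degrees")
        if self.n_gates < 1:
            raise ConfigError("need at least one gate")
        if self.cycle_duration * self.rate < 2:
            raise ConfigError("turn cycle shorter than two frames; check rate and speed")

    @property
    def cycle_duration(self) -> float:
        """One turn cycle (switch to switch) in seconds."""
        return self.gate_distance / self.speed

    @property
    def n_frames(self) -> int:
        return int(round(self.n_gates * self.cycle_duration * self.rate))


@dataclass(frozen=True)
class ArticulationProfile:
    """Periodic joint-angle and posture schedules over the turn cycle.

    Knee angles are included angles (180 = straight); the outside leg stays
    straighter than the inside leg at the turn apex.  All lengths in meters,
    angles in degrees.
    """

    knee_straight: float = 165.0  # outside-leg knee angle at apex
    knee_range: float = 30.0  # extra flexion of the inside leg at apex
    shank_tilt: float = 15.0  # constant forward tilt of the shank
    trunk_tilt_base: float = 30.0  # forward trunk tilt at the switch
    trunk_tilt_amp: float = 10.0  # extra forward tilt at the apex
    lean_tilt: float = 35.0  # lateral leg tilt at apex (drives the lean)
    trunk_lean_gain: float = 0.8  # hip angulation keeps the trunk more upright
    phase: float = np.pi / 2  # turn oscillator phase at t=0 (start at apex)
    stance_half_width: float = 0.15
    shank_length: float = 0.44
    thigh_length: float = 0.46
    trunk_length: float = 0.50
    shoulder_half_width: float = 0.19
    hand_spread_base: float = 0.30  # lateral hand offset from the shoulder
    hand_spread_amp: float = 0.10  # extra spread at the apex
    ski_tail_back: float = 0.85  # ski tail distance behind the ankle
    ski_tip_front: float = 1.05  # ski tip distance ahead of the ankle

    def __post_init__(self) -> None:
        if not 0 < self.knee_straight <= 180 or not 0 <= self.knee_range < self.knee_straight:
            raise ConfigError("knee schedule outside anatomical bounds [0, 180]")
        if any(
            v <= 0
            for v in (
                self.shank_length,
                self.thigh_length,
                self.trunk_length,
                self.stance_half_width,
            )
        ):
            raise ConfigError("segment lengths must be positive")


@dataclass(frozen=True)
class DegradationModel:
    """Monocular-error model applied to a reference stream.

    Applied in order: global scale about the pelvis, per-joint bias, iid
    Gaussian noise per coordinate, optional temporal jitter.  Deterministic
    under a fixed seed.
    """

    sigma: float | np.ndarray = 0.06  # m, per-joint noise SD (scalar or (18,))
    bias: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    scale: float = 0.95  # global scale error about the pelvis
    jitter_frames: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.sigma) < 0):
            raise ConfigError("noise sigma must be >= 0")
        if self.scale <= 0:
            raise ConfigError("scale factor must be positive")


def _rot_x(psi: float) -> np.ndarray:
    c, s = np.cos(psi), np.sin(psi)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(phi: float) -> np.ndarray:
    c, s = np.cos(phi), np.sin(phi)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _local_pose(
    t: float,
    s: float,
    art: ArticulationProfile,
    skeleton: SkeletonDefinition,
) -> np.ndarray:
    """One 3x18 pose in the canonical skier-local frame for oscillator value s."""
    kp = {}
    d = art.stance_half_width
    kp["ankle_l"] = np.array([0.0, d, 0.0])
    kp["ankle_r"] = np.array([0.0, -d, 0.0])
    for side in ("l", "r"):
        a = kp[f"ankle_{side}"]
        kp[f"ski_tail_{side}"] = a + np.array([-art.ski_tail_back, 0.0, 0.0])
        kp[f"ski_tip_{side}"] = a + np.array([art.ski_tip_front, 0.0, 0.0])

    psi = np.radians(art.lean_tilt) * s  # lateral leg tilt, s > 0 leans left (+y)
    tilt = _rot_x(-psi)
    alpha = np.radians(art.shank_tilt)
    u_shank = np.array([np.sin(alpha), 0.0, np.cos(alpha)])
    # inside leg (sign of s) flexes more; outside stays straighter
    knee_angle = {
        "l": art.knee_straight - art.knee_range * (1.0 + s) / 2.0,
        "r": art.knee_straight - art.knee_range * (1.0 - s) / 2.0,
    }
    for side in ("l", "r"):
        gamma = -np.radians(180.0 - knee_angle[side])
        u_thigh = _rot_y(gamma) @ u_shank
        knee = kp[f"ankle_{side}"] + art.shank_length * (tilt @ u_shank)
        kp[f"knee_{side}"] = knee
        kp[f"hip_{side}"] = knee + art.thigh_length * (tilt @ u_thigh)

    mid_hip = 0.5 * (kp["hip_l"] + kp["hip_r"])
    tau = np.radians(art.trunk_tilt_base + art.trunk_tilt_amp * s * s)
    trunk_rot = _rot_x(-art.trunk_lean_gain * psi) @ _rot_y(tau)
    t_hat = trunk_rot @ np.array([0.0, 0.0, 1.0])  # trunk up, tilted forward/lateral
    y_t = trunk_rot @ np.array([0.0, 1.0, 0.0])
    x_t = trunk_rot @ np.array([1.0, 0.0, 0.0])
    neck = mid_hip + art.trunk_length * t_hat
    kp["neck"] = neck
    kp["head"] = neck + 0.15 * t_hat
    spread = art.hand_spread_base + art.hand_spread_amp * s * s
    for side, sgn in (("l", 1.0), ("r", -1.0)):
        shoulder = neck - 0.03 * t_hat + sgn * art.shoulder_half_width * y_t
        hand = shoulder + sgn * spread * y_t + 0.25 * x_t - 0.25 * t_hat
        elbow = 0.5 * (shoulder + hand) + 0.06 * sgn * y_t - 0.03 * t_hat
        kp[f"shoulder_{side}"] = shoulder
        kp[f"hand_{side}"] = hand
        kp[f"elbow_{side}"] = elbow

    pose = np.empty((3, len(skeleton.keypoint_names)))
    for j, name in enumerate(skeleton.keypoint_names):
        pose[:, j] = kp[name]
    return pose


def _course_basis(course: CourseConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Across-slope, down-fall-line and slope-normal unit vectors (z up world)."""
    beta = np.radians(course.slope_angle)
    e_across = np.array([1.0, 0.0, 0.0])
    e_fall = np.array([0.0, np.cos(beta), -np.sin(beta)])
    normal = np.array([0.0, np.sin(beta), np.cos(beta)])
    return e_across, e_fall, normal


def _vary_profile(art: ArticulationProfile, rng: np.random.Generator) -> ArticulationProfile:
    """Small per-run style variation: +/-5% on amplitudes, phase within the apex half."""
    g = lambda: 1.0 + rng.uniform(-0.05, 0.05)
    return replace(
        art,
        knee_straight=min(art.knee_straight * g(), 179.0),
        knee_range=art.knee_range * g(),
        lean_tilt=art.lean_tilt * g(),
        trunk_tilt_base=art.trunk_tilt_base * g(),
        hand_spread_base=art.hand_spread_base * g(),
        phase=art.phase + rng.uniform(-0.1, 0.1) * np.pi,
    )


def generate_reference_run(
    course: CourseConfig = CourseConfig(),
    art: ArticulationProfile = ArticulationProfile(),
    seed: int | None = None,
    skeleton: SkeletonDefinition = DEFAULT_SKELETON,
    subject_id: str = "S1",
    trial_id: str = "T1",
    straight: bool = False,
) -> tuple[PoseSequence, TurnCycleAnnotation, dict]:
    """Simulate one reference run over the course.

    ``straight=True`` freezes the turn oscillator at its initial value:
    a straight schuss with no gates, a constant outside leg and no switches.

    Returns the world-frame pose sequence, the ground-truth turn-cycle
    annotation (switches at the oscillator zero crossings) and a dict of
    closed-form ground-truth metric series: knee/hip angles of the outside
    and inside leg, lean angle, fore/aft sine (and meters), d_vertical,
    world COM and pelvis-relative COM, drag area with its h and w inputs,
    and the per-frame outside-side labels.

    With a seed, segment amplitudes and the turn phase receive a small
    reproducible per-run variation (inter-trial style differences).
    """
    if seed is not None:
        art = _vary_profile(art, np.random.default_rng(seed))

    n = course.n_frames
    times = np.arange(n) / course.rate
    omega = np.pi / course.cycle_duration
    s = np.sin(omega * times + art.phase)
    if straight:
        s = np.full(n, np.sin(art.phase))

    e_across, e_fall, normal = _course_basis(course)
    amp = course.gate_offset / 2.0
    u = -amp * s  # lateral course coordinate; sign ties path curvature to lean
    du = np.zeros(n) if straight else -amp * omega * np.cos(omega * times + art.phase)

    names = skeleton.keypoint_names
    idx = {nm: j for j, nm in enumerate(names)}
    weights = skeleton.mass_array
    w_sum = weights.sum()

    positions = np.empty((n, 3, len(names)))
    truth: dict[str, list] = {
        k: []
        for k in (
            "knee_outside",
            "knee_inside",
            "hip_outside",
            "hip_inside",
            "lean_angle",
            "fore_aft",
            "fore_aft_m",
            "d_vertical",
            "h_cm",
        )
    }
    com_world = np.empty((n, 3))
    com_rel = np.empty((n, 3))
    outside: list[str] = []
    span_world = np.empty((n, 3))
    span_total = np.empty(n)

    for i, (t, s_i) in enumerate(zip(times, s)):
        local = _local_pose(t, s_i, art, skeleton)
        # world placement: heading along the path tangent in the slope plane
        x_w = course.speed * e_fall + du[i] * e_across
        x_w = x_w / np.linalg.norm(x_w)
        y_w = np.cross(normal, x_w)
        rot = np.column_stack([x_w, y_w, normal])
        origin = u[i] * e_across + course.speed * t * e_fall
        positions[i] = rot @ local + origin[:, None]

        # ground truth in the local frame, where the ski triad is the identity
        com_l = local @ weights / w_sum
        out = "right" if s_i > 0 else "left"
        outside.append(out)
        inn = "left" if out == "right" else "right"
        a_out = local[:, idx[f"ankle_{out[0]}"]]
        mid_ankle = 0.5 * (local[:, idx["ankle_l"]] + local[:, idx["ankle_r"]])
        mid_hip = 0.5 * (local[:, idx["hip_l"]] + local[:, idx["hip_r"]])
        v = com_l - a_out
        dv = float(np.linalg.norm(v))
        truth["d_vertical"].append(dv)
        fa = float(np.sin(np.arctan2(v[0], v[2])))
        truth["fore_aft"].append(fa)
        truth["fore_aft_m"].append(fa * dv)
        vm = com_l - mid_ankle
        truth["lean_angle"].append(float(np.degrees(np.arctan2(abs(vm[1]), vm[2]))))
        truth["knee_outside"].append(
            art.knee_straight - art.knee_range * (1.0 - abs(s_i)) / 2.0
        )
        truth["knee_inside"].append(
            art.knee_straight - art.knee_range * (1.0 + abs(s_i)) / 2.0
        )
        for key, side in (("hip_outside", out), ("hip_inside", inn)):
            hip = local[:, idx[f"hip_{side[0]}"]]
            knee = local[:, idx[f"knee_{side[0]}"]]
            neck = local[:, idx["neck"]]
            v1 = neck - mid_hip
            v2 = knee - hip
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            truth[key].append(float(np.degrees(np.arccos(np.clip(cosang, -1, 1)))))
        mid_sh = 0.5 * (local[:, idx["shoulder_l"]] + local[:, idx["shoulder_r"]])
        truth["h_cm"].append(float((mid_sh - mid_ankle)[2]) * 100.0)
        com_world[i] = rot @ com_l + origin
        com_rel[i] = rot @ (com_l - mid_hip)
        sp = local[:, idx["hand_r"]] - local[:, idx["hand_l"]]
        span_world[i] = rot @ sp
        span_total[i] = np.linalg.norm(sp)

    # drag area ground truth: central-difference velocity of the analytic COM
    vel = np.gradient(com_world, axis=0) * course.rate
    v_hat = vel / np.linalg.norm(vel, axis=1, keepdims=True)
    perp = span_world - np.sum(span_world * v_hat, axis=1, keepdims=True) * v_hat
    w_arm = np.clip(np.linalg.norm(perp, axis=1) / span_total, 0.0, 1.0)
    h_cm = np.asarray(truth["h_cm"])
    truth_arrays = {k: np.asarray(vals) for k, vals in truth.items()}
    truth_arrays["w"] = w_arm
    truth_arrays["cda"] = 0.003 * h_cm - 0.026 + 0.041 * (2.0 * w_arm)
    truth_arrays["com_world"] = com_world
    truth_arrays["com_rel"] = com_rel
    truth_arrays["outside_side"] = outside

    switches = [i for i in range(1, n) if (s[i] > 0) != (s[i - 1] > 0)]
    truth_arrays["switch_frames"] = switches

    seq = PoseSequence(
        positions=positions,
        rate=course.rate,
        subject_id=subject_id,
        trial_id=trial_id,
        camera_id="REF",
        reference_flag=True,
        skeleton=skeleton,
    )
    annotation = TurnCycleAnnotation(tuple(switches))
    return seq, annotation, truth_arrays


def degrade(seq: PoseSequence, model: DegradationModel) -> PoseSequence:
    """Apply the monocular degradation model to a reference sequence."""
    rng = np.random.default_rng(model.seed)
    skeleton = seq.skeleton
    out = seq.copy()
    out.reference_flag = False
    out.camera_id = "MONO"

    if model.scale != 1.0:  # identity scale stays bit-exact
        mid_hip = 0.5 * (
            out.positions[:, :, skeleton.index("hip_l")]
            + out.positions[:, :, skeleton.index("hip_r")]
        )
        out.positions = mid_hip[:, :, None] + model.scale * (
            out.positions - mid_hip[:, :, None]
        )
    for name, vec in model.bias.items():
        out.positions[:, :, skeleton.index(name)] += np.asarray(vec, dtype=float)

    sigma_in = np.asarray(model.sigma, dtype=float)
    if sigma_in.ndim == 0:
        # scalar sigma applies to the non-root joints; the hips (the pelvis
        # root of a relative-pose prediction) stay exact by construction
        sigma = np.full(out.n_keypoints, float(sigma_in))
        sigma[[skeleton.index("hip_l"), skeleton.index("hip_r")]] = 0.0
    else:
        sigma = np.broadcast_to(sigma_in, (out.n_keypoints,)).copy()
    if np.any(sigma > 0):
        noise = rng.normal(0.0, 1.0, out.positions.shape) * sigma[None, None, :]
        out.positions = out.positions + noise

    if model.jitter_frames:
        shift = int(model.jitter_frames)
        out.positions = np.roll(out.positions, shift, axis=0)
        edge = out.positions[shift] if shift > 0 else out.positions[shift - 1]
        if shift > 0:
            out.positions[:shift] = edge
        else:
            out.positions[shift:] = edge
    return out


def make_fixture_set(
    out_dir: str | Path,
    n_subjects: int = 6,
    n_trials: int = 4,
    seed: int = 0,
    course: CourseConfig = CourseConfig(),
    art: ArticulationProfile = ArticulationProfile(),
    degradation: DegradationModel = DegradationModel(),
) -> dict:
    """Write a subjects-by-trials layout of reference/monocular CSV pairs.

    Mirrors a six-subject, four-trial validation campaign.  Every stochastic
    step derives its own stream from ``seed``, so a rerun with the same seed
    is byte-identical.  Returns (and writes) the manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trials = []
    for s_i in range(n_subjects):
        for t_i in range(n_trials):
            run_seed = int(
                np.random.SeedSequence(seed, spawn_key=(s_i, t_i)).generate_state(1)[0]
                % (2**31)
            )
            subject, trial = f"S{s_i + 1}", f"T{t_i + 1}"
            ref, annotation, _ = generate_reference_run(
                course, art, seed=run_seed, skeleton=DEFAULT_SKELETON,
                subject_id=subject, trial_id=trial,
            )
            mono = degrade(ref, replace(degradation, seed=run_seed + 1))
            ref_path = out_dir / f"{subject}_{trial}_ref.csv"
            mono_path = out_dir / f"{subject}_{trial}_mono.csv"
            save_pose_sequence(ref, ref_path)
            save_pose_sequence(mono, mono_path)
            trials.append(
                {
                    "subject": subject,
                    "trial": trial,
                    "seed": run_seed,
                    "reference": ref_path.name,
                    "monocular": mono_path.name,
                    "switch_frames": list(annotation.switch_frames),
                }
            )
    manifest = {
        "n_subjects": n_subjects,
        "n_trials": n_trials,
        "seed": seed,
        "course": {
            "gate_distance": course.gate_distance,
            "gate_offset": course.gate_offset,
            "slope_angle": course.slope_angle,
            "n_gates": course.n_gates,
            "rate": course.rate,
            "speed": course.speed,
        },
        "degradation": {
            "sigma": float(np.mean(degradation.sigma)),
            "scale": degradation.scale,
            "jitter_frames": degradation.jitter_frames,
            "bias": {k: list(v) for k, v in degradation.bias.items()},
        },
        "trials": trials,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return manifest
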