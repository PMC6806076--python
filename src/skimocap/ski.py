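"""Ski-relative coordinate frames and skiing-specific metrics.

Because a monocular camera gives no slope calibration, the local "up" is
built from the skier alone: x' is the outside-ski longitudinal axis,
z' = unit(x' x a) with a the left-to-right ankle direction, the sign chosen
so z' points toward the neck, and y' = z' x x' completes the right-handed
triad.  The origin sits on the outside ankle; a second triad with the same
axes but origin at the mid-ankle point (x'', y'', z'') hosts the lean angle.

Metrics:

* ``d_vertical`` — Euclidean distance from outside ankle to COM (m).
* ``d_fore_aft`` — sine of the angle between z' and the ankle->COM vector
  projected to the x'-z' plane, positive toward the ski tip.
* ``lean_angle`` — unsigned angle between z'' and the mid-ankle->COM vector
  projected to the y''-z'' plane (degrees).
* ``cda`` — Barelle's empirical drag area 0.003*h - 0.026 + 0.041*(2w),
  with h the ankle-to-shoulder height along z' in centimeters and w the
  arm span projected orthogonally to the COM velocity, normalized by the
  total arm span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DataError, DegenerateGeometryError
from .kinematics import (
    EPS_NORM,
    angle_between,
    com_relative,
    com_relative_series,
    hip_flexion,
    knee_flexion,
)
from .sequence import PoseFrame, PoseSequence, TurnCycleAnnotation
from .skeleton import DEFAULT_SKELETON, SkeletonDefinition


@dataclass(frozen=True)
class SkiFrame:
    """Orthonormal ski-relative triad, at the outside ankle and at mid-ankle."""

    origin: np.ndarray  # outside ankle
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray
    mid_origin: np.ndarray  # midpoint of the ankles
    outside_side: str  # 'left' | 'right'

    # the mid-ankle triad (x'', y'', z'') shares the axes and shifts the origin
    @property
    def mid_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.x_axis, self.y_axis, self.z_axis


@dataclass(frozen=True)
class DragPosture:
    """Inputs and output of the Barelle posture drag model."""

    h: float  # projected ankle-to-shoulder height, centimeters
    w: float  # normalized projected arm span, dimensionless in [0, 1]
    cda: float  # drag area, m^2


@dataclass
class MetricSeries:
    """A per-frame scalar (or 3-vector) metric with a name and units."""

    name: str
    values: np.ndarray
    units: str
    side_labels: list[str] | None = None


@dataclass(frozen=True)
class MetricConfig:
    """Tunables of the ski-metric pipeline."""

    smoothing_window: int = 5  # frames, majority filter on outside-leg labels
    detection_presmooth_hz: float | None = 1.0  # low-pass for the switch signal
    eps: float = EPS_NORM
    arm_span_mode: str = "straight"  # 'straight' | 'polyline'
    fore_aft_output: str = "sine"  # 'sine' | 'meters' | 'both'
    angle_convention: str = "included"


def detect_outside_leg(
    seq: PoseSequence,
    skeleton: SkeletonDefinition | None = None,
    smoothing_window: int = 5,
    eps: float = 1e-9,
    presmooth_hz: float | None = 1.0,
) -> tuple[list[str], list[int]]:
    """Per-frame outside-leg label and the turn-switch frames.

    The inside leg is the one whose ankle is nearer the COM (the skier
    inclines into the turn), the outside leg the other.  The left-right
    ankle distance difference is a turn-structure signal (a few tenths of
    a hertz), so it is low-passed zero-phase at ``presmooth_hz`` before
    thresholding (pass None to disable); raw labels are then cleaned with a
    centered majority filter before switch frames (first frame of each new
    label) are extracted.  Frames where the ankles are equidistant within
    ``eps`` inherit the previous frame's label.
    """
    skeleton = skeleton or seq.skeleton
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ConfigError("smoothing_window must be a positive odd number of frames")
    com = com_relative_series(seq.positions, skeleton)  # (n, 3)
    ankle_l = seq.positions[:, :, skeleton.index("ankle_l")]
    ankle_r = seq.positions[:, :, skeleton.index("ankle_r")]
    d_l = np.linalg.norm(com - ankle_l, axis=1)
    d_r = np.linalg.norm(com - ankle_r, axis=1)
    diff = d_l - d_r
    if presmooth_hz is not None and 0 < presmooth_hz < seq.rate / 2:
        from scipy.signal import butter, filtfilt

        b, a = butter(2, presmooth_hz / (seq.rate / 2))
        pad = min(3 * max(len(a), len(b)), len(diff) - 1)
        if pad > 0:
            diff = filtfilt(b, a, diff, padlen=pad)
    # inside = nearer ankle; outside = the other: COM nearer left => outside right
    outside_right = diff < 0
    tie = np.abs(diff) < eps
    labels = np.where(outside_right, "right", "left").astype(object)
    if tie[0]:
        raise DataError(
            "ankles equidistant from COM at the first frame; provide a longer "
            "sequence or an explicit seed label"
        )
    for i in np.where(tie)[0]:
        labels[i] = labels[i - 1]
    smoothed = _majority_filter(labels == "right", smoothing_window)
    out = ["right" if s else "left" for s in smoothed]
    switches = [i for i in range(1, len(out)) if out[i] != out[i - 1]]
    return out, switches


def _majority_filter(flags: np.ndarray, window: int) -> np.ndarray:
    """Centered boolean majority vote; window is odd, edges use what exists."""
    n = len(flags)
    half = window // 2
    out = np.empty(n, dtype=bool)
    x = flags.astype(int)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = x[lo:hi].sum() * 2 > (hi - lo)
    return out


def ski_frame(
    frame: PoseFrame,
    outside: str,
    skeleton: SkeletonDefinition = DEFAULT_SKELETON,
    eps: float = EPS_NORM,
) -> SkiFrame:
    """Construct the ski-relative triads for one frame.

    x' runs tail->tip along the outside ski; z' is perpendicular to both the
    ski axis and the ankle-to-ankle line, signed toward the neck; y' closes
    the right-handed triad.
    """
    side = {"left": "l", "right": "r"}[outside]
    tip = frame.point(skeleton.index(f"ski_tip_{side}"))
    tail = frame.point(skeleton.index(f"ski_tail_{side}"))
    ankle_l = frame.point(skeleton.index("ankle_l"))
    ankle_r = frame.point(skeleton.index("ankle_r"))
    neck = frame.point(skeleton.index("neck"))
    ankle_out = ankle_l if outside == "left" else ankle_r

    ski = tip - tail
    n_ski = np.linalg.norm(ski)
    if n_ski < eps:
        raise DegenerateGeometryError(
            f"outside ski has zero length at frame {frame.frame_index}"
        )
    x_axis = ski / n_ski
    a = ankle_r - ankle_l
    n_a = np.linalg.norm(a)
    if n_a < eps:
        raise DegenerateGeometryError(
            f"ankles coincide at frame {frame.frame_index}"
        )
    z = np.cross(x_axis, a / n_a)
    n_z = np.linalg.norm(z)
    if n_z < eps:
        raise DegenerateGeometryError(
            f"ski axis parallel to the ankle line at frame {frame.frame_index}"
        )
    z_axis = z / n_z
    if np.dot(z_axis, neck - ankle_out) < 0:
        z_axis = -z_axis
    y_axis = np.cross(z_axis, x_axis)
    return SkiFrame(
        origin=ankle_out,
        x_axis=x_axis,
        y_axis=y_axis,
        z_axis=z_axis,
        mid_origin=0.5 * (ankle_l + ankle_r),
        outside_side=outside,
    )


def d_vertical(sf: SkiFrame, com: np.ndarray) -> float:
    """Length of the outside-ankle -> COM vector, meters."""
    return float(np.linalg.norm(np.asarray(com, dtype=float) - sf.origin))


def fore_aft(sf: SkiFrame, com: np.ndarray, eps: float = EPS_NORM) -> float:
    """Sine of the fore/aft angle, positive toward the ski tip, in [-1, 1]."""
    v = np.asarray(com, dtype=float) - sf.origin
    vx = float(np.dot(v, sf.x_axis))
    vz = float(np.dot(v, sf.z_axis))
    norm = np.hypot(vx, vz)
    if norm < eps:
        return 0.0
    return float(np.sin(np.arctan2(vx, vz)))


def lean_angle(sf: SkiFrame, com: np.ndarray, eps: float = EPS_NORM) -> float:
    """Unsigned angle from z'' of the mid-ankle -> COM vector in the y''-z'' plane, degrees."""
    v = np.asarray(com, dtype=float) - sf.mid_origin
    vy = float(np.dot(v, sf.y_axis))
    vz = float(np.dot(v, sf.z_axis))
    if np.hypot(vy, vz) < eps:
        return 0.0
    return float(np.degrees(np.arctan2(abs(vy), vz)))


def com_velocity(
    seq: PoseSequence, skeleton: SkeletonDefinition | None = None
) -> np.ndarray:
    """Per-frame COM velocity (m/s) by central differences, one-sided at the ends."""
    if len(seq) < 2:
        raise DataError("velocity needs at least two frames")
    skeleton = skeleton or seq.skeleton
    com = com_relative_series(seq.positions, skeleton)
    vel = np.gradient(com, axis=0) * seq.rate
    return vel


def barelle_drag_area(h_cm: float, w: float) -> float:
    """Barelle posture drag model: C_D A = 0.003 h - 0.026 + 0.041 (2w), m^2."""
    return 0.003 * h_cm - 0.026 + 0.041 * (2.0 * w)


def drag_area(
    frame: PoseFrame,
    sf: SkiFrame,
    velocity: np.ndarray,
    skeleton: SkeletonDefinition = DEFAULT_SKELETON,
    arm_span_mode: str = "straight",
    eps: float = EPS_NORM,
) -> DragPosture:
    """Drag area from projected body height and arm span.

    h is the mid-ankle -> mid-shoulder vector projected on the up axis z',
    in centimeters; w is the hand-to-hand vector projected on the plane
    orthogonal to the COM velocity, divided by the total arm span
    (straight hand-to-hand distance, or the polyline through elbows and
    shoulders when ``arm_span_mode='polyline'``) and clamped to [0, 1].
    """
    vel = np.asarray(velocity, dtype=float)
    speed = np.linalg.norm(vel)
    if speed < eps:
        raise DataError(
            "COM velocity is undefined (zero speed); filter the sequence or use a longer window"
        )
    idx = skeleton.index
    sh = 0.5 * (frame.point(idx("shoulder_l")) + frame.point(idx("shoulder_r")))
    mid_ankle = sf.mid_origin
    h_cm = float(np.dot(sh - mid_ankle, sf.z_axis)) * 100.0

    span = frame.point(idx("hand_r")) - frame.point(idx("hand_l"))
    v_hat = vel / speed
    span_perp = span - np.dot(span, v_hat) * v_hat
    if arm_span_mode == "straight":
        total = np.linalg.norm(span)
    elif arm_span_mode == "polyline":
        chain = ["hand_l", "elbow_l", "shoulder_l", "shoulder_r", "elbow_r", "hand_r"]
        pts = [frame.point(idx(n)) for n in chain]
        total = float(sum(np.linalg.norm(b - a) for a, b in zip(pts, pts[1:])))
    else:
        raise ConfigError(f"arm_span_mode must be 'straight' or 'polyline', got {arm_span_mode!r}")
    if total < eps:
        raise DegenerateGeometryError(f"zero arm span at frame {frame.frame_index}")
    w = float(np.clip(np.linalg.norm(span_perp) / total, 0.0, 1.0))
    return DragPosture(h=h_cm, w=w, cda=barelle_drag_area(h_cm, w))


METRIC_UNITS = {
    "knee_outside": "deg",
    "knee_inside": "deg",
    "hip_outside": "deg",
    "hip_inside": "deg",
    "com_rel": "m",
    "d_vertical": "m",
    "fore_aft": "1",
    "fore_aft_m": "m",
    "lean_angle": "deg",
    "cda": "m^2",
}

ALL_METRICS = tuple(METRIC_UNITS)


def compute_metrics(
    seq: PoseSequence,
    config: MetricConfig = MetricConfig(),
    metrics: tuple[str, ...] | None = None,
) -> tuple[dict[str, MetricSeries], TurnCycleAnnotation]:
    """Compute the full skiing metric set for one pose sequence.

    Returns the metric series keyed by name (knee/hip flexion of the turn
    outside and inside leg, pelvis-relative COM, d_vertical, fore/aft,
    lean angle, drag area) plus the turn-cycle annotation derived from the
    detected outside-leg switches.
    """
    if not seq.all_valid():
        raise DataError("sequence contains invalid keypoints; fill gaps first")
    skeleton = seq.skeleton
    if metrics is None:
        wanted = set(ALL_METRICS)
        if config.fore_aft_output == "sine":
            wanted.discard("fore_aft_m")
        elif config.fore_aft_output == "meters":
            wanted.discard("fore_aft")
        elif config.fore_aft_output != "both":
            raise ConfigError(
                f"fore_aft_output must be 'sine', 'meters' or 'both', got {config.fore_aft_output!r}"
            )
    else:
        wanted = set(metrics)
    unknown = wanted - set(ALL_METRICS)
    if unknown:
        raise ConfigError(f"unknown metrics {sorted(unknown)}")

    labels, switches = detect_outside_leg(
        seq,
        skeleton,
        smoothing_window=config.smoothing_window,
        eps=config.eps,
        presmooth_hz=config.detection_presmooth_hz,
    )
    inside = {"left": "right", "right": "left"}
    vel = com_velocity(seq, skeleton) if "cda" in wanted else None

    n = len(seq)
    store: dict[str, list] = {m: [] for m in ALL_METRICS if m in wanted}
    mid_hip = 0.5 * (
        seq.positions[:, :, skeleton.index("hip_l")]
        + seq.positions[:, :, skeleton.index("hip_r")]
    )
    for i in range(n):
        frame = seq.frame(i)
        out_side = labels[i]
        com = com_relative(frame, skeleton)
        sf = ski_frame(frame, out_side, skeleton, eps=config.eps)
        if "knee_outside" in wanted:
            store["knee_outside"].append(
                knee_flexion(frame, out_side, skeleton, config.angle_convention)
            )
        if "knee_inside" in wanted:
            store["knee_inside"].append(
                knee_flexion(frame, inside[out_side], skeleton, config.angle_convention)
            )
        if "hip_outside" in wanted:
            store["hip_outside"].append(
                hip_flexion(frame, out_side, skeleton, config.angle_convention)
            )
        if "hip_inside" in wanted:
            store["hip_inside"].append(
                hip_flexion(frame, inside[out_side], skeleton, config.angle_convention)
            )
        if "com_rel" in wanted:
            store["com_rel"].append(com - mid_hip[i])
        if "d_vertical" in wanted:
            store["d_vertical"].append(d_vertical(sf, com))
        if "fore_aft" in wanted or "fore_aft_m" in wanted:
            s = fore_aft(sf, com, eps=config.eps)
            if "fore_aft" in wanted:
                store["fore_aft"].append(s)
            if "fore_aft_m" in wanted:
                store["fore_aft_m"].append(s * d_vertical(sf, com))
        if "lean_angle" in wanted:
            store["lean_angle"].append(lean_angle(sf, com, eps=config.eps))
        if "cda" in wanted:
            store["cda"].append(
                drag_area(frame, sf, vel[i], skeleton, config.arm_span_mode, config.eps).cda
            )

    series = {
        name: MetricSeries(name, np.asarray(vals), METRIC_UNITS[name], list(labels))
        for name, vals in store.items()
    }
    annotation = TurnCycleAnnotation(tuple(switches)) if switches else TurnCycleAnnotation(())
    return series, annotation
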