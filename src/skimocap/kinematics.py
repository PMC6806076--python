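"""Joint angles and center of mass from a pose matrix.

Knee flexion is the included angle at the knee between the thigh
(hip − knee) and shank (ankle − knee) vectors; hip flexion the angle
between the trunk vector (neck − mid-hip) and the thigh vector
(knee − hip).  Angles are reported literally as the arccos value, so a
straight leg reads 180°; set ``convention="flexion"`` for the anatomical
supplement 180° − θ.

The relative center of mass is the mass-weighted mean of the keypoints,
with per-keypoint weights from the skeleton's mass model (ski keypoints
carry zero mass).
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigError, DegenerateGeometryError, MissingDataError
from .sequence import PoseFrame
from .skeleton import DEFAULT_SKELETON, SkeletonDefinition

EPS_NORM = 1e-9  # meters; below this a direction vector is degenerate


def angle_between(v1: np.ndarray, v2: np.ndarray) -> float:
    """Included angle between two 3-vectors in degrees, in [0, 180].

    The arccos argument is clamped to [-1, 1] so exactly (anti)parallel
    vectors do not produce NaN from floating-point overshoot.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 < EPS_NORM or n2 < EPS_NORM:
        raise DegenerateGeometryError(
            f"cannot measure an angle with a zero-length vector (norms {n1:.2e}, {n2:.2e})"
        )
    cosine = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosine)))


def _apply_convention(theta: float, convention: str) -> float:
    if convention == "included":
        return theta
    if convention == "flexion":
        return 180.0 - theta
    raise ConfigError(f"angle convention must be 'included' or 'flexion', got {convention!r}")


def knee_flexion(
    frame: PoseFrame,
    side: str,
    skeleton: SkeletonDefinition = DEFAULT_SKELETON,
    convention: str = "included",
) -> float:
    """Knee angle of one leg: angle between hip−knee and ankle−knee."""
    hip = skeleton.side_index("hip", side)
    knee = skeleton.side_index("knee", side)
    ankle = skeleton.side_index("ankle", side)
    if not frame.is_valid(hip, knee, ankle):
        missing = [
            skeleton.keypoint_names[i]
            for i in (hip, knee, ankle)
            if not frame.validity[i]
        ]
        raise MissingDataError(
            f"knee flexion ({side}) needs {missing} at frame {frame.frame_index}"
        )
    theta = angle_between(
        frame.point(hip) - frame.point(knee), frame.point(ankle) - frame.point(knee)
    )
    return _apply_convention(theta, convention)


def hip_flexion(
    frame: PoseFrame,
    side: str,
    skeleton: SkeletonDefinition = DEFAULT_SKELETON,
    convention: str = "included",
) -> float:
    """Hip angle of one leg: angle between trunk (neck − mid-hip) and thigh."""
    neck = skeleton.index("neck")
    hip_l = skeleton.index("hip_l")
    hip_r = skeleton.index("hip_r")
    hip = skeleton.side_index("hip", side)
    knee = skeleton.side_index("knee", side)
    if not frame.is_valid(neck, hip_l, hip_r, knee):
        missing = [
            skeleton.keypoint_names[i]
            for i in (neck, hip_l, hip_r, knee)
            if not frame.validity[i]
        ]
        raise MissingDataError(
            f"hip flexion ({side}) needs {missing} at frame {frame.frame_index}"
        )
    mid_hip = 0.5 * (frame.point(hip_l) + frame.point(hip_r))
    theta = angle_between(frame.point(neck) - mid_hip, frame.point(knee) - frame.point(hip))
    return _apply_convention(theta, convention)


def com_relative(
    frame: PoseFrame, skeleton: SkeletonDefinition = DEFAULT_SKELETON
) -> np.ndarray:
    """Mass-weighted center of mass, (1/M) Σ m_i P_i over mass-bearing keypoints."""
    weights = skeleton.mass_array
    bearing = weights > 0
    if not frame.validity[bearing].all():
        missing = [
            skeleton.keypoint_names[i]
            for i in np.where(bearing & ~frame.validity)[0]
        ]
        raise MissingDataError(
            f"COM needs mass-bearing keypoints {missing} at frame {frame.frame_index}"
        )
    return frame.positions @ weights / weights.sum()


def com_relative_series(
    positions: np.ndarray, skeleton: SkeletonDefinition = DEFAULT_SKELETON
) -> np.ndarray:
    """Vectorized COM over an (n_frames, 3, n_keypoints) stack -> (n_frames, 3)."""
    weights = skeleton.mass_array
    return positions @ weights / weights.sum()
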