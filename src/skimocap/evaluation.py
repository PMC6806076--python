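"""Validation statistics: pose error, cycle normalization, accuracy/precision.

Pose error is the mean per-joint position error (MPJPE) between a predicted
and a reference pose, both expressed relative to the pelvis (mid-hip).
Monocular reconstruction is scale-ambiguous, so the normalized variant
(NMPJPE) first fits the least-squares optimal global scale

    s* = argmin_s sum_J || s * P_pred,J - P_ref,J ||^2
       = sum_J <P_pred,J, P_ref,J> / sum_J ||P_pred,J||^2

and reports MPJPE of the rescaled prediction.

For turn-phase analysis every per-frame series is resampled by linear
interpolation onto 200 equally spaced points of one turn cycle
(switch to switch); point-wise mean and sample SD are taken across trials.

Method-versus-reference agreement uses the validation-study convention:
per trial, the *accuracy* sample is the arithmetic mean of the per-frame
differences (monocular minus reference) and the *precision* sample their
SD; across trials each is reported as mean +/- SD.  Vector-valued series
(the relative COM) use the per-frame Euclidean distance as the difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError, DegenerateGeometryError
from .sequence import PoseFrame
from .skeleton import DEFAULT_SKELETON, SkeletonDefinition

N_NORMALIZED_POINTS = 200


# ---------------------------------------------------------------------------
# pose position error

def pelvis_center(positions: np.ndarray, skeleton: SkeletonDefinition = DEFAULT_SKELETON) -> np.ndarray:
    """Express a 3xJ pose (or a stack of them) relative to the mid-hip root."""
    pos = np.asarray(positions, dtype=float)
    mid_hip = 0.5 * (
        pos[..., :, skeleton.index("hip_l")] + pos[..., :, skeleton.index("hip_r")]
    )
    return pos - mid_hip[..., :, None]


def _subset(skeleton: SkeletonDefinition, joint_subset) -> np.ndarray:
    if joint_subset is None:
        return skeleton.body_indices
    idx = np.asarray(joint_subset, dtype=int)
    if idx.size == 0:
        raise ConfigError("joint subset must not be empty")
    return idx


def mpjpe(
    pred: PoseFrame | np.ndarray,
    ref: PoseFrame | np.ndarray,
    joint_subset=None,
    skeleton: SkeletonDefinition = DEFAULT_SKELETON,
) -> float:
    """Mean per-joint position error (m) over the joint subset, pelvis-relative.

    Defaults to the 14 body joints (ski keypoints excluded).
    """
    p = pred.positions if isinstance(pred, PoseFrame) else np.asarray(pred, dtype=float)
    r = ref.positions if isinstance(ref, PoseFrame) else np.asarray(ref, dtype=float)
    idx = _subset(skeleton, joint_subset)
    pc = pelvis_center(p, skeleton)[:, idx]
    rc = pelvis_center(r, skeleton)[:, idx]
    return float(np.linalg.norm(pc - rc, axis=0).mean())


def fit_scale(
    pred: np.ndarray, ref: np.ndarray, eps: float = 1e-12
) -> float:
    """Least-squares optimal global scale of pred onto ref (both 3xN, centered)."""
    denom = float(np.sum(pred * pred))
    if denom < eps:
        raise DegenerateGeometryError("prediction is all-zero; scale fit undefined")
    return float(np.sum(pred * ref) / denom)


def nmpjpe(
    pred: PoseFrame | np.ndarray,
    ref: PoseFrame | np.ndarray,
    joint_subset=None,
    skeleton: SkeletonDefinition = DEFAULT_SKELETON,
) -> tuple[float, float]:
    """Scale-normalized MPJPE (m) and the fitted scale factor."""
    p = pred.positions if isinstance(pred, PoseFrame) else np.asarray(pred, dtype=float)
    r = ref.positions if isinstance(ref, PoseFrame) else np.asarray(ref, dtype=float)
    idx = _subset(skeleton, joint_subset)
    pc = pelvis_center(p, skeleton)[:, idx]
    rc = pelvis_center(r, skeleton)[:, idx]
    s = fit_scale(pc, rc)
    return float(np.linalg.norm(s * pc - rc, axis=0).mean()), s


@dataclass
class ErrorReport:
    """Per-frame MPJPE/NMPJPE of one trial stream plus summary statistics."""

    per_frame_mpjpe: np.ndarray
    per_frame_nmpjpe: np.ndarray
    scale_factors: np.ndarray
    subject_id: str = ""
    trial_id: str = ""
    camera_id: str = ""

    @property
    def mean_nmpjpe(self) -> float:
        return float(self.per_frame_nmpjpe.mean())

    @property
    def sd_nmpjpe(self) -> float:
        return float(self.per_frame_nmpjpe.std(ddof=1)) if len(self.per_frame_nmpjpe) > 1 else 0.0

    @property
    def mean_mpjpe(self) -> float:
        return float(self.per_frame_mpjpe.mean())


def sequence_error(
    pred_seq,
    ref_seq,
    joint_subset=None,
    scale_fit: str = "per_frame",
) -> ErrorReport:
    """MPJPE/NMPJPE per frame for a paired prediction/reference sequence.

    ``scale_fit='per_sequence'`` fits one scale to the whole (pelvis-
    centered) trial instead of one per frame.
    """
    if len(pred_seq) != len(ref_seq):
        raise DataError("prediction and reference sequences differ in length")
    skeleton = ref_seq.skeleton
    idx = _subset(skeleton, joint_subset)
    pc = pelvis_center(pred_seq.positions, skeleton)[:, :, idx]
    rc = pelvis_center(ref_seq.positions, skeleton)[:, :, idx]
    per_mpjpe = np.linalg.norm(pc - rc, axis=1).mean(axis=1)
    if scale_fit == "per_frame":
        denom = np.sum(pc * pc, axis=(1, 2))
        if np.any(denom < 1e-12):
            raise DegenerateGeometryError("all-zero predicted pose; scale fit undefined")
        scales = np.sum(pc * rc, axis=(1, 2)) / denom
    elif scale_fit == "per_sequence":
        scales = np.full(len(pred_seq), fit_scale(pc, rc))
    else:
        raise ConfigError("scale_fit must be 'per_frame' or 'per_sequence'")
    per_nmpjpe = np.linalg.norm(scales[:, None, None] * pc - rc, axis=1).mean(axis=1)
    return ErrorReport(
        per_frame_mpjpe=per_mpjpe,
        per_frame_nmpjpe=per_nmpjpe,
        scale_factors=scales,
        subject_id=pred_seq.subject_id,
        trial_id=pred_seq.trial_id,
        camera_id=pred_seq.camera_id,
    )


# ---------------------------------------------------------------------------
# turn-cycle time normalization

@dataclass
class NormalizedCurve:
    """A series resampled to 200 equally spaced points over one turn cycle."""

    mean: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        if len(self.mean) != N_NORMALIZED_POINTS:
            raise DataError(
                f"normalized curves have exactly {N_NORMALIZED_POINTS} points, got {len(self.mean)}"
            )
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.mean.shape:
                raise DataError("mean and sd lengths differ")


def time_normalize(values: np.ndarray, cycle: tuple[int, int]) -> NormalizedCurve:
    """Resample one turn cycle [start, stop) onto 200 points by linear interpolation.

    The first and last of the 200 points coincide with the two switch
    instants (``start`` and ``stop - 1``).
    """
    values = np.asarray(values, dtype=float)
    start, stop = int(cycle[0]), int(cycle[1])
    if not (0 <= start < stop <= len(values)):
        raise DataError(f"cycle [{start},{stop}) outside series of length {len(values)}")
    seg = values[start:stop]
    if len(seg) < 2:
        raise DataError("a turn cycle must span at least two frames")
    t_src = np.linspace(0.0, 1.0, len(seg))
    t_dst = np.linspace(0.0, 1.0, N_NORMALIZED_POINTS)
    if seg.ndim != 1:
        raise ConfigError("time_normalize expects a scalar series; reduce vectors first")
    return NormalizedCurve(mean=np.interp(t_dst, t_src, seg))


def curve_stats(curves: list[NormalizedCurve | np.ndarray]) -> NormalizedCurve:
    """Point-wise mean and sample SD (ddof=1) across trials."""
    if len(curves) < 2:
        raise DataError("need at least two curves for across-trial statistics")
    stack = np.vstack(
        [c.mean if isinstance(c, NormalizedCurve) else np.asarray(c, dtype=float) for c in curves]
    )
    return NormalizedCurve(mean=stack.mean(axis=0), sd=stack.std(axis=0, ddof=1))


# ---------------------------------------------------------------------------
# accuracy / precision protocol

@dataclass
class AccuracyPrecision:
    """Trial-wise mean/SD errors and their across-trial aggregation.

    ``accuracy = accuracy_mean +/- accuracy_sd`` (mean and SD across trials
    of the per-trial mean differences); ``precision = precision_mean +/-
    precision_sd`` (same for the per-trial SDs).  With a single trial the
    across-trial SDs are undefined and reported as None.
    """

    per_trial_mean: np.ndarray
    per_trial_sd: np.ndarray
    accuracy_mean: float
    accuracy_sd: float | None
    precision_mean: float
    precision_sd: float | None

    def as_dict(self) -> dict:
        return {
            "accuracy_mean": self.accuracy_mean,
            "accuracy_sd": self.accuracy_sd,
            "precision_mean": self.precision_mean,
            "precision_sd": self.precision_sd,
            "per_trial_mean": list(map(float, self.per_trial_mean)),
            "per_trial_sd": list(map(float, self.per_trial_sd)),
        }


def _difference_series(diff: np.ndarray) -> np.ndarray:
    """Scalar per-frame differences; vector differences become Euclidean distances."""
    d = np.asarray(diff, dtype=float)
    if d.ndim == 2:
        return np.linalg.norm(d, axis=1)
    if d.ndim != 1:
        raise DataError(f"difference series must be 1-D or (n,3), got shape {d.shape}")
    return d


def accuracy_precision(trial_differences: list[np.ndarray]) -> AccuracyPrecision:
    """Aggregate per-trial difference series into accuracy and precision.

    Each element is the per-frame (monocular - reference) difference of one
    trial; vector-valued differences are reduced to per-frame Euclidean
    distances first.
    """
    if not trial_differences:
        raise DataError("no trials provided")
    means, sds = [], []
    for diff in trial_differences:
        d = _difference_series(diff)
        if d.size == 0:
            raise DataError("empty difference series")
        means.append(float(d.mean()))
        sds.append(float(d.std(ddof=1)) if d.size > 1 else 0.0)
    per_trial_mean = np.asarray(means)
    per_trial_sd = np.asarray(sds)
    single = len(trial_differences) < 2
    return AccuracyPrecision(
        per_trial_mean=per_trial_mean,
        per_trial_sd=per_trial_sd,
        accuracy_mean=float(per_trial_mean.mean()),
        accuracy_sd=None if single else float(per_trial_mean.std(ddof=1)),
        precision_mean=float(per_trial_sd.mean()),
        precision_sd=None if single else float(per_trial_sd.std(ddof=1)),
    )


def accuracy_precision_multicam(
    per_camera_trial_differences: dict[str, list[np.ndarray]],
) -> AccuracyPrecision:
    """Accuracy/precision with per-trial statistics averaged across cameras first.

    Mirrors reporting 'averages over the cameras': for each trial the
    per-trial mean and SD are averaged over the camera list before the
    across-trial aggregation.
    """
    cams = sorted(per_camera_trial_differences)
    if not cams:
        raise DataError("no cameras provided")
    n_trials = {len(v) for v in per_camera_trial_differences.values()}
    if len(n_trials) != 1:
        raise DataError("all cameras must cover the same trials")
    per_cam = {c: accuracy_precision(per_camera_trial_differences[c]) for c in cams}
    per_trial_mean = np.mean([per_cam[c].per_trial_mean for c in cams], axis=0)
    per_trial_sd = np.mean([per_cam[c].per_trial_sd for c in cams], axis=0)
    single = per_trial_mean.size < 2
    return AccuracyPrecision(
        per_trial_mean=per_trial_mean,
        per_trial_sd=per_trial_sd,
        accuracy_mean=float(per_trial_mean.mean()),
        accuracy_sd=None if single else float(per_trial_mean.std(ddof=1)),
        precision_mean=float(per_trial_sd.mean()),
        precision_sd=None if single else float(per_trial_sd.std(ddof=1)),
    )
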