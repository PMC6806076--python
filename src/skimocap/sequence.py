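"""Pose containers: single frames, timed sequences, turn-cycle annotations.

Coordinates are meters in a right-handed frame with z up in world data.
A pose is the 3 x 18 matrix ``P`` whose column ``J`` is keypoint ``J``;
sequences store the stack as an ``(n_frames, 3, 18)`` array plus a
per-frame, per-keypoint validity mask for missing reconstructions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, DataError
from .skeleton import DEFAULT_SKELETON, SkeletonDefinition


@dataclass(frozen=True)
class PoseFrame:
    """One 3x18 pose matrix with a validity mask.

    ``positions[:, J]`` is the 3D position of keypoint J in meters.
    """

    positions: np.ndarray
    frame_index: int = 0
    time: float = 0.0
    validity: np.ndarray | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[0] != 3:
            raise DataError(f"pose matrix must be 3 x n_keypoints, got {pos.shape}")
        object.__setattr__(self, "positions", pos)
        if self.validity is None:
            object.__setattr__(self, "validity", np.isfinite(pos).all(axis=0))
        else:
            v = np.asarray(self.validity, dtype=bool)
            if v.shape != (pos.shape[1],):
                raise DataError("validity mask must have one entry per keypoint")
            object.__setattr__(self, "validity", v)

    @property
    def n_keypoints(self) -> int:
        return self.positions.shape[1]

    def point(self, index: int) -> np.ndarray:
        return self.positions[:, index]

    def is_valid(self, *indices: int) -> bool:
        return bool(self.validity[list(indices)].all())


@dataclass
class PoseSequence:
    """Time-stamped stack of pose matrices from one trial/camera stream."""

    positions: np.ndarray  # (n_frames, 3, n_keypoints)
    rate: float = 50.0
    validity: np.ndarray | None = None  # (n_frames, n_keypoints)
    frame_indices: np.ndarray | None = None
    subject_id: str = ""
    trial_id: str = ""
    camera_id: str = ""
    reference_flag: bool = True
    skeleton: SkeletonDefinition = field(default_factory=lambda: DEFAULT_SKELETON)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[1] != 3:
            raise DataError(
                f"positions must be (n_frames, 3, n_keypoints), got {self.positions.shape}"
            )
        if self.rate <= 0:
            raise ConfigError("rate must be positive")
        n, _, k = self.positions.shape
        if self.validity is None:
            self.validity = np.isfinite(self.positions).all(axis=1)
        else:
            self.validity = np.asarray(self.validity, dtype=bool)
            if self.validity.shape != (n, k):
                raise DataError("validity must be (n_frames, n_keypoints)")
        if self.frame_indices is None:
            self.frame_indices = np.arange(n)
        else:
            self.frame_indices = np.asarray(self.frame_indices, dtype=int)
            if np.any(np.diff(self.frame_indices) <= 0):
                raise DataError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def n_keypoints(self) -> int:
        return self.positions.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.frame_indices / self.rate

    def frame(self, i: int) -> PoseFrame:
        return PoseFrame(
            positions=self.positions[i],
            frame_index=int(self.frame_indices[i]),
            time=float(self.frame_indices[i] / self.rate),
            validity=self.validity[i],
        )

    def frames(self):
        for i in range(len(self)):
            yield self.frame(i)

    def copy(self) -> "PoseSequence":
        return replace(
            self,
            positions=self.positions.copy(),
            validity=self.validity.copy(),
            frame_indices=self.frame_indices.copy(),
        )

    def all_valid(self) -> bool:
        return bool(self.validity.all())


@dataclass(frozen=True)
class TurnCycleAnnotation:
    """Turn-switch frame indices; cycle k is the half-open [switch_k, switch_{k+1})."""

    switch_frames: tuple[int, ...]

    def __post_init__(self) -> None:
        sf = tuple(int(s) for s in self.switch_frames)
        if any(b <= a for a, b in zip(sf, sf[1:])):
            raise DataError("switch frames must be strictly increasing")
        object.__setattr__(self, "switch_frames", sf)

    @property
    def n_cycles(self) -> int:
        return max(len(self.switch_frames) - 1, 0)

    def cycles(self) -> list[tuple[int, int]]:
        return list(zip(self.switch_frames, self.switch_frames[1:]))

    def validate_against(self, seq: PoseSequence) -> None:
        if self.switch_frames and (
            self.switch_frames[0] < 0 or self.switch_frames[-1] > len(seq)
        ):
            raise DataError("switch frames outside sequence bounds")
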