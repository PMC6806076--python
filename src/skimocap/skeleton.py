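"""The 18-keypoint skier skeleton and its mass model.

The skeleton covers the major human joint centers plus the four ski
extremities (tails and tips), which carry no body mass but anchor the
ski-relative coordinate frames.  Per-keypoint mass fractions are derived
from Clauser's cadaver segment-mass table by splitting each segment
fraction equally between its two bounding keypoints; terminal segments
(hand, foot) are assigned wholly to their keypoint and the trunk is split
half to the neck and a quarter to each hip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError

KEYPOINT_NAMES: tuple[str, ...] = (
    "head",
    "neck",
    "shoulder_l",
    "shoulder_r",
    "elbow_l",
    "elbow_r",
    "hand_l",
    "hand_r",
    "hip_l",
    "hip_r",
    "knee_l",
    "knee_r",
    "ankle_l",
    "ankle_r",
    "ski_tail_l",
    "ski_tail_r",
    "ski_tip_l",
    "ski_tip_r",
)

N_KEYPOINTS = 18

# (parent, child) connectivity of the segment model
SEGMENTS: tuple[tuple[str, str], ...] = (
    ("head", "neck"),
    ("neck", "shoulder_l"),
    ("neck", "shoulder_r"),
    ("shoulder_l", "elbow_l"),
    ("shoulder_r", "elbow_r"),
    ("elbow_l", "hand_l"),
    ("elbow_r", "hand_r"),
    ("neck", "hip_l"),
    ("neck", "hip_r"),
    ("hip_l", "hip_r"),
    ("hip_l", "knee_l"),
    ("hip_r", "knee_r"),
    ("knee_l", "ankle_l"),
    ("knee_r", "ankle_r"),
    ("ankle_l", "ski_tail_l"),
    ("ankle_l", "ski_tip_l"),
    ("ankle_r", "ski_tail_r"),
    ("ankle_r", "ski_tip_r"),
)

# Clauser whole-body segment mass fractions (sum to 1.0):
#   head+neck 0.073, trunk 0.507, upper arm 0.026, forearm 0.016,
#   hand 0.007, thigh 0.103, shank 0.043, foot 0.015
# mapped to keypoints as documented in the module docstring.
_CLAUSER_KEYPOINT_WEIGHTS: dict[str, float] = {
    "head": 0.073 / 2,
    "neck": 0.073 / 2 + 0.507 / 2,
    "shoulder_l": 0.026 / 2,
    "shoulder_r": 0.026 / 2,
    "elbow_l": 0.026 / 2 + 0.016 / 2,
    "elbow_r": 0.026 / 2 + 0.016 / 2,
    "hand_l": 0.016 / 2 + 0.007,
    "hand_r": 0.016 / 2 + 0.007,
    "hip_l": 0.507 / 4 + 0.103 / 2,
    "hip_r": 0.507 / 4 + 0.103 / 2,
    "knee_l": 0.103 / 2 + 0.043 / 2,
    "knee_r": 0.103 / 2 + 0.043 / 2,
    "ankle_l": 0.043 / 2 + 0.015,
    "ankle_r": 0.043 / 2 + 0.015,
    "ski_tail_l": 0.0,
    "ski_tail_r": 0.0,
    "ski_tip_l": 0.0,
    "ski_tip_r": 0.0,
}


@dataclass(frozen=True)
class SkeletonDefinition:
    """Named keypoints, connectivity and per-keypoint mass fractions.

    Parameters
    ----------
    keypoint_names
        Ordered keypoint identifiers; the column order of every pose matrix.
    segments
        (parent, child) index pairs into ``keypoint_names``.
    mass_weights
        Per-keypoint mass fraction ``m_i``; normalized so the total body
        mass ``M = sum(m_i)`` is 1. Ski keypoints carry weight 0.
    """

    keypoint_names: tuple[str, ...] = KEYPOINT_NAMES
    segments: tuple[tuple[int, int], ...] = field(
        default_factory=lambda: tuple(
            (KEYPOINT_NAMES.index(a), KEYPOINT_NAMES.index(b)) for a, b in SEGMENTS
        )
    )
    mass_weights: tuple[float, ...] = field(
        default_factory=lambda: tuple(
            _CLAUSER_KEYPOINT_WEIGHTS[name] for name in KEYPOINT_NAMES
        )
    )
    name: str = "ski18"

    def __post_init__(self) -> None:
        if len(self.keypoint_names) != N_KEYPOINTS:
            raise ConfigError(
                f"skeleton must have {N_KEYPOINTS} keypoints, got {len(self.keypoint_names)}"
            )
        if len(self.mass_weights) != len(self.keypoint_names):
            raise ConfigError("one mass weight per keypoint required")
        if any(w < 0 for w in self.mass_weights):
            raise ConfigError("mass weights must be non-negative")
        n = len(self.keypoint_names)
        for a, b in self.segments:
            if not (0 <= a < n and 0 <= b < n):
                raise ConfigError(f"segment ({a},{b}) out of range")
        total = float(sum(self.mass_weights))
        if abs(total - 1.0) > 1e-9:
            # normalize in place (frozen dataclass -> object.__setattr__)
            object.__setattr__(
                self, "mass_weights", tuple(w / total for w in self.mass_weights)
            )

    def index(self, name: str) -> int:
        """Column index of a keypoint name."""
        try:
            return self.keypoint_names.index(name)
        except ValueError:
            raise KeyError(f"unknown keypoint {name!r}") from None

    @property
    def total_mass(self) -> float:
        return float(sum(self.mass_weights))

    @property
    def mass_array(self) -> np.ndarray:
        return np.asarray(self.mass_weights, dtype=float)

    @property
    def body_indices(self) -> np.ndarray:
        """Indices of the 14 body joints (ski keypoints excluded)."""
        return np.array(
            [i for i, n in enumerate(self.keypoint_names) if not n.startswith("ski_")]
        )

    def side_index(self, joint: str, side: str) -> int:
        """Index of e.g. ('knee', 'left') -> knee_l."""
        side = {"left": "l", "right": "r", "l": "l", "r": "r"}.get(side.lower())
        if side is None:
            raise ConfigError("side must be 'left' or 'right'")
        return self.index(f"{joint}_{side}")


DEFAULT_SKELETON = SkeletonDefinition()
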