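"""Gap filling and low-pass filtering of marker/keypoint trajectories.

Multi-camera reconstructions drop keypoints when no camera pair sees them;
short gaps are bridged by per-coordinate linear interpolation before the
trajectories are smoothed with a zero-phase second-order Butterworth
low-pass (applied forward and backward, so effectively fourth order with
no lag).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import ConfigError, DataError
from .sequence import PoseSequence

log = logging.getLogger(__name__)

DEFAULT_MAX_GAP = 5  # frames = 0.1 s at 50 Hz
DEFAULT_CUTOFF_HZ = 6.0


def _gap_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, stop) runs of consecutive invalid frames."""
    runs = []
    n = len(valid)
    i = 0
    while i < n:
        if not valid[i]:
            j = i
            while j < n and not valid[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def fill_gaps(
    seq: PoseSequence, max_gap: int = DEFAULT_MAX_GAP
) -> tuple[PoseSequence, list[dict]]:
    """Linearly interpolate gaps of at most ``max_gap`` frames per keypoint.

    Gaps longer than ``max_gap``, or touching the sequence boundary, are
    left invalid.  Returns the filled sequence and a report of every gap
    seen: ``{"keypoint", "start", "stop", "filled"}``.
    """
    if max_gap < 1:
        raise ConfigError("max_gap must be >= 1 frame")
    out = seq.copy()
    report: list[dict] = []
    n = len(seq)
    for j, name in enumerate(seq.skeleton.keypoint_names):
        for start, stop in _gap_runs(seq.validity[:, j]):
            boundary = start == 0 or stop == n
            fill = (stop - start) <= max_gap and not boundary
            if fill:
                t0, t1 = start - 1, stop  # valid anchors
                for t in range(start, stop):
                    w = (t - t0) / (t1 - t0)
                    out.positions[t, :, j] = (1 - w) * seq.positions[t0, :, j] + w * seq.positions[t1, :, j]
                out.validity[start:stop, j] = True
            else:
                log.warning(
                    "gap at %s frames [%d,%d) left unfilled (%s)",
                    name,
                    start,
                    stop,
                    "boundary" if boundary else f"longer than max_gap={max_gap}",
                )
            report.append(
                {"keypoint": name, "start": start, "stop": stop, "filled": fill}
            )
    return out, report


def lowpass_filter(seq: PoseSequence, cutoff: float = DEFAULT_CUTOFF_HZ) -> PoseSequence:
    """Zero-phase second-order Butterworth low-pass on every coordinate."""
    nyquist = seq.rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ConfigError(f"cutoff must lie in (0, {nyquist}) Hz, got {cutoff}")
    if not seq.all_valid():
        raise DataError("sequence contains invalid keypoints; fill gaps first")
    b, a = butter(2, cutoff / nyquist)
    out = seq.copy()
    # filtfilt along the frame axis for all 3*18 coordinates at once
    flat = seq.positions.reshape(len(seq), -1)
    out.positions = filtfilt(b, a, flat, axis=0).reshape(seq.positions.shape)
    return out
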