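"""Reading and writing the pose CSV dialect and the report files.

Canonical pose file pair:

* ``<name>.csv`` — header ``frame,time_s,keypoint,x_m,y_m,z_m``, one row per
  (frame, keypoint), UTF-8, '.' decimal separator.  A missing row marks the
  keypoint invalid in that frame.
* ``<name>.json`` — metadata: subject_id, trial_id, camera_id, rate_hz,
  reference_flag, skeleton.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .sequence import PoseSequence
from .skeleton import DEFAULT_SKELETON, SkeletonDefinition

POSE_COLUMNS = ["frame", "time_s", "keypoint", "x_m", "y_m", "z_m"]


def load_pose_sequence(
    csv_path: str | Path,
    meta_path: str | Path | None = None,
    skeleton: SkeletonDefinition = DEFAULT_SKELETON,
) -> PoseSequence:
    """Load a pose sequence from the canonical CSV + JSON metadata pair.

    Missing (frame, keypoint) rows become invalid keypoints; duplicate rows
    and unknown keypoint names raise :class:`SchemaError`.
    """
    csv_path = Path(csv_path)
    if meta_path is None:
        meta_path = csv_path.with_suffix(".json")
    try:
        # round_trip parsing keeps write->load bit-exact on coordinates
        table = pd.read_csv(csv_path, float_precision="round_trip")
    except Exception as exc:  # pandas raises many flavors on malformed input
        raise SchemaError(f"cannot parse {csv_path}: {exc}") from exc
    missing_cols = set(POSE_COLUMNS) - set(table.columns)
    if missing_cols:
        raise SchemaError(f"{csv_path}: missing columns {sorted(missing_cols)}")
    bad = ~table["keypoint"].isin(skeleton.keypoint_names)
    if bad.any():
        line = int(table.index[bad][0]) + 2  # header + 1-based
        raise SchemaError(
            f"{csv_path}:{line}: unknown keypoint {table['keypoint'][bad].iloc[0]!r}"
        )
    coords = table[["x_m", "y_m", "z_m"]].to_numpy()
    if not np.isfinite(coords).all():
        line = int(np.where(~np.isfinite(coords).all(axis=1))[0][0]) + 2
        raise SchemaError(f"{csv_path}:{line}: non-finite coordinate")
    if table.duplicated(subset=["frame", "keypoint"]).any():
        dup = table[table.duplicated(subset=["frame", "keypoint"])].iloc[0]
        raise SchemaError(
            f"{csv_path}: duplicate row for frame {dup['frame']}, keypoint {dup['keypoint']}"
        )

    meta = json.loads(Path(meta_path).read_text(encoding="utf-8"))
    rate = float(meta.get("rate_hz", 50.0))

    frames = np.sort(table["frame"].unique()).astype(int)
    frame_pos = {f: i for i, f in enumerate(frames)}
    kp_pos = {n: i for i, n in enumerate(skeleton.keypoint_names)}

    n, k = len(frames), len(skeleton.keypoint_names)
    positions = np.full((n, 3, k), np.nan)
    validity = np.zeros((n, k), dtype=bool)
    rows_f = table["frame"].to_numpy(dtype=int)
    rows_k = table["keypoint"].map(kp_pos).to_numpy(dtype=int)
    fi = np.fromiter((frame_pos[f] for f in rows_f), dtype=int, count=len(rows_f))
    positions[fi, :, rows_k] = coords
    validity[fi, rows_k] = True

    return PoseSequence(
        positions=positions,
        rate=rate,
        validity=validity,
        frame_indices=frames,
        subject_id=str(meta.get("subject_id", "")),
        trial_id=str(meta.get("trial_id", "")),
        camera_id=str(meta.get("camera_id", "")),
        reference_flag=bool(meta.get("reference_flag", True)),
        skeleton=skeleton,
    )


def save_pose_sequence(
    seq: PoseSequence, csv_path: str | Path, meta_path: str | Path | None = None
) -> None:
    """Write a sequence as the canonical CSV + JSON pair (invalid keypoints omitted)."""
    csv_path = Path(csv_path)
    if meta_path is None:
        meta_path = csv_path.with_suffix(".json")
    records = []
    names = seq.skeleton.keypoint_names
    for i in range(len(seq)):
        f = int(seq.frame_indices[i])
        t = f / seq.rate
        for j, name in enumerate(names):
            if seq.validity[i, j]:
                x, y, z = seq.positions[i, :, j]
                records.append((f, t, name, repr(float(x)), repr(float(y)), repr(float(z))))
    table = pd.DataFrame.from_records(records, columns=POSE_COLUMNS)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(csv_path, index=False)
    meta = {
        "subject_id": seq.subject_id,
        "trial_id": seq.trial_id,
        "camera_id": seq.camera_id,
        "rate_hz": seq.rate,
        "reference_flag": seq.reference_flag,
        "skeleton": seq.skeleton.name,
    }
    Path(meta_path).write_text(json.dumps(meta, indent=1), encoding="utf-8")


def write_metric_csv(path: str | Path, series_by_name: dict, rate: float) -> None:
    """Write per-frame metric values as ``frame,time_s,metric,value,units,side``."""
    rows = []
    for name, series in series_by_name.items():
        vals = np.asarray(series.values, dtype=float)
        sides = getattr(series, "side_labels", None)
        for i in range(vals.shape[0]):
            v = vals[i]
            value = float(np.linalg.norm(v)) if v.ndim else float(v)
            rows.append(
                (
                    i,
                    i / rate,
                    name,
                    value,
                    series.units,
                    sides[i] if sides is not None else "",
                )
            )
    pd.DataFrame(rows, columns=["frame", "time_s", "metric", "value", "units", "side"]).to_csv(
        Path(path), index=False
    )


def write_curve_csv(path: str | Path, curve) -> None:
    """Write a 200-point normalized curve as ``t_norm,mean,sd``."""
    t = np.linspace(0.0, 1.0, len(curve.mean))
    sd = curve.sd if curve.sd is not None else np.full(len(curve.mean), np.nan)
    pd.DataFrame({"t_norm": t, "mean": curve.mean, "sd": sd}).to_csv(Path(path), index=False)
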