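"""End-to-end trial evaluation: metrics, pose error, accuracy/precision.

One *trial* is a paired (reference, monocular) stream of the same run.
Following the validation protocol, each trial is evaluated over one turn
cycle (switch to switch, detected on the reference stream); per-frame
differences (monocular minus reference) of every metric feed the
accuracy/precision aggregation, and per-frame NMPJPE is time-normalized to
200 points for across-trial turn-phase curves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .evaluation import (
    NormalizedCurve,
    accuracy_precision,
    curve_stats,
    sequence_error,
    time_normalize,
)
from .io import load_pose_sequence, write_curve_csv
from .sequence import PoseSequence
from .ski import MetricConfig, compute_metrics

SCALAR_METRICS = (
    "knee_outside",
    "knee_inside",
    "hip_outside",
    "hip_inside",
    "lean_angle",
    "d_vertical",
    "fore_aft",
    "cda",
)
VECTOR_METRICS = ("com_rel",)


@dataclass
class TrialResult:
    """Evaluation of one paired trial over one turn cycle."""

    subject: str
    trial: str
    nmpjpe_mean: float
    nmpjpe_sd: float
    mpjpe_mean: float
    differences: dict[str, np.ndarray]  # per-frame mono - ref, per metric
    nmpjpe_curve: NormalizedCurve
    cycle: tuple[int, int]


@dataclass
class EvaluationSummary:
    """Across-trial summary in the layout of a validation-study report."""

    nmpjpe_mean: float
    nmpjpe_sd: float
    per_metric: dict[str, dict]
    nmpjpe_curve: NormalizedCurve
    n_trials: int
    per_subject_nmpjpe: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "nmpjpe_mean_m": self.nmpjpe_mean,
            "nmpjpe_sd_m": self.nmpjpe_sd,
            "n_trials": self.n_trials,
            "per_subject_nmpjpe_m": self.per_subject_nmpjpe,
            "metrics": self.per_metric,
        }
        return json.dumps(payload, indent=1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, stats in self.per_metric.items():
            rows.append(
                {
                    "metric": name,
                    "accuracy_mean": stats["accuracy_mean"],
                    "accuracy_sd": stats["accuracy_sd"],
                    "precision_mean": stats["precision_mean"],
                    "precision_sd": stats["precision_sd"],
                }
            )
        return pd.DataFrame(rows)


def evaluate_trial(
    ref: PoseSequence,
    mono: PoseSequence,
    config: MetricConfig = MetricConfig(),
    cycle: tuple[int, int] | None = None,
    metrics: tuple[str, ...] | None = None,
) -> TrialResult:
    """Evaluate one paired trial.

    The turn cycle defaults to the first full cycle of the reference
    stream's detected switches; pass ``cycle=(start, stop)`` to override
    (e.g. ground-truth switches), or ``cycle=(0, len(ref))`` for all frames.
    """
    if len(ref) != len(mono):
        raise DataError("reference and monocular streams differ in length")
    ref_metrics, ref_cycles = compute_metrics(ref, config, metrics)
    mono_metrics, _ = compute_metrics(mono, config, metrics)

    if cycle is None:
        if ref_cycles.n_cycles < 1:
            raise DataError(
                "no full turn cycle detected in the reference stream; pass cycle explicitly"
            )
        cycle = ref_cycles.cycles()[0]
    start, stop = int(cycle[0]), int(cycle[1])

    report = sequence_error(mono, ref)
    sl = slice(start, stop)
    diffs = {}
    for name in ref_metrics:
        d = mono_metrics[name].values - ref_metrics[name].values
        diffs[name] = d[sl]
    nm = report.per_frame_nmpjpe[sl]
    return TrialResult(
        subject=ref.subject_id,
        trial=ref.trial_id,
        nmpjpe_mean=float(nm.mean()),
        nmpjpe_sd=float(nm.std(ddof=1)) if len(nm) > 1 else 0.0,
        mpjpe_mean=float(report.per_frame_mpjpe[sl].mean()),
        differences=diffs,
        nmpjpe_curve=time_normalize(report.per_frame_nmpjpe, (start, stop)),
        cycle=(start, stop),
    )


def summarize(results: list[TrialResult]) -> EvaluationSummary:
    """Aggregate trial results into accuracy/precision per metric and NMPJPE stats."""
    if not results:
        raise DataError("no trial results to summarize")
    nmpjpe_means = np.array([r.nmpjpe_mean for r in results])
    per_metric = {}
    for name in results[0].differences:
        ap = accuracy_precision([r.differences[name] for r in results])
        per_metric[name] = ap.as_dict()
    by_subject: dict[str, list[float]] = {}
    for r in results:
        by_subject.setdefault(r.subject, []).append(r.nmpjpe_mean)
    if len(results) > 1:
        curve = curve_stats([r.nmpjpe_curve for r in results])
    else:
        curve = results[0].nmpjpe_curve
    return EvaluationSummary(
        nmpjpe_mean=float(nmpjpe_means.mean()),
        nmpjpe_sd=float(nmpjpe_means.std(ddof=1)) if len(results) > 1 else 0.0,
        per_metric=per_metric,
        nmpjpe_curve=curve,
        n_trials=len(results),
        per_subject_nmpjpe={s: float(np.mean(v)) for s, v in by_subject.items()},
    )


def evaluate_fixture_dir(
    fixture_dir: str | Path,
    config: MetricConfig = MetricConfig(),
    use_truth_cycles: bool = False,
) -> tuple[EvaluationSummary, list[TrialResult]]:
    """Evaluate every paired trial listed in a fixture manifest."""
    fixture_dir = Path(fixture_dir)
    manifest_path = fixture_dir / "manifest.json"
    if not manifest_path.exists():
        raise DataError(f"no manifest.json in {fixture_dir}")
    manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    results = []
    for entry in manifest["trials"]:
        ref = load_pose_sequence(fixture_dir / entry["reference"])
        mono = load_pose_sequence(fixture_dir / entry["monocular"])
        cycle = None
        if use_truth_cycles:
            sw = entry.get("switch_frames", [])
            if len(sw) >= 2:
                cycle = (sw[0], sw[1])
        results.append(evaluate_trial(ref, mono, config, cycle=cycle))
    return summarize(results), results


def write_summary(summary: EvaluationSummary, out_dir: str | Path) -> None:
    """Write the summary as CSV + JSON plus the 200-point NMPJPE curve."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary.to_frame().to_csv(out_dir / "accuracy_precision.csv", index=False)
    (out_dir / "summary.json").write_text(summary.to_json(), encoding="utf-8")
    write_curve_csv(out_dir / "nmpjpe_curve.csv", summary.nmpjpe_curve)
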