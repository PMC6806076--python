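import math

import numpy as np
import pytest

from skimocap import (
    DataError,
    NormalizedCurve,
    accuracy_precision,
    accuracy_precision_multicam,
    curve_stats,
    mpjpe,
    nmpjpe,
    pelvis_center,
    time_normalize,
)
from conftest import random_pose


def oracle_mpjpe(pred, ref, indices):
    """Plain-loop mean of per-joint Euclidean distances, pelvis-relative."""
    def center(p):
        mid = [(p[c][8] + p[c][9]) / 2.0 for c in range(3)]
        return [[p[c][j] - mid[c] for j in range(18)] for c in range(3)]

    pc, rc = center(pred.tolist()), center(ref.tolist())
    total = 0.0
    for j in indices:
        total += math.sqrt(sum((pc[c][j] - rc[c][j]) ** 2 for c in range(3)))
    return total / len(indices)


def golden_section_scale(pred_c, ref_c, lo=-100.0, hi=100.0, tol=1e-6):
    """Brute-force 1-D minimization of the scale-fit objective: golden-section
    bracketing followed by one parabolic-vertex step (exact for a quadratic)."""
    phi = (math.sqrt(5) - 1) / 2

    def objective(s):
        return float(np.sum((s * pred_c - ref_c) ** 2))

    a, b = lo, hi
    c, d = b - phi * (b - a), a + phi * (b - a)
    while b - a > tol:
        if objective(c) < objective(d):
            b, d = d, c
            c = b - phi * (b - a)
        else:
            a, c = c, d
            d = a + phi * (b - a)
    m, h = (a + b) / 2, 1e-3
    f_lo, f_m, f_hi = objective(m - h), objective(m), objective(m + h)
    return m + h * (f_lo - f_hi) / (2.0 * (f_lo - 2.0 * f_m + f_hi))


def test_mpjpe_identical_and_single_offset(skeleton):
    ref = random_pose(np.random.default_rng(0))
    assert mpjpe(ref, ref) == 0.0
    pred = ref.copy()
    pred[:, skeleton.index("head")] += [0.18, 0.0, 0.0]
    assert mpjpe(pred, ref, joint_subset=range(18)) == pytest.approx(0.01, abs=1e-12)


def test_mpjpe_matches_loop_oracle(rng, skeleton):
    for _ in range(30):
        pred, ref = random_pose(rng), random_pose(rng)
        idx = skeleton.body_indices
        assert mpjpe(pred, ref) == pytest.approx(oracle_mpjpe(pred, ref, idx), abs=1e-12)


def test_nmpjpe_removes_pure_scale(rng):
    ref = random_pose(rng)
    err, s = nmpjpe(3.0 * ref, ref)
    assert err == pytest.approx(0.0, abs=1e-12)
    assert s == pytest.approx(1.0 / 3.0, abs=1e-12)
    err2, s2 = nmpjpe(ref, ref)
    assert err2 == pytest.approx(0.0, abs=1e-12) and s2 == pytest.approx(1.0)


def test_nmpjpe_scale_matches_golden_section(rng, skeleton):
    for _ in range(10):
        pred, ref = random_pose(rng), random_pose(rng)
        _, s = nmpjpe(pred, ref)
        idx = skeleton.body_indices
        pc = pelvis_center(pred, skeleton)[:, idx]
        rc = pelvis_center(ref, skeleton)[:, idx]
        assert s == pytest.approx(golden_section_scale(pc, rc), abs=1e-9)


def test_nmpjpe_invariant_to_prediction_rescaling(rng):
    pred, ref = random_pose(rng), random_pose(rng)
    base, _ = nmpjpe(pred, ref)
    for alpha in (0.01, 0.5, 7.0, 300.0):
        err, _ = nmpjpe(alpha * pred, ref)
        assert err == pytest.approx(base, abs=1e-9)


def test_time_normalize_linear_ramp_and_constant():
    ramp = np.linspace(0.0, 1.0, 73)
    curve = time_normalize(ramp, (0, 73))
    assert len(curve.mean) == 200
    assert curve.mean[0] == 0.0 and curve.mean[-1] == 1.0
    assert np.allclose(np.diff(curve.mean), np.diff(curve.mean)[0], atol=1e-12)
    const = time_normalize(np.full(40, 2.5), (0, 40))
    assert np.all(const.mean == 2.5)


def test_time_normalize_sine_within_interpolation_bound():
    """Resampling error of a sine obeys the h^2/8 * max|f''| bound."""
    n, rate = 50, 50.0
    t = np.arange(n) / rate
    series = np.sin(2 * np.pi * t)
    curve = time_normalize(series, (0, n))
    t_norm = np.linspace(t[0], t[-1], 200)
    truth = np.sin(2 * np.pi * t_norm)
    h = 1.0 / rate
    bound = h**2 / 8.0 * (2 * np.pi) ** 2
    assert np.abs(curve.mean - truth).max() <= bound


def test_time_normalize_rejects_degenerate_cycles():
    with pytest.raises(DataError):
        time_normalize(np.zeros(10), (4, 5))
    with pytest.raises(DataError):
        time_normalize(np.zeros(10), (0, 20))


def test_curve_stats_examples_and_oracle(rng):
    a = NormalizedCurve(mean=np.zeros(200))
    b = NormalizedCurve(mean=np.full(200, 2.0))
    stats = curve_stats([a, a])
    assert np.all(stats.sd == 0.0)
    stats2 = curve_stats([a, b])
    assert np.all(stats2.mean == 1.0)
    assert np.allclose(stats2.sd, np.sqrt(2.0))
    stack = rng.normal(size=(7, 200))
    got = curve_stats([NormalizedCurve(mean=row) for row in stack])
    assert np.allclose(got.mean, stack.mean(axis=0), atol=1e-12)
    assert np.allclose(got.sd, stack.std(axis=0, ddof=1), atol=1e-12)


def test_accuracy_precision_constant_offset():
    ap = accuracy_precision([np.full(50, 0.3)] * 4)
    assert ap.accuracy_mean == pytest.approx(0.3)
    assert ap.accuracy_sd == pytest.approx(0.0)
    assert ap.precision_mean == pytest.approx(0.0, abs=1e-15)
    assert ap.precision_sd == pytest.approx(0.0, abs=1e-15)


def test_accuracy_precision_across_trial_spread():
    ap = accuracy_precision([np.full(10, 1.0), np.full(10, 2.0), np.full(10, 3.0)])
    assert ap.accuracy_mean == pytest.approx(2.0)
    assert ap.accuracy_sd == pytest.approx(1.0)  # sample SD of {1,2,3}
    assert ap.precision_mean == 0.0


def test_accuracy_precision_recovers_bias_and_noise(rng):
    """Estimates equal the realized per-trial statistics exactly."""
    bias, sigma = 0.07, 0.02
    trials = [bias + rng.normal(scale=sigma, size=400) for _ in range(24)]
    ap = accuracy_precision(trials)
    means = np.array([t.mean() for t in trials])
    sds = np.array([t.std(ddof=1) for t in trials])
    assert ap.accuracy_mean == pytest.approx(means.mean(), abs=1e-12)
    assert ap.precision_mean == pytest.approx(sds.mean(), abs=1e-12)
    # and the realized statistics themselves sit near the injected values
    assert ap.accuracy_mean == pytest.approx(bias, abs=4 * sigma / np.sqrt(400 * 24))
    assert ap.precision_mean == pytest.approx(sigma, rel=0.05)


def test_accuracy_precision_vector_series_uses_euclidean_distance(rng):
    diffs = rng.normal(size=(60, 3))
    ap = accuracy_precision([diffs])
    assert ap.accuracy_mean == pytest.approx(np.linalg.norm(diffs, axis=1).mean())
    assert ap.accuracy_sd is None and ap.precision_sd is None  # single trial


def test_sign_mirroring_negates_accuracy_preserves_precision(rng):
    trials = [rng.normal(loc=0.2, scale=0.1, size=100) for _ in range(6)]
    ap = accuracy_precision(trials)
    flipped = accuracy_precision([-t for t in trials])
    assert flipped.accuracy_mean == pytest.approx(-ap.accuracy_mean, abs=1e-12)
    assert flipped.precision_mean == pytest.approx(ap.precision_mean, abs=1e-12)
    assert flipped.precision_sd == pytest.approx(ap.precision_sd, abs=1e-12)


def test_multicam_averages_per_trial_statistics(rng):
    cam3 = [rng.normal(loc=0.1, size=50) for _ in range(4)]
    cam5 = [rng.normal(loc=0.3, size=50) for _ in range(4)]
    ap = accuracy_precision_multicam({"CAM3": cam3, "CAM5": cam5})
    expected = 0.5 * (
        np.mean([t.mean() for t in cam3]) + np.mean([t.mean() for t in cam5])
    )
    assert ap.accuracy_mean == pytest.approx(expected, abs=1e-12)
    with pytest.raises(DataError):
        accuracy_precision_multicam({"CAM3": cam3, "CAM5": cam5[:2]})
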