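# Methods

## Scope and data model

`skimocap` evaluates skiing-specific 3D kinematics computed from paired
pose streams: a *reference* stream (multi-camera stereophotogrammetry in a
field study; the synthetic generator here) and a *monocular* stream
(single-camera 3D pose estimation; the degradation model here). Poses live
on an 18-keypoint skeleton — head, neck, left/right shoulder, elbow, hand,
hip, knee, ankle, and left/right ski tail and tip — as 3×18 matrices in
meters, right-handed, z up in world data, sampled nominally at 50 Hz with
0-based frame indices. Missing keypoints are carried as a validity mask,
never as NaN magic values.

## Mass model

The relative center of mass is p_COM = (1/M) Σ mᵢ Pᵢ over keypoints.
Cadaver tables give *segment* mass fractions, so a mapping to keypoints is
required; we split each Clauser segment fraction equally between its two
bounding keypoints, assign terminal segments (hand, foot) wholly to their
keypoint, and split the trunk half to the neck and a quarter to each hip
(head+neck 0.073, trunk 0.507, upper arm 0.026, forearm 0.016, hand 0.007,
thigh 0.103, shank 0.043, foot 0.015; total 1.0). Ski keypoints carry zero
mass: the tables cover body segments only, and loading the skis would make
the COM depend on equipment geometry. Weights are overridable per
`SkeletonDefinition` and renormalized to Σ mᵢ = 1 when needed.

## Preprocessing

Gaps from failed reconstructions are bridged by per-coordinate linear
interpolation up to `max_gap` frames (default 5 = 0.1 s at 50 Hz); longer
or boundary gaps stay invalid and are reported. Commercial pattern-fill
algorithms that exploit rigidly co-moving markers are proprietary; linear
interpolation is the simplest defensible stand-in and every filled gap is
flagged. Trajectories are smoothed with a second-order Butterworth low-pass
applied forward-backward (zero phase, hence effectively fourth order and
lag-free). The cut-off is a configuration value, default 6 Hz — a standard
choice for ski kinematics; automatic residual-based cut-off selection is
not implemented.

## Angle conventions

Knee and hip angles are reported literally as the arccos of the normalized
dot product (180° = straight limb), with the argument clamped to [−1, 1] to
absorb floating-point overshoot on collinear limbs. Users expecting
anatomical flexion (0° = straight) can set `angle_convention="flexion"` for
the supplement. The hip angle uses the mid-hip point as the trunk root
because the skeleton has no explicit pelvis keypoint.

## Ski-relative frames and metrics

Monocular capture gives no slope calibration, so "up" is built from the
skier: x′ = unit(tip − tail) of the outside ski; z′ = unit(x′ × a), a the
left-to-right ankle direction, with the sign chosen so z′ points toward
the neck (the trunk defines up without knowing the slope; this assumes the
skis stay roughly perpendicular to the body, approximately true even
airborne); y′ = z′ × x′. The triad's origin is the outside ankle; the
lean-angle triad (x″, y″, z″) shares the axes with its origin at the
mid-ankle point.

- *d_vertical* = ‖COM − outside ankle‖ (m).
- *d_fore/aft* = sin φ, φ the angle from z′ of the ankle→COM vector
  projected to the x′–z′ plane, signed positive toward the ski tip ("fore"
  means toward the tip). A config option also emits sin φ · d_vertical in
  meters, since the dimensionless sine and a meter-valued fore/aft offset
  are both in circulation.
- *λ_lean* = unsigned angle from z″ of the mid-ankle→COM vector projected
  to the y″–z″ plane (degrees).
- Drag area (Barelle's posture model): C_D·A = 0.003·h − 0.026 +
  0.041·(2w). h is the mid-ankle→mid-shoulder vector projected on z′, in
  **centimeters** — with h in meters the formula goes negative, and h ≈ 60
  cm with small w reproduces the known ≈0.20 m² tuck drag area. w is the
  hand-to-hand vector projected on the plane orthogonal to the COM velocity
  (central differences, one-sided at the ends), normalized by the total arm
  span and clamped to [0, 1]. The total span defaults to the instantaneous
  straight hand-to-hand distance; a polyline mode (hand–elbow–shoulder–
  shoulder–elbow–hand) is available since the normalizing span is not
  standardized.

### Outside-leg detection

The inside leg is the one whose ankle is nearer the COM — skiers incline
into the turn, so the COM-nearest ankle cannot be the loaded outside leg
(the opposite mapping fails the synthetic lean geometry). The left-minus-
right ankle-distance signal evolves at the turn frequency (≈0.3 Hz in
giant slalom), so it is low-passed zero-phase at 1 Hz before thresholding
(`detection_presmooth_hz`, disableable); labels are then cleaned by a
5-frame centered majority vote, and switch frames are the first frame of
each new label. Zero-phase smoothing and a centered vote introduce no
systematic delay. Equidistant frames (|d_L − d_R| < ε) inherit the previous
label; a tie on the first frame raises an error asking for a longer
sequence or an explicit seed label.

## Evaluation statistics

Poses are expressed relative to the pelvis (mid-hip) before position
errors are computed, matching networks that predict pelvis-relative pose.
MPJPE is the mean per-joint Euclidean distance over a joint subset — by
default the 14 body joints, skis excluded, with a switch to include them.
NMPJPE first fits the least-squares optimal global scale
s\* = Σ⟨P̂ⱼ,Pⱼ⟩ / Σ‖P̂ⱼ‖² of the prediction onto the reference (per frame by
default; per sequence by config) and reports MPJPE of the rescaled
prediction; it is invariant to any positive rescaling of the prediction,
and the fitted objective never exceeds the unscaled one. Only scale is
normalized — no Procrustes rotation.

Per-frame series are resampled onto 200 equally spaced points of one turn
cycle (switch to switch) by linear interpolation; across trials, the mean
and sample SD (n−1 throughout, given small trial counts) are taken per
point. Accuracy is the mean ± SD across trials of the per-trial mean
monocular-minus-reference differences; precision the mean ± SD of the
per-trial SDs. Vector-valued COM differences are reduced to per-frame
Euclidean distances first, so the COM accuracy is strictly positive. When
several cameras are evaluated, per-trial statistics are averaged across the
camera list before the across-trial aggregation.

## Synthetic giant slalom

The generator exists so the whole pipeline can be verified against known
ground truth. Defaults follow a typical giant-slalom setting: 27 m gate
distance, 8 m gate offset, 26° slope, three gates, 50 Hz, 14 m/s along the
fall line (one turn cycle ≈ 1.93 s; a non-integer number of frames per
cycle avoids switches landing exactly on frames).

A single oscillator s(t) = sin(πt/T + φ) drives the motion: the lateral
course coordinate is −(offset/2)·s so path curvature and lean agree; legs
tilt laterally by 35°·s at the apex (moderate for elite giant slalom) with
the trunk at 0.8 of that tilt (hip angulation); knee angles interpolate
between 165° (outside at apex) and 135° (inside at apex); the trunk pitches
forward 30–40°; hands spread with the turn phase. Each pose is built in a
canonical local frame (x along the skis, y left, z up, origin at the
mid-ankle ground point), where every ground-truth metric is evaluated in
closed form — the ski triad there is the identity, so the formulas are
plain coordinate reads and prescribed angles are exact by construction.
The pose is then placed on the inclined course by a per-frame rigid motion
(heading along the path tangent, up along the slope normal). The analysis
pipeline must re-detect the outside leg and rebuild the frames in world
coordinates, so agreement with ground truth (to 1e-6 and better in the
tests) exercises the construction *and* rigid-motion equivariance. The
drag-area ground truth uses the same central-difference velocity estimator
as the pipeline, applied to the analytic world COM path. With a seed, the
profile amplitudes and phase receive a ±5% reproducible per-run variation
(inter-trial style differences); all randomness flows through explicit
`numpy` generators, never global state.

The degradation model applies, in order: a global scale error about the
pelvis (default 0.95 — monocular scale ambiguity), per-joint bias vectors
(default none), iid Gaussian noise per coordinate (default σ = 0.06 m on
all non-root joints; the hips are the root of a pelvis-relative prediction
and stay exact, which makes the expected per-joint error exactly the 3-D
chi mean 2σ√(2/π) ≈ 1.596σ and puts NMPJPE over the 14 body joints near
(12/14)·1.596·σ ≈ 0.08 m, the magnitude typical of monocular capture at
ski-track camera distances), and optional temporal jitter. Identity
operations are skipped so zero degradation is bit-exact.

**What the generator does not emulate:** temporally correlated and
view-dependent network errors (real monocular error varies with the camera
perspective and is strongly autocorrelated), soft-tissue and annotation
error in the reference, ski deflection and snow interaction, and
perspective-dependent occlusion. Passing tests therefore demonstrate the
correctness of the metric calculus and the estimators under controlled
error structure — not the field accuracy of any particular network.
Because the injected noise is temporally white and unfiltered, the
synthetic angle precisions (≈10–15°) run larger, and arccos nonlinearity
biases near-extended knee angles low; both effects are properties of the
chosen error model, not of the estimators.

## Numerical choices

- ε = 1e-9 m for degenerate-vector checks; arccos arguments clamped to
  [−1, 1]; fore/aft and lean return 0 with a warning when the in-plane
  projection vanishes.
- Scale fitting refuses all-zero predictions (Σ‖P̂‖² < 1e-12).
- Ties in outside-leg detection carry the previous label.
- Turn cycles are half-open [switch_k, switch_{k+1}); the 200-point
  normalized curve spans the cycle endpoints inclusively.
- CSV ingestion uses round-trip float parsing so write→load is bit-exact.

## Problem sizes

The default test and acceptance workloads use three-gate runs (≈289 frames
at 50 Hz), a 6×4 = 24-trial campaign for the accuracy/precision estimators,
20 seeded runs (60 switches) for switch detection, 10 000 frames for the
noise-law check, and 1000 random frames for oracle-equivalence checks —
sizes at which every statistical check is already well resolved.

## Known limitations

- No TRC/C3D ingestion; the canonical CSV/JSON dialect is the only file
  interface.
- No automatic filter cut-off selection; the cut-off is configuration.
- Gap filling is per-coordinate linear, not rigid-body aware.
- Only global scale is normalized in NMPJPE (no rotational alignment), by
  design.
- The accuracy/precision protocol assumes equal-length paired streams on a
  common clock; temporal alignment beyond integer jitter is out of scope.
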