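# Methods

## Physical model

The monitored object is a magnetised nucleus: a nacre bead carrying a small
cylindrical neodymium magnet, implanted in the gonad of a pearl oyster that
sits inside a 4.2 L hemispherical dome. The dome carries 25 single-axis
magnetoresistive sensors: eight each on elevation rings at 6°, 30° and 60°
above the base plane, plus one at the zenith. The ring partition (8+8+8+1)
is the only symmetric split of 25 consistent with a single zenith sensor;
the dome radius, r = (3V/2π)^{1/3} ≈ 0.126 m, follows from the enclosure
volume. Each sensor reads the field component along its measurement axis,
taken as the **outward radial** direction: with that sign convention the
position-weighted channel sum (below) recovers the magnet's moment
direction rather than its antipode. Sensor gain is unknown, so fields are
in arbitrary units with a unit dipole prefactor,
B(r) = (3(m̂·r̂)r̂ − m̂)/|r|³, and noise levels are specified relative to the
RMS of the noiseless signal (default 5%). Per-channel offsets default to
zero: the physical sensors carry offset-compensation circuits. The oyster
rests on a base that places the nucleus on the dome axis at the height of
the second sensor ring, the position with the best calibration accuracy.

## Rotation regimes

Three regimes reproduce the patterns associated with the final shape
classes. All are built on a *tangent walk*: the unit moment direction u
advances by exactly `speed·Δt` of arc along a tangent heading w each step,
and w then diffuses in the tangent plane by a Gaussian angle of SD
`jitter·√Δt`.

- **Round** (random tumbling): heading jitter 30 °/√h — the rotation axis
  decorrelates within hours and u wanders over the sphere.
- **Atypical** (axial rotation): heading jitter 2 °/√h — near-uniform
  rotation about a slowly drifting axis; with zero jitter the trajectory is
  exactly periodic (one closed circle per revolution).
- **Other** (no rotation): u wobbles around a fixed direction. The wobble
  is a sum of three random-phase sinusoids per tangent component with
  periods drawn log-uniformly between 2 h and 12 h, scaled to a total
  angular SD of 0.5°. Sinusoidal (band-limited) wobble keeps the apparent
  angular speed below 0.05 ° min⁻¹ at *any* sampling rate, which diffusive
  or white perturbations cannot do.

Per-pearl rotation speeds are drawn from Normal(0.69, 0.13²) ° min⁻¹
truncated to positive, **identically for Round and Atypical**: the study
conditions found no speed difference between shape classes, so speed must
carry no class signal — only the pattern does. Other pearls have speed 0.

A rejection-event injector ramps the angular speed to 4.8 ° min⁻¹ (default
over 10 min) after a chosen onset, leaving the trajectory bit-identical
before it — the signature observed before nucleus rejection.

## Signal path

Channels are denoised with a Gaussian-weighted moving average (window 60
samples at the native 1 Hz; kernel SD = window/5, a standard engineering
default, edge windows renormalised). Orientation is reconstructed by the
acquisition software's estimator: v_t = Σᵢ valueᵢ(t)·p̂ᵢ, normalised to the
unit sphere. The estimator is linear, so smoothing and reconstruction
commute up to normalisation. With hemispherical coverage it is biased: for
the 25-sensor dome with the magnet at second-ring height the transfer
matrix is diagonal, ≈ diag(0.83, 0.83, 1) up to scale, giving a median
direction error of ≈ 4° (bounded < 10°) that vanishes on a dense full-sphere
grid (< 0.01° at 1000 sensors). Because the matrix is azimuthally isotropic,
equator-projected azimuth rates are exact: the simulated clock scene
(one revolution per hour, moment perpendicular to the axis) reconstructs to
6 ° min⁻¹ within 1e−6.

Frames whose raw norm falls below 1% of the series median are flagged
invalid rather than interpolated. The equator projection masks samples with
|z| > 0.95 (pole-ill-conditioned azimuth). Angular speed is the mean
great-circle step converted to ° min⁻¹; on noisy data the step is taken at
a 10-minute lag, which suppresses the positive chord bias that independent
direction errors induce at slow speeds (at 5% noise and a 600 s lag the
residual bias is < 1%). Speed is measured from 3-D step angles by default;
the azimuth-rate estimator used for the calibration rig is available
separately. Whether a near-static signal means a non-rotating pearl or
rotation about the magnet's own axis is unknowable from the sensors; an
*observability score* (fraction of steps above a noise floor) surfaces the
ambiguity instead of hiding it. The legacy tabular representation — per-bin
mean angular velocity and acceleration, 100 bins per day — is retained for
comparison with feature-based classifiers.

The calibration rig's *parallel* orientation (moment on the rotation axis)
produces a constant field and is unobservable by symmetry; calibration
accuracy, 100·max(0, 1 − |est − true|/true), is therefore averaged over the
observable orientations (perpendicular, diagonal). At the third ring the
reconstruction's polar stretch collapses the diagonal scene inside the pole
cut, and the ring's accuracy drops sharply — qualitatively matching the
physical device, where only the first two rings calibrated well.

## Imaging

Each dataset sample is one 224×224 RGB image of a trajectory segment
scattered on the unit sphere, viewed orthographically from the *barycenter
viewpoint* — the normalised mean direction, i.e. the camera that faces the
densest part of the data; for antipodally balanced clouds the fallback is
the normal of the best-fit plane (smallest-variance scatter axis). Points
are coloured by time rank (viridis) on a dark background with a thin sphere
outline; the rasteriser is a deterministic latest-point-wins painter, so
identical segments give bit-identical pixels on any platform. Six views
rotated in 60° increments about the camera axis can be rendered; only the
first enters the datasets (additional views added noise in the reference
evaluation). Segments are contiguous days (86 400 s) or weeks (604 800 s);
a trailing partial segment is kept only if at least half full. Variants:
`full` = all weekly segments, `week` = last weekly segment (one per pearl),
`month` = last ≤ 4 weekly segments, `day` = last week split per day. Each
sample carries the pearl's total cultivation days and the graft-to-segment
offset in days.

## Classifier

Transfer-learning architecture: a frozen convolutional backbone, two
z-scored metadata scalars appended to the flattened features, then a
trainable dense(256) → dropout(0.5) → dense(3, softmax) head. The metadata
weighting is learned by the first dense layer on z-scored inputs (no
hand-set constants). The default backbone, `tiny-cnn`, is a frozen
fixed-seed random-filter conv stack (block-mean 224→56, conv 3×3×8 + ReLU +
max-pool, conv 3×3×16 + ReLU, adaptive 4×4 average pool → 256 features);
random convolutional features are a standard cheap image embedding and
need no pretrained weights, keeping the pipeline self-contained and
deterministic. `vgg16-frozen` (ImageNet VGG-16 conv base, 7·7·512 = 25 088
features) is registered for environments providing torch/torchvision. The
head is trained with minibatch Adam (lr 1e−3, batch 16, ≤ 30 epochs) on
softmax cross-entropy with inverted dropout; feature and metadata
normalisation statistics come from the training split only; the best
validation epoch's weights are restored (patience 10). Training is
deterministic under a fixed seed. Per-pearl predictions take the modal
class over the pearl's samples, ties broken by highest mean probability.

## Evaluation

Splits are grouped by pearl (70/15/15 train/val/test), stratified by class
with largest-remainder apportionment, with harvest-date terciles
interleaved within each class so every split receives a spread of harvest
dates where group sizes permit (the exact balancing protocol of the
reference evaluation is unspecified; quantile groups with best-effort
interleaving is this package's stand-in). Holdout is repeated with
independent seed-derived splits; metrics (accuracy, per-class F1, macro F1
= unweighted mean, weighted F1 = support-weighted mean, F1 = 0 when
undefined) are reported at sample and pearl level with mean ± SD over
repeats. Repeats whose test split lacks a class are flagged and excluded
from per-class aggregation. Grid search is exhaustive on train+validation,
selecting by validation accuracy (ties → fewer epochs, then lower learning
rate). Survival-table percentages truncate toward zero, matching the
printed reference cells (14/22 → 63%).

## Scaled problem sizes

The package's default experiment is a desk-scale analogue of the year-long
physical study, chosen once as the standard configuration: 60 pearls,
acquisitions covering the last 3–6 weeks of cultivation sampled at one
point per minute (the physical device samples at 1 Hz for up to a week per
acquisition), 5% sensor noise, 10-repeat holdout. At the 60 s sampling
interval the smoothing window defaults to 9 samples so that the filter span
(9 min) stays below the 10-min speed-estimation lag while still attenuating
noise ≈ 3×; parameter-recovery analyses at the native 1 Hz use the full
60-sample window. Cohort-level speed recovery uses 40 pearls × 2 h at 1 Hz.

## What the generator does and does not emulate

It emulates: dipole geometry and the resulting reconstruction bias,
class-conditional rotation patterns with realistic speeds, sensor noise,
the weekly acquisition structure, and cultivation metadata. It does not
emulate: oyster body movement (the magnet position is fixed; slow
translation is plumbed but off by default), nonstationary or mixed rotation
patterns, temperature/feeding covariates, or calibrated field units.
Consequently the synthetic classes are more cleanly separable than real
pearls: end-to-end accuracies here (≈ 0.95–1.0) show that the pipeline
preserves and recovers the class signal, not that real cohorts are this
easy. One concrete divergence: with the Round regime's axis diffusion of
30 °/√h a *single day* of data already reveals the tumbling pattern, so
day-level classification is about as accurate as week-level on synthetic
cohorts, whereas on real data day-level prediction was much worse than
week-level. The expected full ≥ week relation does hold (more training
samples per pearl, denoised by the per-pearl vote).

## Numerical choices

Unit-norm drift in the tangent walk is controlled by renormalising every
1024 steps (residual < 1e−13 per week). arccos arguments are clamped to
[−1, 1]; step-angle tolerances in tests allow the ~1e−8 rad arccos noise
floor. Degenerate inputs: zero-norm reconstruction frames are flagged, not
interpolated; empty renders produce the background-plus-wireframe image;
training with a class missing from the training split warns and proceeds
(its F1 reports 0 when undefined). All random draws flow from explicit
integer seeds through `numpy.random.default_rng`; derived child seeds stay
below 2³¹.
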