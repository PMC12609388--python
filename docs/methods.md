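# Methods

## The problem

Skeleton-based fall detectors classify short sequences of 3D body
keypoints as *fall* versus *daily activity*. Two failure modes dominate in
deployment: the camera views the subject from an angle unseen in training,
and parts of the body are occluded. The pipeline implemented here counters
both with (a) training-time augmentation — synthetic viewpoint generation
by two-axis rotation and skeleton-level occlusion simulation — and (b) a
consensus rule at inference time that averages the fall probabilities of
several rotated copies of the input. A per-joint affine alignment converts
Kinect-25 skeletons into the COCO-17 convention so heterogeneous sources
can train one model.

## Data model and coordinate conventions

A sequence is a `(T, V, 3)` array of joint positions with a binary label,
a convention tag (COCO-17 or Kinect-25) and a per-frame validity mask.
Coordinates live in a subject-centred world frame: origin on the floor
beneath the subject, `z` up (the yaw axis), `x` the tilt axis, `y`
completing a right-handed frame. Rotations are therefore taken about the
coordinate origin, which is meaningful only for subject-centred data; an
optional `recenter_mid_hip` step converts to strictly root-relative
coordinates when a pose-lifter emits an arbitrary frame. Occluded joints
and dead frames are encoded as exact zeros (with the mask cleared for dead
frames), never NaN — zeros pass unchanged through rotation and match how
the classifier's zero-masking treats missing evidence.

Normalization fixes `T = 300` frames by default: longer sequences are
uniformly subsampled (output frame *i*, 1-based, takes input frame
`round(i·T/target)`), shorter ones are tail-padded with zeros and a false
mask. Padding with zeros rather than loop-repeat keeps padding
indistinguishable from a blackout, which the model must tolerate anyway.

## Augmentation

The viewpoint operator is `R(θx, θz) = Rx(θx) · Rz(θz)` — yaw about the
vertical axis first, then tilt — applied frame-wise to every joint. The
default grid is `θx ∈ {0°, 15°, 25°}` × `θz ∈ {0°, 40°, …, 320°}`,
i.e. 27 views per sequence. Angles are degrees in every interface and
radians internally.

Occlusion is simulated at the skeleton level: a *spatial box* zeroes all
joints inside a randomly placed axis-aligned box (sized as a fraction,
default 0.3, of the skeleton's bounding box) over a random contiguous
frame window; a *temporal blackout* zeroes whole frames and clears their
mask. Ten variants per source sequence by default. This is a deliberate
fidelity gap: a real pipeline occludes pixels and re-runs pose extraction,
whose failure modes (joint hallucination, interpolation) are richer than
zeroing. A blackout is clamped so at least 10% of frames stay valid — an
all-zero sequence carries no trainable signal. All placement randomness is
drawn from the occlusion specification's seed, so augmentation is reproducible.

## Kinect-25 → COCO-17 alignment

Each COCO target joint *j* is predicted from one corresponding Kinect
joint through its own affine map, `P'_j = P_kinect,corr(j) A_jᵀ + b_j`,
fitted by ordinary least squares in homogeneous coordinates on 30 randomly
sampled paired frames (uniform without replacement, seeded). A full 3×3
`A_j` absorbs rotation, scale and shear; per-joint maps (rather than one
body-wide map) correct the differing joint schemas. Fit quality is the
per-joint mean squared Euclidean error (MPJPE squared) and its mean over
joints, plus mean Euclidean error before/after alignment for bar-chart
comparison. Four non-degenerate frames determine a 3D affine map, so
fitting refuses fewer, and a joint whose source points are affinely
dependent (e.g. a frozen joint) raises an error naming the joint. The
default correspondence table is anatomically motivated configuration —
the five facial COCO keypoints all draw on the Kinect head joint and are
separated by their translations — and callers may substitute their own.

## The synthetic generator

The generator is the package's study-condition definition: it produces
the statistical structure the experiments assume, not biomechanics. A
canonical unit-height body (proportions fixed, per-sequence scale jitter
±10%) is driven through keyframe motifs: falls (stand → smoothstep descent
→ prone persistence), walking (sinusoidal gait), sitting, squatting, and a
slow controlled recline that ends at the same floor height and pitch as a
fall. The recline exists so that *final posture does not identify a fall*
— only descent speed does, which is exactly the cue whose distribution
shifts between datasets of staged versus realistic falls. A slow rigid 3D
sway keeps every joint trajectory affinely full-rank (needed for affine
map fitting) and adds realism.

Two domains encode the fall-dynamics contrast between a realistic-fall
corpus and a slower, staged-fall corpus:

| motif descent duration | fast domain | slow domain |
|---|---|---|
| fall | U(0.20, 0.35) s | U(2.0, 2.6) s |
| recline | U(1.1, 1.4) s | U(4.0, 5.0) s |

The bands are disjoint *within* each domain — a one-dimensional threshold
on the floor-descent-rate statistic (`floor_descent_rate`) classifies
>90% in-domain, which the tests verify — and interleave *across* domains:
a slow-domain fall descends more slowly than a fast-domain recline, so a
fast-domain-only model has no basis for calling it a fall. Mean peak
vertical fall velocity differs between domains by a factor ≈ 8 (the
package asserts ≥ 2). The per-domain durations are design constants, not
measurements of any real corpus.

Defaults are 300 frames at 25 fps (12 s), which accommodates the slowest
motif. Tests and the acceptance script run at 80 frames / 10 fps — the
same kinematics on a coarser clock; the fastest fall still spans 2–4
frames and every duration contrast survives. Gaussian coordinate jitter
(default sd 0.01 body heights) models pose-estimation noise; it is white,
whereas real pose-extraction error is temporally correlated and
structured, so passing tests here show correctness of the pipeline, not
performance on real video.

A paired mode emits the same motion in the Kinect-25 layout together with
a COCO-17 view generated by known per-joint affine maps (random
well-conditioned maps, |det A| ≥ 0.2), for map-recovery experiments. A
rebalancing utility oversamples the minority class with jittered copies,
keeping source ids so split logic treats copies as variants.

## The classifier

The classifier is a multi-stream spatio-temporal graph-convolutional
network in the richly-activated style. Each stream alternates spatial
graph convolution over the 17-joint bone graph — `y = Σ_k (W_k x) A_k`
with a partitioned, row-normalized adjacency stack (uniform / distance /
spatial partitions) — with temporal convolution along frames, batch
normalisation and ReLU, then global average pooling and a two-class head.
Streams after the first receive the input with exactly
`ceil(mask_fraction · 17)` joints zeroed: the joints most activated by the
preceding streams, ranked by the rectified class-activation map of the
predicted class, aggregated over earlier streams. Class scores are summed
across streams before the softmax. The masks are treated as constants in
the backward pass.

The backbone is implemented in numpy with explicit forward/backward
passes (verified against finite differences in the test suite); it is
single-precision and deterministic under the initialisation seed. The
`mixed_precision` flag is accepted and recorded for configuration
compatibility but computation is single-precision float32 regardless —
half precision buys nothing on a BLAS-backed CPU path. Default depth is
three blocks, channels (16, 32, 32) with temporal strides (1, 2, 2): the
strided hierarchy gives the receptive field (~2 s at 10 fps) needed to
discriminate descent durations; a two-block variant learns single-domain
tasks but underfits the dual-domain task. Parameter count is a pure
function of the configuration. No published layer widths exist for the
reference design at 17 joints, so no parameter-count claim is made; the
count is logged in `summary()`.

Training is mini-batch gradient descent (SGD with momentum and step decay
by default; Adam available and used in the tests for fast convergence at
small scale), softmax cross-entropy with optional balanced class weights.
Rotation/occlusion augmentation can run lazily inside the batch loader
with a per-epoch seed stream, so the training loop sees fresh transformed
copies each epoch. Single-class data warns and proceeds; a non-finite
loss aborts with a diagnostic. The decision threshold on the fall
probability is 0.5.

## Consensus inference and evaluation

`aggregate_predict` generates one rotated copy per configured angle pair
(default: identity plus 15° and 25° tilt), predicts each independently and
averages the fall probabilities arithmetically; majority vote and
logit-mean are non-default options. With a single identity angle it
reduces exactly to plain prediction. Metrics are the five standard
confusion-matrix quantities with falls positive; undefined ratios (zero
denominators) are NaN, never 0, and tabular output renders percentages
with two decimals.

The ablation driver trains data-recipe variants (plain / +occluded /
+rotated / +second domain) over folds × seeds and scores each against a
suite of evaluation sets. Folds partition by `source_id`, and an overlap
between any training pool and an evaluation set aborts — augmented copies
of a recording must never be scored by a model that trained on it.
Desk-scale defaults are 2 folds × 2 seeds; the full 5 × 5 protocol is a
parameter away.

## Problem sizes and expected outcomes

The experiment-scale defaults used by the test suite and the acceptance
script: 80-frame clips at 10 fps, 160 training sequences per domain,
1-stream (domain experiments) or 2-stream (learnability) networks of
16–32 channels, 20–40 epochs with Adam at lr 0.01. Under these
conditions the package reproduces, at synthetic scale, the qualitative
result structure of augmentation-based fall detection: a reduced model
reaches ≥95% training accuracy on 200 separable sequences in 20 epochs;
a fast-domain-only model scores ≥90% in-domain but near 50% on the slow
domain (it reads slow falls as controlled reclines); a dual-domain model
scores ≥90% on both.

## Known limitations

- Motifs are keyframe kinematics, not dynamics: no impact transients,
  balance recovery, or inter-subject style variation.
- Occlusion is modelled as zeroed joints/frames, not as the output of a
  pose extractor on occluded pixels.
- White coordinate noise understates the structured error of real pose
  estimation.
- The Kinect-25 correspondence table is a configuration default, not a
  validated anatomical mapping.
- The numpy backbone is CPU-bound; it is sized for desk-scale experiments,
  not for training on real corpora.
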