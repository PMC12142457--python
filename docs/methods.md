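# Methods

`brachychoice` classifies a pelvic brachytherapy anatomy — the clinical
target volume (CTV), the organs at risk (OARs) and the digitized central
tandem — as suited to an interstitial Syed applicator (label 1) or an
intracavitary tandem-and-ovoids (T&O) applicator (label 0). This note
records the model, the conventions the implementation fixes where the
problem leaves them open, what the synthetic-data generator does and does
not emulate, and the numerical choices that matter.

## Input encoding

CT intensities are deliberately excluded: TG-43 dose calculation assumes
homogeneous tissue, so the anatomy's *geometry* carries the decision. An
insertion is encoded on a 2 mm isotropic grid of 165 x 176 x 176 voxels
(axis order superior-inferior, anterior-posterior, left-right) as three
channels:

1. a coded label volume — 0 background, 1 CTV (HR-CTV unioned with the
   IR-CTV when contoured), 2 the central tandem dilated to a 5 mm diameter
   tube, 3 any OAR (bladder, rectum, sigmoid, small bowel, large bowel);
2. the Euclidean distance, in millimetres, from every CTV voxel center to
   the tandem's central axis, zero elsewhere;
3. the same distance map for OAR voxels.

No normalization is applied anywhere: the raw millimetre values are the
point — they give the network absolute size and distance information that
a label mask alone lacks (the ablation experiment quantifies exactly this).

Conventions fixed here:

- **Distances are to the tandem polyline**, not to the dilated tube
  surface (the two differ by a constant 2.5 mm offset) and not in-plane
  only. The distance is the closed-form point-to-segment minimum over
  polyline segments, evaluated at voxel centers with no sub-voxel
  correction.
- **Label precedence at overlaps is tandem > CTV > OAR.** The tandem
  anchors both distance channels and must stay visible. Voxels re-coded 2
  lose their membership in the distance-channel supports.
- **The crop window is centered on the tandem centroid**, registering
  every insertion to the same anatomical axis. Structures extending beyond
  the window are truncated with a warning reporting the voxel loss.
- **Rasterization** assigns a voxel to a planar contour when its center z
  lies within half the native slice spacing of the contour plane and its
  in-plane center is inside the polygon under the even-odd rule.
  Resampling of label masks is nearest-neighbor (labels are categorical).
- The tandem polyline must be strictly monotone along the
  superior-inferior axis; malformed tandems are rejected, never silently
  reordered.

## Network

A compact 3D CNN: six blocks of zero-pad, stride-1 convolution, max-pool,
batch-norm, ReLU, followed by global average pooling, a dense layer of 8
units, dropout, a single output unit and a sigmoid. Block parameters
(pad / filters / kernel / pool):

| block | pad | filters | kernel | pool |
|------:|-----|--------:|--------|------|
| 1 | (1,1,1) | 4 | (3,2,2) | (3,3,3) |
| 2 | (1,1,1) | 4 | (2,2,2) | (2,2,2) |
| 3 | (1,1,1) | 8 | (3,3,3) | (2,2,2) |
| 4 | (2,1,1) | 8 | (3,2,2) | (2,2,2) |
| 5 | (1,1,1) | 4 | (3,3,3) | (2,2,2) |
| 6 | (1,1,1) | 4 | (3,3,3) | (2,2,2) |

The 3-channel network has 3409 parameters — 3281 convolution/dense weights
and biases plus 4 values per batch-normalized channel (scale, shift,
running mean, running variance; 32 channels, 128 values). The counting
convention matters: counting only optimizer-updated values would give 3345
(scale and shift) or 3281 (weights and biases alone). The 1-channel
mask-only variant has 3313 parameters (only the block-1 kernel shrinks).

The network is implemented directly on NumPy arrays with an explicit
backward pass. At 3.4k parameters an autodiff framework adds nothing; the
analytic gradients are verified against central finite differences to a
relative 1e-4 in the test suite. Parameters are float32 by default (a
float64 build is available and is what the gradient checks use).

Conventions fixed here, since no single standard exists:

- **Pooling is non-overlapping and ceil-mode**: a window must fit at least
  once, trailing partial windows are allowed. Floor-mode pooling would
  collapse the chain to size zero on the 48^3 downscaled grid used by the
  recovery experiments, while ceil mode leaves the full-size
  165 x 176 x 176 chain unchanged (final feature map 2 x 2 x 2).
- **Initialization** is uniform fan-in scaling, U(-1/sqrt(fan_in),
  +1/sqrt(fan_in)) for weights, zero biases, under a caller-supplied seed;
  two builds with one seed are bit-identical.
- **Dropout (rate 0.10)** sits between the two dense layers and is
  inactive at inference. **Inference uses batch-norm running statistics**
  (momentum 0.1), so predictions are independent of batch composition.
- The decision rule is Syed iff the sigmoid score p >= 0.5 (boundary
  inclusive). A threshold-sweep utility is provided for sensitivity /
  specificity trade-offs; ties break toward 0.5.

## Training

The loss is binary cross-entropy over the batch plus an L1 penalty,

    L = -(1/N) sum_i [y_i log p_i + (1 - y_i) log(1 - p_i)] + lambda sum_j |W_j|,

with lambda = 0.03 at full scale. The L1 term is applied to every
optimizer-updated parameter (convolution and dense weights and biases,
batch-norm scale and shift; running statistics excluded). Scores at exactly
0 or 1 are clamped to machine epsilon with a warning.

- **Balanced patient-level sampling**: each batch slot independently picks
  a class with probability 0.5, then a uniform patient of that class, then
  a uniform insertion of that patient — the expected class frequency in a
  batch is 0.5 regardless of the insertion imbalance.
- **Augmentation**: with probability 0.75 a sample is augmented — equally
  likely a translation (uniform per-axis, bounded by +/-10 mm by default;
  the bound is not standardized and is configurable) or a rotation of up
  to 10 degrees about the superior-inferior axis — followed by an
  independent left-right flip with probability 0.5 (overall flip rate
  0.375; the flip is conditional on having been augmented). No deformation
  is ever applied: absolute volume and distances drive the decision. All
  channels are transported rigidly with nearest-neighbor resampling —
  under a rigid motion applied jointly to anatomy and tandem the distance
  values are exactly unchanged, so transporting them is exact, not an
  approximation.
- **Schedule**: learning rate 0.001 decaying by 0.93 every 200 batches
  (staircase), 400 epochs of 40 batches (cross-validation) or 50 batches
  (final full-cohort training) of 8 samples at full scale. The optimizer
  is not standardized for this architecture; Adam (beta 0.9/0.999) is used.
- **Cross-validation is grouped at the patient level**: all insertions of
  one patient share a fold (repeat insertions are highly correlated and
  would otherwise leak). Folds are stratified by class where possible —
  an addition that reduces fold-to-fold variance; patient counts per fold
  differ by at most one. Validation accuracy is defined per insertion;
  fold summaries report mean and sample standard deviation (ddof = 1).

The model surface follows the statsmodels idiom: `SuitabilityModel(records,
spec, config).fit()` returns a `TrainingResults` with the trained network,
per-epoch history and a `summary()`; `cross_validate` returns per-fold
tables with the same conventions.

## Handcrafted features and the classical-ML benchmark

Twenty geometric features per insertion, in a fixed, documented order
(also the CSV schema):

- CTV volume (cc): voxel count x voxel volume;
- average and maximum **lateral extension**: per CTV-containing axial
  slice, the maximum in-plane distance from the tandem axis point on that
  slice to any CTV voxel center; the axis is the polyline interpolated in
  z, extended beyond its endpoints as the least-squares straight line;
- average and maximum **center-of-mass offset** (asymmetry): per-slice
  in-plane distance between the CTV centroid and the axis point;
- per OAR (bladder, rectum, sigmoid, small bowel, large bowel): maximum,
  minimum and average distance to the CTV surface over the **nearest-2cc**
  portion of the organ — the spatial analogue of the D2cc planning metric.
  The distance of an OAR voxel is the unsigned Euclidean distance from its
  center to the nearest CTV *boundary* voxel center (6-connectivity
  boundary), and 0 inside the CTV; the selection is the
  floor(2000 mm^3 / voxel volume) voxels of smallest distance (250 at
  2 mm), all voxels when the organ is smaller than 2 cc, ties broken by
  distance then lexicographic voxel index. A missing OAR contour
  contributes a 999 mm sentinel (far = dosimetrically irrelevant), logged.

The benchmark ranks features by one-way ANOVA F-score (constant features
get F = 0 with a warning), balances classes with SMOTE (each synthetic
minority sample is x + u(neighbor - x), u ~ U(0,1), neighbor among the k=5
nearest minority samples), standardizes, grid-searches four classifier
families (SVM, random forest, k-NN, decision tree; the search spaces are
not standardized and are defined in `DEFAULT_GRIDS`, logged per run) with
five-fold CV, and soft-votes: Syed iff the mean of the four predicted Syed
probabilities is >= 0.5. Any number of top-ranked features from 1 to 20 is
supported; 8 is the default.

## Synthetic cohorts

Institutional contour data cannot be shared, so validation runs on
parametric phantoms: a near-vertical tandem (60 mm, quadratic lateral bow
up to ~2 mm), a CTV of one to three ellipsoids with controllable volume
(the regimes span roughly 20-110 cc; the generator accepts anything in the
20-120 cc clinical range), lateral extent and left-right offset, and five
OARs placed anatomically (bladder anterior, rectum posterior, sigmoid
superior — clear of the tandem tip — bowel lateral/superior) at
controllable gaps. Contours are sampled at 2.5 mm slice spacing with a
smooth low-order radial surface jitter (1 mm default).

The ground-truth label is a deterministic geometric rule evaluated on the
*generating parameters* by dense (0.5 mm) slice integration of the exact
cross-sections — never on the rasterization: Syed iff maximal lateral
extension > 30 mm, or maximal center-of-mass offset > 8 mm, or volume >
60 cc. The thresholds follow the published guidance that intracavitary
applicators suit tumors smaller than roughly 4 x 3 x 3 cm, with the
asymmetry threshold set to the scale at which an offset tumor leaves the
reach of a centered intracavitary dose distribution. Labels are therefore
noiseless; an optional label-flip rate can emulate physician variability.
Patients receive one to five insertions as jittered copies (a few mm) of a
shared base anatomy, so grouped-CV leakage is meaningful to test, and the
class-regime sampling keeps each patient's intended class stable under the
jitter.

What the phantoms do **not** emulate: real contouring variability and
inter-observer disagreement, non-ellipsoidal tumor topologies, deformable
inter-insertion anatomy, hybrid applicators, and any dosimetry. Passing
the recovery experiments shows the pipeline faithfully recovers a
geometric decision rule end to end; it does not certify clinical accuracy
on patient data.

## Downscaled experiments

The full-scale configuration (165 x 176 x 176, 400 epochs) is sized for a
GPU and institutional data. The package's reference validation runs the
identical pipeline at desk scale: a 48^3 grid at 4 mm spacing (192 mm
field of view, large enough for the phantom pelvis; absolute millimetre
distances are preserved so the rule thresholds keep their meaning), 60
patients x 2 insertions, 3-fold grouped CV, 25 epochs of 20 batches of 8,
and an L1 weight of 0.003 — the full-scale 0.03 was tuned against a 16k-step
schedule and at a few hundred steps it drives the 3.4k-parameter network
toward the all-zero solution. The ablation comparison (FULL vs MASK_ONLY
input) reuses 60 insertions under identical seeds and folds, 2 folds, 15
epochs. These sizes are the package's reference configuration for the
recovery checks, chosen so the whole validation runs on one CPU core in
minutes.

## Numerical choices and degenerate inputs

- Even-odd point-in-polygon by horizontal ray casting; points exactly on a
  polygon edge are ambiguous at float precision (tests exclude a 1e-9
  neighborhood of the boundary). Polygons need >= 3 vertices
  (`DegenerateContour` otherwise).
- Tube membership uses a <= comparison with a 1e-12 slack; diameter 0
  keeps exactly the voxel centers on the line.
- `lat_ext_avg <= lat_ext_max` (and the per-OAR min <= avg <= max) are
  enforced structurally; float summation can otherwise violate them by
  1e-15.
- Metrics with an empty denominator are NaN, never 0; percentages are
  reported to one decimal.
- Empty CTV -> `MissingTarget`; absent tandem -> `MissingTandem`;
  single-class training data -> `ClassMissing`; a minority class of one ->
  `SmoteError`; fewer patients than folds -> `FoldError`; non-finite loss
  -> `TrainingDiverged`.
- All randomness flows from caller-supplied integer seeds through
  `numpy.random.Generator`; repeat runs are bit-identical.

## Known limitations

- The published trained weights are not released, so no attempt is made to
  reproduce their exact fold accuracies or test metrics on patient data;
  the published table metrics are recomputed from their confusion counts
  and the architecture/loss/schedule are implemented exactly.
- The padding/stride, pooling-edge, initializer and optimizer conventions
  above are this package's documented choices, not established facts about
  the original training setup.
- Whether batch-norm statistics were frozen per-fold or recomputed at test
  time is not standardized; this implementation freezes running statistics
  at the end of training.
- The mask-only ablation mode still sees absolute size implicitly (voxel
  counts at fixed spacing); the ablation therefore measures the value of
  *explicit* distance encoding, which is the published comparison.
- Training at the full 165 x 176 x 176 scale is possible but slow on one
  CPU; the NumPy implementation is tuned for the downscaled validation
  scale.
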