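# Methods

`phandose` implements a desk-scale version of a question from knowledge-based
treatment planning: **can the baseline risk of late rectal bleeding after
prostate radiotherapy be estimated from anatomy alone**, by predicting the
3D dose distribution a planner would produce with a convolutional network
and then evaluating normal-tissue complication probability (NTCP) models on
the predicted dose?  Every stage — cohort simulation, preprocessing, model
training, dose prediction, DVH/NTCP evaluation — runs from a single seed
with no patient data.

## Synthetic pelvic phantoms

Real planning CTs and VMAT doses cannot be redistributed, so the package
generates patient-equivalents whose *statistical* structure matches what the
analysis needs: anatomically plausible organ geometry with inter-patient
variability, PTV-conformal dose with concave rectal sparing, and a spread
of rectal NTCP values comparable to a clinical VMAT cohort.

**Anatomy.** On a 64 x 64 x 32 grid at 3 mm isotropic voxels (about a
pelvis-sized field of view at coarse resolution), each phantom has: a
prostate-PTV ellipsoid (radii sampled per axis, ~13-21 mm); a curved
rectal tube posterior to it (radius 12-16 mm, bowing posteriorly toward the
cranial/caudal ends); a bladder superior-anterior; two femoral-head spheres
lateral; an elliptical body outline.  The key sampled quantity is the
**PTV-rectum gap** (default -9 to -4 mm): negative values leave a thin
overlap band where the PTV margin reaches into the anterior rectal wall,
exactly as clinical structure sets overlap (clinical rectum D2% values at or
above the prescription imply the rectum contour reaches full dose).  All
other organ pairs are disjoint by construction.  Structures are cropped
craniocaudally to PTV +/- 1 cm, the range in which prostate plans contour
them.  Default organ dimensions are textbook-scale rather than fitted to any
dataset, and every one of them is a config field.

**Dose.** The dose model is analytic, not a transport or optimiser
simulation — the analysis needs realistic DVH/NTCP structure, not physical
deliverability.  With `d` the Euclidean distance (mm) from the PTV surface:

    dose = P * [ (1-b) * sigmoid((d50 - d)/w) + b * exp(-d/L) ] * sparing

* `P` = 74.8 Gy prescription in 34 fractions (the intermediate/high-risk
  prostate schedule the cohort emulates);
* sigmoid penumbra: ~100% at the PTV surface, 50% at `d50` (sampled
  9-13 mm), width `w` = 2 mm — the lateral fall-off of an arc plan;
* low-dose bath: fraction `b` = 0.32 decaying over `L` = 45 mm, carrying
  the intermediate dose that spreads toward the bladder;
* rectal sparing: a multiplicative attenuation `1 - a * exp(-d_rect/9mm)`
  (strength `a` sampled 0.15-0.25, suppressed inside/near the PTV) that
  deepens toward the rectum and produces the concave posterior isodose
  characteristic of rectum-sparing VMAT.

Inside the PTV the dose is `P * (1 + boost)` with a smooth random boost in
[-3%, +7%] tapered toward the PTV surface (optimisers push hot spots away
from the rectal interface), which makes D50% > D95% strictly and gives the
coverage-rescaling step something real to do.  Smooth additive noise
(0.6 Gy) emulates plan-to-plan variability; dose is clipped to 110% of
prescription (the planning-goal maximum) and zeroed outside the body.

**Calibration.** The free dose-model parameters were calibrated once so the
default 60-phantom cohort reproduces the target statistics, and then frozen:
planned G2-LRB LKB NTCP range 7.0-15.5% with 90% of samples in [8%, 17%];
rectum V57.7Gy <= 18% in 90% and V75.1Gy = 0% in 95% of samples (the
clinical rectal constraints); Spearman correlation of rectum V70Gy with the
sampled gap -0.92.  That anatomy-dose coupling is the learnable signal the
network must recover.

**What the phantoms do not emulate** — and hence what passing tests do not
show about clinical data: real CT texture and artefacts, inter-planner
variability in optimisation style, deformable anatomy (gas, bladder
filling), non-ellipsoidal target shapes, and any dose-volume trade-offs
beyond the single rectum-sparing mechanism.  Results on phantoms demonstrate
that the *pipeline* can recover a known anatomy-risk signal at desk scale,
not that the clinical effect size is reproduced.

## Preprocessing

1. **Crop/resize** (clinical-scale grids): the in-plane field of view is
   cropped around the body-mask centroid and resampled — bilinear for image
   and dose, nearest-neighbour for masks (kept strictly binary).  In-plane
   spacing scales by crop/target (e.g. 0.98 mm at 400 -> 128 becomes
   3.06 mm).  Phantom grids are already network-sized, so the default
   config passes them through.  Crop centering on the body centroid mimics
   a couch-centred field of view without registration.
2. **Slice selection**: consecutive slices covering the PTV plus a 1 cm
   craniocaudal margin, capped at 80; if the extent exceeds the cap the
   range is truncated symmetrically about the PTV centroid slice (preserves
   target context).
3. **Coverage rescaling**: every dose (planned, and later predicted) is
   multiplied by `0.95 * P / D95%(PTV)` so that 95% of the PTV receives 95%
   of the prescription.  This removes target-coverage outliers as a source
   of variance and anchors all comparisons to one coverage level; it is
   idempotent, and D95% always reads 71.06 Gy afterwards (at 74.8 Gy).
   The D95% estimator is the DVH module's interpolated quantile at 0.1 Gy
   bins — a single definition shared project-wide.
4. **Global normalisation**: training doses are divided by the cohort-wide
   maximum dose; the constant is stored and reused to denormalise
   predictions (never recomputed on test data).
5. **Channel assembly**: per slice, 7 channels in fixed order — CT
   (windowed linearly from [-200, 800] HU-equivalent into [0, 1]), rectum,
   bladder, femoral left/right, PTV, body.

At prediction time the network output is denormalised by the *training*
constant, clamped at zero (the network head is linear), and then
coverage-rescaled using the **predicted** PTV D95% — a pre-treatment
prediction has no planned dose to lean on, so the prediction itself must
satisfy the coverage goal of the optimisation protocol.  Rescaling by the
planned D95% instead is available behind a flag for sensitivity analysis.

## Dose-prediction model

A 2D U-net maps the 7-channel slice to a single-channel normalised dose
slice; slices are treated as independent training examples (a 2D model
stays trainable at small cohort sizes, at the cost of craniocaudal
continuity).

* **Architecture**: encoder-decoder with skip concatenations between
  matching resolutions.  Each resolution level holds a residual block
  (conv3x3-BN-ReLU-conv3x3-BN, identity added, ReLU) followed by one
  dropout layer (rate 0.1) — dropout after every two batch-normalisation
  layers.  Downsampling is a 2x2 stride-2 convolution doubling features;
  upsampling is nearest-neighbour followed by a 3x3 convolution halving
  them (chosen over transposed convolution to avoid checkerboard
  artefacts), then a 3x3 fuse convolution merges the skip.  `same` padding
  throughout, so output size equals input size.  Feature widths are
  `base * 2^level`, with `base` and `depth` config-exposed.
* **Training**: mean squared error between planned and predicted normalised
  doses; Adam with learning rate 1e-3, beta1 0.9, beta2 0.999, weight decay
  0; mini-batch 15 slices; 5-fold cross-validation with folds split over
  *samples* (no patient's slices leak across folds).  All randomness —
  initialisation, shuffling, dropout — derives from one seed, so runs are
  bit-reproducible.
* **Ensembling**: the final predictor is the voxelwise arithmetic mean of
  the five fold models' predictions.  Averaging *predictions*, not weights:
  parameter averaging across independently initialised networks is not
  meaningful.
* **Inference**: dropout off, batch-norm running statistics.

The layer stack (convolutions, batch norm, dropout, Adam) is implemented in
the package itself on NumPy, with the three convolution geometries (3x3
'same', 2x2 stride-2, 1x1) as compiled numba kernels and explicit backward
passes; gradients are verified against finite differences and brute-force
oracles in the test suite.  This keeps the model dependency-light, exactly
seeded, and fast enough to train on one CPU core.

### Desk-scale configuration

The configuration the test suite trains is deliberately small: 64 x 64
slices, base 4 features, depth 2 (~12k parameters), 30 epochs, 40 training
phantoms — a scaled-down analogue of a clinical 128 x 128 / 60-patient /
250-epoch run.  It is chosen so the full 5-fold cross-validation completes
in minutes on a single CPU core while still recovering the anatomy-to-risk
signal; the clinical-scale configuration remains expressible through the
same configs.  The compact network uses learning rate 2e-3 (the full-scale
protocol's 1e-3 under-converges it within 30 epochs, which surfaces as an
inflated coverage-rescale factor on predictions: a blurred PTV lowers the
predicted D95% and the rescale step then overheats the whole prediction,
biasing NTCP upward).  An optional cosine learning-rate decay is available
in `TrainConfig`.

## DVH and plan metrics

Cumulative DVHs are built from in-mask voxel doses at 0.1 Gy bins (fine
enough that interpolation error is far below the 0.01 Gy reporting
precision; NTCP values move by < 0.1 percentage points under bin halving,
which is asserted as a test rather than guessing an unstated bin width).
Conventions, fixed project-wide:

* `V_xGy` interpolates linearly between bin edges; `D_x%` inversely
  interpolates, resolving ties on flat segments to the **largest**
  qualifying dose ("minimum dose to the hottest x%").
* Structure volumes are voxel counts times the voxel volume of the
  structure's own grid.
* Rectal metrics and NTCP use the craniocaudally cropped rectum (PTV +/-
  1 cm) — that is the structure that gets contoured, and relative volumes
  `v_i` refer to it.
* R50% counts the half-prescription isodose over the whole grid intersected
  with the body mask (dose in air is not counted).
* The homogeneity index is `100 * (D2% - D98%) / D50%` for the PTV.

The standard report carries 23 DVH metrics (PTV D98/D95/D50/D2/Dmean/HI/
R50%; rectum and bladder V70/V60/V50/V40/D2/Dmean; femoral-head D2/Dmean)
plus 8 NTCP endpoints.

## NTCP models

Each DVH bin is first converted to its equivalent dose in 2-Gy fractions,
`EQD2 = D * (d + a/b) / (2 + a/b)` with per-bin fraction dose `d = D/34`
evaluated at the bin centre and `a/b = 3` Gy for late rectal endpoints.

**LKB**: `Deff = (sum_i v_i * EQD2_i^(1/n))^n`, a generalised power mean
(evaluated in log-space so serial organs with `1/n > 5` cannot overflow),
then `NTCP = Phi((Deff - TD50) / (m * TD50))` with the normal CDF computed
via the double-precision error function (reported precision is 0.01%, so no
lookup table).  `n` is the volume effect (small = serial, hottest
subvolume dominates), `m` the slope, `TD50` the 50%-complication tolerance
dose.

**Relative seriality**: per-bin Poisson response
`P(D) = 2^(-exp(e^gamma (1 - D/D50)))` combined as
`NTCP = (1 - prod_i (1 - P_i^s)^{v_i})^{1/s}` with seriality `s`.

The endpoint registry ships as versioned YAML: seven LKB endpoints (grade
>= 1 and >= 2 late rectal bleeding, stool frequency, bowel pain, sphincter
control, stricture/ulcer) and one relative-seriality grade >= 2 bleeding
endpoint.  It is immutable at runtime; public outputs are percentages,
internal math fractions.  Fitting NTCP parameters to outcome data is out of
scope.

## Evaluation

* **iDSC(d)**: Dice overlap `2|A n B| / (|A| + |B|)` of the planned and
  predicted iso-dose volumes at level `d`, evaluated inside the body mask.
  (The set-union form sometimes typeset for this coefficient would exceed 1
  for identical sets; the name and its [0, 1] range force the Dice
  denominator.)  When both volumes are empty — levels above both maxima —
  the value is defined as 1: the plans agree the isodose is absent, which
  keeps the mean well-defined near the prescription level.  Mean iDSC is
  averaged over levels from 0 (or 50) Gy to the prescription in 1 Gy steps.
* **%MAE**: for Gy-valued metrics, `100 * |pred - plan| / prescription`
  averaged over samples; for %-valued metrics (V_xGy, NTCP), the mean
  absolute difference in percentage points.  Predicted values enter after
  coverage rescaling, like the planned ones.
* **Goodness of fit**: ordinary least squares of predicted on planned with
  `R^2` and a two-sided Wald t-test on the slope.  Constant predictions
  (zero variance) are reported as R^2 = 0, p = 1 rather than NaN.
* **Power**: for a target R^2 with effect size `f^2 = R^2/(1 - R^2)`, the
  power of the slope test is provided in two labelled conventions — the
  large-sample normal approximation `Phi(sqrt(n f^2) - z_{1-a/2})` (the
  default) and the exact noncentral-F computation (df 1 and n-2,
  noncentrality `n f^2`) — because design statements in the literature do
  not always name theirs.  At n = 15, R^2 = 0.35, alpha = 0.05 the normal
  convention gives 0.81.

## Numerical and reproducibility notes

* Training math is float32 (model weights, activations); analysis math
  (DVH, NTCP, statistics) is float64.
* Every source of randomness flows from `numpy.random.SeedSequence` spawns
  of one master seed: phantom cohorts, fold splits, weight initialisation,
  batch shuffling, dropout masks.  Same seed, same bytes.
* Degenerate inputs are rejected loudly rather than coerced: empty masks
  have no DVH, zero dose on the PTV has no coverage rescale, cohorts
  smaller than the fold count cannot be cross-validated.
* The generalised-mean limit `n -> 0` approaches `max * v_max^n`, not the
  bare maximum; tests assert the exact limit.

## Known limitations

* 2D slice independence: no craniocaudal continuity in predictions (visible
  as slice-to-slice wobble), accepted for trainability at small n.
* The phantom's single sparing mechanism means the network's task is easier
  than clinical planning; phantom results bound feasibility, not clinical
  accuracy.
* NTCP parameters are literature values for conventionally fractionated
  external beam; applying them to other schedules or endpoints requires
  recalibration, which is explicitly out of scope.
* The desk-scale network is far smaller than clinical-scale dose
  predictors; its absolute dosimetric accuracy (iDSC, per-metric %MAE) is
  correspondingly lower than published clinical models, and only the
  anatomy-to-risk recovery claim is asserted by the acceptance suite.
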