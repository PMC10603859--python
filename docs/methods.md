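# Methods

`caroseg` implements a complete desk-scale analysis workflow for 3D carotid
ultrasound (3DUS) vessel-wall assessment: manual-segmentation
reproducibility analysis at varying inter-slice distance (ISD), vessel-wall
volume (VWV) and vessel-wall-plus-plaque thickness (VWT) quantification, a
two-channel U-Net trained with an adaptive triple Dice loss (ATDL), and a
comparison of two train/test partition schemes for serial (baseline/
follow-up) imaging. Because no patient data ship with the package, every
experiment runs on synthetic carotid phantoms with known ground truth; this
note records the models, the numerical choices, and what the synthetic
results do and do not establish.

## Coordinates and containers

All geometry lives in physical millimetres. A `Volume3DUS` stores an axial
image stack with anisotropic voxel spacing (default 0.21 x 0.21 x 0.35 mm);
slice index k maps to z = z0 + k*Vz, with z increasing from the proximal
common carotid artery (CCA) toward the distal internal carotid artery
(ICA). A `Contour` is a closed, simple, counter-clockwise polygon on an
axial plane, classified as media-adventitia boundary (MAB) or lumen-intima
boundary (LIB); a `ContourStack` holds per-slice (MAB, LIB) pairs anchored
at a bifurcation position with a fixed ISD, covering 15 mm of CCA proximal
to the bifurcation and 10 mm of ICA distal to it. The LIB is inside the MAB
on every slice; the stack constructor validates this.

## Shape-based inter-slice interpolation

Boundaries segmented at different anchors or ISDs are compared on common
axial slices. Contours are interpolated between adjacent slices as the zero
level set of a linear blend of their signed distance fields (SDFs):
`(1-t)*SDF(prox) + t*SDF(dist)`. The SDF is computed from two Euclidean
distance transforms of the rasterized polygon on a 0.05 mm grid (bounds =
joint bounding box padded by 2 mm), and the level set is extracted by
marching squares with linear sub-cell interpolation, keeping the largest
closed component if several appear. The 0.05 mm grid is at least four times
finer than the finest voxel dimension, so discretization error sits an
order of magnitude below the boundary distances of interest (~0.5-1 mm);
the concentric-circle test verifies the interpolated radius is linear in t
to within one grid step. This linear-SDF-blend construction is the
package's own stand-in for classical shape-based interpolation; it
reproduces endpoints exactly (within one grid step) by construction.
Study-scale code may pass a coarser 0.1 mm SDF grid; the convergence test
shows VWV changes by <0.2% when the reslicing step is halved, and the same
check bounds the grid effect well below the 1% tolerances used throughout.

## Reproducibility metrics

Per common slice (the common grid is the multiples of Vz inside the overlap
of the two stacks), two boundaries are compared with the Dice similarity
coefficient, DSC = 2|M1 n M2| / (|M1| + |M2|) with areas from exact polygon
clipping, and the in-plane Hausdorff distance, the max over the two
directed distances where each directed distance takes a dense (0.05 mm arc
step) resampling of one boundary against the other polygon's segments.
Rasterization-based DSC is kept as a brute-force oracle in the tests; dense
resampling for HD was chosen over vertex-set HD because stored vertex
counts are arbitrary. Bifurcation-localization reproducibility is the
absolute longitudinal distance between the anchors of two trials.
Stratified tables report mean/SD of DSC and HD over {CCA, ICA, BF,
CCA w/o BF, Overall} x {MAB, LIB}, where BF is the single CCA slice nearest
the bifurcation per volume; pooling is across slices (not volumes), so
slice counts set the sample size.

## VWV and VWT

The volume enclosed by one boundary surface is computed by reslicing the
stack to a 0.1 mm step with the shape-based interpolation and integrating
the cross-sectional polygon areas along z with the trapezoid rule, CCA and
ICA segments separately (the bifurcation must not contribute a cross-branch
trapezoid). VWV = enclosed MAB volume - enclosed LIB volume. This
reslice-and-integrate scheme replaces a mesh-based surface reconstruction;
the analytic-cylinder test (120 pi mm^3 within 1%) and the step-halving
convergence test bound its error.

Point-wise VWT uses an order-preserving correspondence: MAB and LIB are
resampled to n points (default 100) by normalized arc length from a common
anchor (the boundary crossing of the +x ray from the MAB centroid), and the
LIB parameterization is cyclically shifted to minimize the total pair
distance. Pair distances are the VWT samples. The 2D L-shaped map places
one row per longitudinal position (1 mm row step; CCA rows proximal to
distal, then ICA rows) and one column per circumferential bin; ICA rows
occupy a leading column block scaled by the ICA/CCA mean perimeter ratio,
remaining cells missing. Two maps are compared cell-wise over jointly
non-missing cells with identical (row, theta) indexing. The anchor
direction and the column allocation are package choices; both are
configurable and their effect cancels in paired comparisons of maps built
with the same convention.

## Statistics

Paired comparisons use a Shapiro-Wilk gate at alpha = 0.05 applied to the
paired differences (the quantity whose normality the paired t-test actually
assumes): normal -> paired t-test, otherwise Wilcoxon signed-rank (exact
sign-permutation null for n <= 25). Agreement uses ICC(A,1), the two-way
mixed-model single-measure intraclass correlation with absolute agreement,
computed from the ANOVA mean squares

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)),

with the F-based two-sided 95% confidence interval (Satterthwaite
denominator degrees of freedom); the implementation is cross-checked
against pingouin's ICC(A,1) in the tests. Bland-Altman analysis reports
bias = mean difference, the repeatability coefficient RPC = 1.96 x SD of
the differences, limits of agreement bias +/- RPC, and the coefficient of
variation CV = 100 x SD of differences / mean of the pairwise averages.
Delta summaries report mean/SD of (auto - manual) and of its absolute
value. No multiple-testing correction is applied; each comparison is judged
at p < 0.05. For VWT, the unit of analysis for ICC/correlation is the
per-cell map value pooled across volumes, since each map carries hundreds
of local measurements.

## Synthetic phantoms

A `CarotidGeometry` is analytic: a gently wobbling CCA centerline splits at
the bifurcation into an ICA and a smaller ECA (rendered as a distractor
only — it has no ground-truth contours, mimicking the ambiguity that makes
distal slices hard). Radii are smooth in (z, theta): baseline MAB radius is
lognormal around 3.5 mm (sigma_log = 0.10), the LIB/MAB ratio uniform in
[0.60, 0.75], ICA caliber 0.8x and ECA 0.55x the CCA, with a mild linear
taper. Plaques are raised-cosine (C1) bumps that reduce the LIB radius
only — wall thickening into the lumen — with thickness 0.5-1.5 mm,
longitudinal extent 2.5-8 mm (short plaques deliberately occur, since short
plaques are a known driver of segmentation variability at coarse ISD), and
angular extent pi/3 to pi. A follow-up geometry is progression-only:
existing plaques grow by up to 25% and a new small plaque appears with
probability 0.35, both scaled by a `progression_noise` factor whose zero
value yields an exact-copy follow-up (used by the partition experiment's
directional check).

Rendering assigns tissue-class means (lumen 0.08, wall 0.75, background
0.45 in arbitrary units), multiplies by gamma speckle (shape 4, mean 1) and
applies a 0.25 mm Gaussian blur. Difficulty cases are optional: hypoechoic
plaques darken the wall locally; calcified plaques cast an intensity-
dropout cone away from the transducer. The renderer is a texture phantom,
not a physical ultrasound simulator: no beamforming, refraction, or
depth-dependent point-spread function. Consequently, passing segmentation
tests show the pipeline and the training machinery work end to end on
speckle-like images with the right geometry and contrast polarity; they do
not certify accuracy on clinical images.

The virtual observer emulates repeated manual segmentation: the bifurcation
anchor is jittered by a zero-mean Gaussian whose SD grows with ISD (defaults
0.2 / 0.3 / 0.6 mm at ISD 1 / 2 / 3 mm — configurable shape parameters, not
estimates of any real observer), rounded to the voxel slice grid; each
contour's radius function is perturbed by a truncated Fourier series
(harmonics <= 6, i.i.d. Gaussian coefficients, pointwise SD 0.15 mm by
default) so perturbations look like plausible tracing variation rather than
pixel jitter; the LIB is clipped inside the MAB. No claim is made that
these parameters reproduce any particular observer's variability; they
exist so the reproducibility harness has realistic, monotone-in-ISD
behaviour to measure.

## Segmentation network and ATDL

The network is a 2D U-Net: per level two 3x3 stride-1 convolutions each
followed by batch normalization and ReLU; 2x2 max-pooling for descent; 2x2
stride-2 transposed convolutions for ascent with skip concatenation; a 1x1
convolution head with two independent sigmoids (not softmax — the lumen is
inside both boundaries, so the two channel probabilities must be free to
overlap) giving per-pixel MAB and LIB probabilities. Full width is 64
encoder channels at the top level with depth 4; a width multiplier and
depth knob scale the model for CPU-scale runs. Inputs are resampled to
192 x 256 and min-max normalized to [0, 1].

Because the execution environment provides no deep-learning framework, the
layers, backpropagation, and the Adam optimizer are implemented directly on
numpy (im2col/GEMM convolutions with a numba-compiled gather); gradients
are verified against central differences in the tests, and training is
reproducible from the seed.

The loss is the adaptive triple Dice loss
L = a*L_MAB + b*L_LIB + c*L_CVW, where L_DSC(y, yhat) =
1 - 2*sum(y*yhat)/(sum(y) + sum(yhat) + 1e-6), CVW (the carotid vessel
wall) has label y_MAB - y_LIB and prediction clip(yhat_MAB - yhat_LIB, 0, 1),
and (a, b, c) are nonnegative with a + b + c = 1 always. Training has two
phases: phase 1 uses uniform weights (1/3 each) to let the network localize
the vessel; the component losses are exponentially smoothed (decay 0.9),
and once the smoothed MAB and LIB losses both fall below the CVW loss —
checked only after a 20-step burn-in so the smoother is meaningful — or
after a warmup (default 2 epochs), whichever comes first, phase 2 sets the
weights proportional to the smoothed losses with a per-weight floor of
0.05, renormalized to sum to one. The proportional rule directs weight at
whichever component currently lags; the floor keeps every component in
play. The exact switch rule and phase-2 formula are package choices among
the family of "adjust the weights according to the loss values" schemes.
The output-layer bias is initialized to -2 (a background prior) so the Dice
losses see informative gradients from the first steps.

Optimizer settings (Adam, lr 2e-3, batch 4-8) are package defaults, logged
in `TrainConfig` and overridable. Training data are truth slices optionally
resliced to 0.5 mm, with flip/translation (+/-10%)/rotation (+/-15 deg)
augmentation; labels are transformed with nearest-neighbour sampling so the
LIB-inside-MAB invariant survives every transform. Test-time augmentation
predicts on the original, horizontally flipped, and vertically flipped
image, un-flips, thresholds at 0.5, and takes a per-pixel majority vote.
ICA slices are masked by an axis-aligned box linearly interpolated between
two user-supplied end boxes (the workflow's manual interaction; phantoms
derive them from ground truth). Per slice, the largest connected component
per channel is kept, the boundary is extracted by marching squares with a
5-vertex circular moving average to suppress the half-pixel staircase
(vessel boundaries are smooth at that scale), and the LIB is clipped inside
the MAB. Slices with empty or degenerate predictions are flagged missing,
never fabricated.

## Experiments

The ISD study runs a virtual observer twice per volume at each ISD in
{1, 2, 3} mm and reports: bifurcation-distance summaries, pooled DSC/HD per
boundary x branch (branch "ALL" plus per-branch, since pooling granularity
is a reporting choice), normality-gated paired tests of per-slice DSC
between ISD pairs (slices paired by common (volume, z) on the Vz grid), and
ICC(A,1) of VWV (volumes x trials) and of pooled VWT map cells.

The partition study trains one model per scheme. Patient-based: half the
patients contribute baseline and follow-up volumes to training; the other
half's baselines validate and its follow-ups test. Time-based: all
baselines train; follow-ups split into validation (first half's) and test
(second half's). The test set is identical across schemes by construction.
The evaluation reports stratified DSC/HD against the manual-style
reference, paired tests of per-slice DSC between schemes on the common test
slices, and VWV/VWT agreement (delta summaries, Pearson r, Bland-Altman).
The follow-up validation/test split ratio (50/50 by seeded patient shuffle)
is a package choice.

## Problem sizes and numerical defaults

Desk-scale defaults, chosen once for single-CPU runs: the held-out accuracy
check trains a width-0.25, depth-3 U-Net on a 20-patient synthetic training
cohort (baseline volumes, ISD 2 mm slices, full 192 x 256 resolution) for
two epochs and evaluates per-slice DSC on held-out patients; the partition
comparison uses width 0.125, depth 3 on 4-patient cohorts across 3 seeds
with near-copy follow-up geometry, asserting the directional property
(time-based not worse than patient-based beyond 0.01 DSC) rather than any
particular effect size. The working resolution is a configuration knob
(the network is fully convolutional): the partition comparison and the
overfit sanity run use 96 x 128 to keep CPU runtimes short, while the
preprocessing contract and all accuracy-bearing checks keep the 192 x 256
default.
Study harnesses use a 0.1 mm SDF grid; definitional and analytic checks use
the 0.05 mm default. Degenerate inputs (constant images, zero-area
polygons, empty overlaps, constant paired differences) raise explicit
errors rather than returning sentinel values.

## Known limitations

- The phantom is a texture model; results do not transfer to clinical
  image quality claims (shadowing, reverberation, probe pressure, and
  reconstruction artifacts are absent or stylized).
- The correspondence stand-in (anchored arc-length resampling + cyclic
  alignment) is order-preserving but not the original symmetric
  correspondence construction; VWT values agree for smooth, near-convex
  walls but may differ around sharp concavities.
- The bifurcation and ICA boxes are treated as given inputs, as in the
  interactive workflow; their sensitivity is not modelled.
- In-plane Hausdorff distances are 2D per slice; no 3D surface distance is
  computed.
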