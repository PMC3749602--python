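# Methods

`otomedia` classifies otoendoscopic images of the tympanic membrane into
acute otitis media (AOM), otitis media with effusion (OME) and no effusion
(NOE) with an interpretable two-part design: a **vocabulary** of eight
engineered features that mirror the visual cues otoscopists report (bulging,
central concavity, light, malleus presence, translucency, amber level,
bubble presence, grayscale variance), and a **grammar** — a three-stage rule
tree over those features whose thresholds are learned by cross-validated
grid search. This note records the model, the numerical choices, and what
the synthetic phantoms do and do not establish.

## Preprocessing

**Segmentation.** A morphological geodesic active contour evolves on the
inverted-gradient edge map `g = 1/sqrt(1 + alpha*|grad G_sigma * I|)`
(`seg_edge_alpha = 300`, `seg_edge_sigma = 3`), initialised as a circle at
the image centre with radius 25% of `min(H, W)` and grown by a unit balloon
force. Evolution stops when the mask area changes by less than 0.1%
(relative) across a 10-iteration window, or at 200 iterations (the last
mask is returned with a non-convergence flag). Because the membrane is
convex in projection, the final outline is the convex hull of the converged
contour; this bridges bites where the contour pins on internal edges such
as a bulge rim. Masks below 1% of the frame raise an error. The
initialisation must start inside the membrane: strongly off-centre
membranes whose boundary crosses the initial circle let the balloon leak
into the smooth canal background — a known limitation, flagged through the
non-convergence warning.

**Specular highlights.** Otoscope reflections are saturated, so membrane
pixels with gray intensity above `specular_threshold = 0.90` (unit scale)
form the highlight mask; connected components use 8-connectivity.
Correction is gradient-domain editing with a zero guidance field: each
component of each channel is replaced by the discrete harmonic interpolant
of its 4-neighbour boundary values (sparse 5-point Laplace solve; stencil
degree reduced at the frame). There is no donor patch to clone in an
eardrum image, so pure membrane interpolation is the appropriate
specialisation. Pixels outside the highlight mask are untouched bit-exact.

**Rejection.** If the largest connected highlight component covers strictly
more than `reject_fraction = 0.15` of the membrane, boundary interpolation
cannot be trusted and the image is rejected before any feature is computed;
the denominator is the membrane-mask area (configurable to full frame).
"Largest component" implements the idea of one continuous overexposed
region, as opposed to many small reflections whose union is large but each
of which is fillable.

## The vocabulary

All means and variances are restricted to membrane-mask pixels. Intensity
features run on unit-interval gray (ITU-R 601 weights); colour distances
run on the 0-255 RGB scale where the distance threshold `T_t = 10` is
meaningful.

**Bulging `f_b`.** Depth is recovered from shading and thresholded at
`T_d = 0.6` after min-max normalisation; `f_b` is the fraction of membrane
pixels above threshold, with flat (degenerate) maps giving 0. Under the
coaxial illumination of an otoscope the Lambertian image
`E = 1/sqrt(1 + |grad z|^2)` inverts in closed form to a slope magnitude
`|grad z| = sqrt(1/E^2 - 1)`; the height field is the minimal slope
integral from the membrane rim, computed by an iterative upwind
(Rouy–Tourin) scheme run to convergence (at most `sfs_iterations = 300`
Jacobi passes). We first implemented the per-pixel Newton linearisation of
the reflectance map; under frontal light its denominator `dR/dz -> 0` on
flat surfaces, and after per-image normalisation, near-flat membranes
produced noise-dominated depth maps whose thresholded area was essentially
arbitrary. The upwind integration has no such degeneracy and recovers a
rendered hemisphere with rank correlation 0.98.

Robustness steps (all in `PipelineConfig`): Gaussian pre-smoothing
(`sigma = 1` px); albedo estimated as the 90th brightness percentile of the
membrane and divided out, so a dark but flat palette (translucent gray) is
not mistaken for slope; the 25th percentile of the slope field is
subtracted as the sensor-noise floor; the rim is eroded by 5 px because
smoothing bleeds the dark canal into boundary pixels, which would otherwise
fake a wall of slope around the whole membrane; and a grayscale opening
with a disk of radius 15 px (the concavity-core scale, R/4) removes narrow
peaks — the ascent-only integration renders concave pits as spikes, and a
structure narrower than the concavity core is not a bulge. A surface whose
total relief is below `sfs_relief_tol = 1` pixel of height is flat at
imaging resolution and is treated as degenerate (`f_b = 0`).

**Central concavity `f_c`.** For candidate centres on a 5-px grid inside
the central 151x151 window (candidates whose circular neighbourhood leaves
the frame are skipped) the radius-60 neighbourhood is resampled to polar
coordinates (360 angles, bilinear, angle measured from the row axis), and
for each core radius `R'` in `[R/4, 3R/4]` the ratio
mean(annulus)/mean(core) is formed (core means clamped at `eps = 1e-6`);
`f_c` is the maximum. Note the polar mean weights every ring equally, not
by pixel area — this matches the polar-grid definition and is what the
tests' analytic oracles reproduce. Ties keep the first candidate in
row-major order with the smallest core radius.

**Light `f_l`.** The gray image is histogram-equalised over membrane pixels
and thresholded at `light_threshold = 0.70` to a brightly-lit mask. For 180
angles over `[0, pi)` the membrane is split by the line through the
concavity centre; `f_l` is the maximal ratio of bright-pixel fractions
between the two sides (empty side: angle skipped; empty bright mask:
`f_l = 0`). The side convention is the half-plane
`(n - n_c) cos(theta) - (m - m_c) sin(theta) >= 0`, which agrees with the
`n >= tan(theta)(m - m_c) + n_c` form below `pi/2` and remains defined at
the vertical split. Since the dark-side fraction can be zero, the
eps-guarded ratio is unbounded; the threshold learner is quantile-based and
indifferent to the scale of such outliers. Global (not local/adaptive)
equalisation is used; the choice is not observable from flat fixtures and
is recorded here as a convention.

**Malleus presence `f_m`.** Moment-based ellipse fit of the mask; the image
is rotated so the major axis is horizontal; colours are quantised by mean
shift (bandwidth 16 in 0-255 RGB, modes fitted on a seeded subsample of at
most 2000 membrane pixels, all pixels assigned to the nearest mode); Canny
edges (`sigma = 1.4`, hysteresis 0.1/0.3) are taken inside a slightly
eroded mask; a straight-line Hough transform restricted to +/-50 rows
around the major axis and to orientations within 15 degrees of horizontal
votes for collinear edge pixels. `f_m = 1` iff a peak reaches 40% of the
major-axis length — enough collinear evidence to span a ridge. Smoothly
shaded membranes produce only curved quantisation boundaries whose
near-straight runs are far shorter.

**Translucency `f_t` and amber `f_a`.** A colour vocabulary is 10 k-means
centres (fixed seed) trained on 2000 pixels — 100 pixels from each of 20
images of the target appearance (translucent gray for NOE, amber for OME).
A membrane pixel belongs to the region when its minimal Euclidean RGB
distance to any centre is strictly below `T_t = 10` (amber threshold
defaults to the same value, as the amber assignment reuses the same
machinery); the feature is the labelled fraction. On phantoms the training
pixels are sampled from rendered membranes of the corresponding class with
stripe/bubble/highlight pixels excluded, emulating hand-picked clean
patches.

**Bubble presence `f_bp`.** Canny edges of the red and green channels are
united (computed inside a 3-px-eroded mask so the membrane outline does not
count), morphologically closed (disk radius 2) to bridge the parallel
boundaries Canny places on either side of a real edge, hole-filled, and
cleaned of components below 30 px; `f_bp` is the covered membrane fraction.
The feature responds to any closed contour — strongly shaded AOM membranes
score high — which is harmless in the grammar because AOM is decided at
Stage 1 before `f_bp` is consulted.

**Grayscale variance `f_v`.** Population variance of unit-interval gray
over the membrane; bounded by 0.25.

## The grammar

Stage 1 (AOM): `f_b > tau_b or f_l > tau_l or f_c > tau_c`, with `f_m = 1`
vetoing the candidacy (a visible malleus indicates a neutral or retracted
membrane; the veto is configurable). Within candidates, `f_a > tau_a`
diverts to OME — the partial-bulging escape for effusions that mimic a
bulge. Stage 2 (NOE, non-candidates): `f_t > tau_t`, or all OME cues low
(`f_a <= tau_a and f_bp <= tau_bp and f_v <= tau_v`). Stage 3: the
remainder is OME. The tree is total and single-valued; evaluation order is
strictly Stage 1 → 2 → 3, and the amber escape applies to every Stage-1
candidate rather than only to the low-light/low-concavity subset — both
readings are expressible, this one is the default.

**Threshold learning.** The training data are split 70/30 (stratified,
seeded) into learning and validation sets. Thresholds are tuned greedily in
tree order (`tau_b, tau_l, tau_c, tau_a, tau_t, tau_bp, tau_v`), each by
grid search over the empirical deciles of its feature on the learning
split, refined once with an 11-point uniform grid between the deciles
flanking the best cell; the criterion is misclassification on the
validation split, with untuned thresholds held at learning-split medians
and the whole sequence swept twice so late thresholds can inform early
ones. Ties are resolved to the **median element of the minimising
plateau**: the plateau's edges sit on the boundary of a class's observed
support, and a threshold there misfires on fresh draws, whereas the plateau
centre preserves margin on both sides. Everything is deterministic given
the seed.

**Nested cross-validation.** Stratified 5-fold outer loop; each training
fold runs the learning/validation split internally; learned thresholds are
applied once to the outer test fold and the confusion matrix is aggregated.
If `k_folds` exceeds the smallest class count (leave-one-out regimes) the
folds fall back to unstratified k-fold with a warning.

## Synthetic phantoms

Phantoms are elliptical membranes (horizontal major axis, axis ratio 0.85,
radius ~37% of the frame, default frame 256x256) on a vignetted dark-brown
canal background. Class archetypes quantify the clinical colour words as
RGB anchors — AOM pale-yellow (235, 220, 180), OME amber (200, 150, 60),
NOE translucent gray (128, 128, 128) — with per-draw jitter; AOM adds a
Lambertian-shaded spherical-cap bulge (random radius fraction 0.55-0.7,
centre offset 15% of the membrane radius, so illumination is laterally
asymmetric) and a darkened central concavity core; OME adds 1-3 darker
bubble rings; NOE adds a bright straight malleus ridge. Difficulty levels
scale palette jitter (3/8/16 gray levels), noise (2/4/8 of 255), bulge
amplitude overlap and cue dropout; "separable" keeps class-conditional cue
distributions disjoint. Every phantom exports its membrane mask, analytic
height field, stripe/bubble/highlight masks and cue flags.

What the phantoms do not emulate: real membrane texture and vascularity,
device-dependent colour response, off-axis illumination, partial occlusion
by wax or hair, and pose variation. Passing tests therefore establish that
each stage implements its definition and behaves correctly on geometry it
can verify — not clinical accuracy; the published clinical image set is not
deposited, so headline clinical accuracies are out of reach by design.

## Problem sizes in the test suite

The suite sizes simulations so each check is informative but bounded: 90
separable phantoms (30/class) for nested-CV parameter recovery, 50 phantoms
for segmentation Dice, 200 seeded archetype triplets for the feature
orderings, all 2x2 tables with total at most 20 for the Fisher-enumeration
equivalence, and 3 matched seed pairs of 18 phantoms at frame 192 (search
stride 10) for the separable-vs-hard difficulty ordering.

## Known limitations

* Depth from shading assumes a single albedo after percentile
  normalisation; multi-coloured membranes violate this and bias slopes at
  colour boundaries.
* The eikonal integration is monotone from the rim and represents
  depressions only through the opening step; depth inside a true concavity
  is not quantitatively meaningful.
* The light ratio is unbounded when one half-plane has no bright pixels
  (eps-guarded); thresholds on it should be learned, not hand-set.
* Segmentation requires the initial circle to start inside the membrane.
* The Fisher helper follows the standard two-sided convention (sum of
  tables no more probable than observed); published p-values computed under
  other conventions will differ.
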