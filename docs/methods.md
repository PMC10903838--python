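# Methods

## Coordinate and unit conventions

All arrays follow a fixed patient-anatomy convention: array axis 0 (+x)
runs patient right→left, axis 1 (+y) anterior→posterior, axis 2 (+z)
inferior→superior, with the physical position of voxel (i, j, k) equal to
`origin + (i, j, k) · spacing` (0-based, millimetres). NIfTI affines are
reduced to this convention on read; acquisitions whose direction cosines
are further than 1e-3 from axis-aligned after permutation are rejected
rather than resliced, so registration semantics stay unambiguous. All
internal quantities are mm and mL; centimetres appear only in the
movement report. Volumes are stored as float32 (bit-exact file round
trips); attenuation-scaled intermediates are float64 so scaling is exactly
invertible.

## Preprocessing

Both scans are resampled to a `cube_side`³ grid (default 192) by linear
(volumes) or nearest (labels) interpolation. The physical extent per axis
is preserved, so output spacing is `extent / cube_side` and may be
anisotropic; this extent-preserving resize was chosen over an
isotropic-spacing crop/pad because the analysis resizes whole scans to a
cube. Attenuation is clipped to (−1024, 600) HU before division by 3000:
the clip bounds the interpolation overshoot of sharp-kernel
reconstructions while covering all lung-window content, and the divisor
puts intensities on an O(1) scale so demons image gradients are
well-conditioned. Resizing happens before scaling; for these linear
operations the order is immaterial up to rounding. Tests run at cube sides
40–96 for speed; 192 is the documented production default.

## Lung segmentation

The segmenter is deliberately classical and fully deterministic:
binarize below −320 HU, remove components touching the x/y grid border
(exterior air), drop components under 100 mL, close with a 3 mm ball,
then split right/left by component centroids (or at the minimum of the
sagittal occupancy profile when the lungs fuse). It is the stand-in for a
trained segmentation network: it needs no model download and is exact on
phantom anatomy, but it will under-segment consolidated or fibrotic lung
(attenuation above the threshold), exactly as thresholding does on real
ILD. Lobar masks on real data must therefore come from an external
segmenter; external maps are validated by requiring ≥95% Dice agreement
of their lung extent with the internal lung mask, then adopted verbatim.
On phantoms, lobes can instead be resolved from the generator's geometric
fissure planes. A static plane cannot follow a deformed fissure, so
plane-resplit *prone* lobar volumes are biased when the deformation is
large; per-scan material labels (the generator's, or an external
segmenter's) are the reference for lobar volumetry. Segmentation QC fails
a mask whose whole-lung volume leaves [1000, 9000] mL (physiologic
total-lung-capacity bounds), whose expected lobes are empty, or whose
left/right volume ratio leaves [0.2, 5].

## Shear-free affine registration

The prone whole-lung mask is registered onto the supine mask with
translation + rotation + per-axis scale and no shear, honouring that this
stage only removes centring/pose differences; intensity is ignored.
Initialization is closed-form: translation from mask centroids, rotation
from the principal axes of the second-moment tensors with the 180°
eigenvector ambiguity resolved toward the identity (valid because inputs
are already in patient-anatomy coordinates), scale from the cube root of
the mask-volume ratio (isotropic by default; anisotropic is available but
initialized isotropically). Refinement is a gradient-free compass/pattern
search over the 9 (or 7 isotropic) parameters on the mean-squared
mismatch of Gaussian-softened masks, run on masks downsampled to ≤48
voxels per axis for speed; steps start at 2 mm / 1° / 0.01 and halve on
failed sweeps until 1e-3, with at most 200 sweeps. Refinement is
guaranteed never to reduce the full-resolution mask Dice: if it would,
the initialization is returned. The transform class is exactly closed
under inversion/composition only for isotropic scale; the general case is
re-decomposed by polar decomposition with a residual check. Post-affine
whole-lung Dice < 0.80 marks the subject a registration failure — a
recorded QC state, so cohort runs continue.

## Demons deformable registration

The displacement map is estimated by the classic additive demons loop
over a coarse-to-fine pyramid (3 levels, ×2 downsampling). Per iteration
the update at each voxel is

    du = (f − m∘φ) · ∇(m∘φ) / (‖∇(m∘φ)‖² + (m∘φ − f)² / κ)

with κ the squared mean voxel spacing, capped at 2 mm, smoothed with a
Gaussian of 2 mm (fluid-like), added to the field, which is then smoothed
with 3 mm (elastic-like). Numerical choices: smoothing sigmas are
physical but floored at one voxel per pyramid level (coarse levels would
otherwise be effectively unregularized and can random-walk on noise);
each level stops at its iteration cap (100/60/30 coarse→fine), on a
relative MSE change below 1e-4, or when an update fails to decrease the
MSE, in which case that update is reverted — the per-level MSE trace is
therefore strictly decreasing by construction. The field lives on the
fixed (supine) grid and maps supine points into affine-registered-prone
space. Registration uses the 1/3000-scaled volumes. The demons stage is
an algorithmic stand-in for a learning-based registration tool;
externally computed fields can be imported from 4D NIfTI (mm, or voxel
units converted through the spacing) and used everywhere a demons field
is.

Known behaviour: because the phantom lung interior is homogeneous, the
intensity-driven field is informed mainly at boundaries and interfaces and
the regularizer interpolates inside; recovered movement maxima therefore
understate the true peak displacement (roughly 60–70% on phantoms), and
the mask-driven affine absorbs part of the bulk displacement first. Rank
orderings — more damping ⇒ less recovered movement, larger amplitude ⇒
more recovered movement — are preserved, which is what the cohort-level
comparisons use.

## Quantification

Regional volumes are voxel count × voxel volume, reported in mL for
whole/right/left and the five lobes, with additivity enforced to 0.5%.
Volume change is prone − supine measured on each position's own
(resampled, pre-registration) masks: the affine stage includes scaling,
which would distort volumes measured after alignment. Volumes are
computed on the resampled cube grid and thus inherit its spacing;
lobar volumes require all five lobes in both maps. Movement statistics
are percentiles (default 100 = strict maximum, matching a
"maximum pixel movement" reading; configurable because the pure max is
noise-sensitive) of the absolute x/y/z components and of the Euclidean
magnitude over the supine whole-lung mask, in cm. Dice is 2|A∩B|/(|A|+|B|)
with the two-empty-masks case defined as 1.0.

## Synthetic phantom

The phantom emulates the study conditions, not CT realism: a body
ellipsoid (+40 HU) in air, two ellipsoidal lungs (−850 HU, together
~1.9 L), five lobes cut by an oblique plane per lung plus the right
horizontal fissure, Gaussian noise (20 HU) added after warping so the two
scans share no noise. Fibrosis (−300 HU) fills the requested fraction of
lung voxels chosen dorsal-basal subpleural first (scored by posterior
position, basal position and pleural proximity), mirroring the usual
distribution of fibrotic ILD.

The prone scan is the supine anatomy pushed forward by a smooth
displacement field and observed through a residual pose — a modest
shear-free affine (defaults drawn uniformly within ±10 mm, ±8°, scale
0.97–1.03) rather than a 180° scanner flip, since patient-anatomy
coordinates already absorb the flip. The field is a sum of Gaussian
displacement bumps centred dorsal-caudally in each lung plus a radial
expansion component centred on each lower lobe. The expansion scale is
solved by secant iteration on the Jacobian-integral volume gain of the
lower lobes until it matches `lower_lobe_expansion_ml` (default 80 mL)
within 1%, and the bump scale is then solved by bisection so the peak
field magnitude equals `deformation_amplitude_mm` (default 15 mm);
amplitude 0 disables the field entirely. Damping multiplies the field by
(1 − damping) exactly at fibrotic voxels, ramping linearly back to 1 over
max(12 mm, 2·damping·amplitude) outside the fibrotic region — a hard step
would fold the deformation; the generator verifies the discrete Jacobian
determinant stays positive in the lung and rejects folding specs. Prone
voxels are sampled by fixed-point inversion of the field composed with
the pose, so label maps are material (they follow the tissue). All
randomness uses numpy's PCG64 generator seeded from the spec; identical
specs give bit-identical phantoms on any platform.

Deliberate simplifications and their consequences: the lungs carry no
airways, vessels or texture, so intensity-driven registration is easier
at boundaries and harder in the interior than on real CT; the movement
bumps have non-zero divergence outside the lower lobes, so the whole lung
also gains volume (as it does physiologically at full inspiration in the
prone study setting); the pose's isotropic scale emulates inspiration
differences and rescales all volumes by scale³ — phantoms built for
volumetric validation therefore fix scale = 1, because a position change
does not rescale the patient. Passing tests on phantoms demonstrate the
pipeline's correctness and its sensitivity to the encoded effects; they
do not certify accuracy on real fibrotic CT.

The cohort generator draws fibrosis extent from a discrete distribution
over {0, 10, …, 70}% with weights (12, 7, 20, 21, 12, 19, 13, 3) — the
visual-score distribution typical of an ILD cohort — then couples
deformation amplitude negatively to fibrosis (20 mm − 0.15 mm/% + N(0,2),
floored at 2 mm), FVC positively to amplitude (1.5 L + 0.08 L/mm +
N(0,0.3)), and the lower-lobe volume target proportionally to amplitude
(80 mL at 15 mm). Pattern groups are assigned by extent (0% → normal,
≥40% → UIP or probable UIP, otherwise indeterminate/alternative).

## Statistics

Paired t (dof n−1, 95% CI from the t quantile), Welch's unequal-variance
t with Welch–Satterthwaite dof (chosen over pooled Student as the safer
default for an unspecified "independent t-test"), classical one-way
ANOVA for three-level groupings (the three-group comparison needs *some*
omnibus test; ANOVA is our documented choice), and tie-corrected
(average-rank) Spearman with the t-approximation P and a Fisher-z CI.
Computation is delegated to scipy.stats; the test suite checks every
routine against independent textbook-formula implementations to 1e-10.
A subject with exactly 30% fibrosis falls in the severe group. P values
are reported raw — no multiple-testing correction, a documented
limitation — with an optional Holm adjustment helper. Missing FVC is
dropped pairwise in correlations. Zero-variance inputs raise a
degenerate-input error rather than returning p = 0; the table builder
converts this into a flagged row.

## Visualisation

The HSV movement map encodes, per lung voxel of a chosen slice,
H = min(|dx|/dmax, 1), S = min(|dy|/dmax, 1), V = min(|dz|/dmax, 1) with
dmax = 30 mm by default (comfortably above typical maximum movements, so
the scale rarely saturates); non-lung voxels show the anatomical
background in greyscale. This particular normalization is our documented
mapping — signed-direction encodings are out of scope. Quiver maps show
the in-plane components at a configurable stride with a 10 mm reference
arrow. Rendering is deterministic; identical inputs produce byte-identical
PNGs.

## Problem sizes used in the shipped validation

Phantom validation runs use 96³ grids at 3 mm spacing for the
registration-quality and volumetry checks (matching the production cube
in voxel count), 64³ at 4.5 mm for affine/deformable recovery and the
damping comparison, and a 50-subject cohort at 48³ at 6 mm for the
covariate-coupling check — the same 288 mm physical extent throughout, so
anatomy and field parameters are unchanged and only voxel size varies.

## Known limitations

* The segmenter and demons stages are classical stand-ins for the trained
  networks used in practice; interface compatibility (masks in, fields
  out/in) is the design goal, not numerical equivalence.
* Lobar volumetry via fissure planes is only valid per scan; on real data
  use external lobar masks.
* Recovered movement maxima are regularization-biased low; comparisons
  across groups are meaningful, absolute magnitudes are conservative.
* Attenuation-change (aeration) analysis is out of scope.
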