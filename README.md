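# pronelung

Registration-driven analysis of how lung parenchyma changes volume and
moves when a patient turns from supine to prone on CT.

Prone positioning redistributes aeration toward the dorsal lung and is used
clinically in hypoxic patients, but patients with fibrotic interstitial
lung disease (ILD) — whose fibrosis sits subpleural and basal, exactly in
the dorsal lung — may benefit less. `pronelung` quantifies this on paired
supine/prone thoracic CT:

1. **Preprocess** — both scans are resampled to a fixed cubic grid
   (192×192×192 by default, physical extent preserved) and CT attenuation
   is clipped to a lung window and scaled by 1/3000 so registration works
   on O(1) intensities.
2. **Segment** — whole-lung masks from a deterministic threshold/morphology
   segmenter (labels: 1 RUL, 2 RML, 3 RLL, 4 LUL, 5 LLL; 1/4 for
   unresolved right/left). Lobar masks from any external segmenter are
   accepted as first-class input and validated against the lung mask.
3. **Affine registration** — the prone whole-lung mask is aligned onto the
   supine mask with translation, rotation and scaling only (no shearing):
   closed-form moments initialization plus a pattern-search refinement.
   A whole-lung Dice below 0.80 flags the subject as a registration
   failure (a QC state, not an error).
4. **Deformable registration** — a multi-resolution Gaussian-regularized
   demons algorithm produces the dense spatial displacement map u(x) (mm)
   on the supine grid, with `moving(x + u(x)) ≈ fixed(x)`. Externally
   computed fields (e.g. from a learning-based tool) can be imported from
   4D NIfTI instead.
5. **Quantify** — lobar/whole-lung volumes and prone-minus-supine changes
   (measured on each scan's own masks, before any registration), per-axis
   and 3D Euclidean movement maxima over the lung (reported in cm),
   whole/right/left Dice after full registration, HSV and quiver movement
   maps.
6. **Cohort statistics** — paired t (position volume change), Welch t
   (<30% vs ≥30% fibrosis), one-way ANOVA (three-level groupings) and
   tie-corrected Spearman correlations (FVC, fibrosis extent).

Because real paired scans are rarely shareable, the package ships a
**synthetic phantom generator**: five-lobe ellipsoidal lungs in CT
attenuation units, a residual prone pose (translation/rotation/scale), a
smooth dorsal-caudal expansion field with a known peak amplitude and a
known lower-lobe volume gain, and fibrosis-like regions that locally damp
the deformation. Every phantom carries its ground truth (pose, field,
labels, fissure planes), so segmentation, registration and volumetry can
be validated end to end.

## Worked example

```python
from pronelung import (AnalysisConfig, PhantomSpec, PoseParams, PreprocessConfig,
                       analyze_subject, generate_phantom_pair)

pose = PoseParams(translation_mm=(6, -4, 3), rotation_deg=(4, -3, 5), scale=1.0)
pair = generate_phantom_pair(PhantomSpec(seed=1, pose=pose))  # 96³, 3 mm voxels
cfg = AnalysisConfig(preprocess=PreprocessConfig(cube_side=96))
res = analyze_subject("demo", pair.supine_vol, pair.prone_vol, cfg,
                      supine_labels=pair.supine_labels,
                      prone_labels=pair.prone_labels)
```

This prints (via `res.to_dict()`), with the default 15 mm deformation
amplitude and 80 mL lower-lobe expansion target:

```
qc_passed    True
affine_dice  0.973      # whole-lung Dice after the shear-free affine
dice_whole   0.9795     # after affine + demons (right 0.9805, left 0.9785)
movement     x 0.28  y 0.22  z 0.23  3D 0.29 cm   (maximum over lung voxels)
RLL delta   +40.3 mL    LLL delta +37.6 mL        (prone − supine)
```

The recovered lower-lobe gain (40.3 + 37.6 = 77.9 mL) matches the 80 mL
built into the phantom to within 3%; the Dice ≈ 0.98 says the two
positions are brought into near-perfect overlap; the movement maxima are
the demons estimate of how far lung tissue travelled (they understate the
true 15 mm peak because the mask-driven affine absorbs part of the bulk
displacement and the regularized field is smooth).

## Command line

```bash
pronelung simulate --out cohort/ --n 5 --seed 1          # phantom cohort
pronelung preprocess --in ct.nii.gz --out ct192.nii.gz --cube 192
pronelung segment --in ct192.nii.gz --out mask.nii.gz
pronelung register-affine --fixed-mask sup.nii.gz --moving-mask pro.nii.gz \
    --out-transform T.json
pronelung register-deformable --fixed sup.nii.gz --moving pro.nii.gz \
    --transform T.json --out-field field.nii.gz
pronelung analyze --supine sup.nii.gz --prone pro.nii.gz --out result.json
pronelung viz --field field.nii.gz --mask mask.nii.gz --axis y --out hsv.png
pronelung run --config run.yaml                          # whole cohort
pronelung run --fixture --output-dir out/                # 48³ smoke run
```

File formats: NIfTI-1 (`.nii`/`.nii.gz`) for volumes and label maps
(in-memory convention: +x right→left, +y anterior→posterior, +z
inferior→superior; oblique acquisitions are rejected — reslice upstream),
4D NIfTI + JSON sidecar for displacement fields (mm), UTF-8 CSV with
columns `subject_id,fibrosis_extent,pattern_group,fvc_l` for subject
metadata. DICOM is out of scope; convert to NIfTI first.

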