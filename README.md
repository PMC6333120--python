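# atlas-sct

Multi-atlas synthetic CT (sCT) generation from Dixon water/fat MR images for
MR-only radiotherapy planning of the pelvis.

The pipeline conditions CT and MR volumes into a shared intensity frame,
builds a co-registered CT-MR atlas, propagates it onto a new subject's MR,
and fuses the atlas CT values with weights derived from a local generalized
registration error (GRE) metric:

1. **MR preprocessing** — slice-wise multiplicative bias reduction,
   landmark-based histogram standardization (dark mode / valley / bright
   mode mapped onto a fixed standard scale), and construction of the
   fat-enhanced water image `(W + alpha*F) / (1 + alpha)`.
2. **CT conditioning** — air thresholding (HU < −250), fuzzy c-means
   fat/muscle/bone clustering, bone suppression (bone → air HU), and a
   piecewise-linear remap matching the fat/muscle cluster centers to the
   water-MR landmark frame (`CT_S,BS,FS`).
3. **Registration** — landmark-initialized rigid alignment followed by
   cubic B-spline free-form deformation with a mean-squared-error cost,
   Gaussian pyramid, L-BFGS and bending-energy regularization.
4. **Atlas** — per subject, the original planning CT warped onto its own MR
   grid (`ct_reg`) stored next to the standardized fat-enhanced water image;
   serialized as a directory of NIfTI files plus `manifest.json`.
5. **Fusion** — per voxel and per atlas, GRE = geometric mean of the
   squared mean, variance and entropy of the in-plane patch difference
   between target and atlas MR; a 2-mm in-plane search finds each atlas's
   best offset; the sCT is the 1/GRE-weighted average of the
   offset-corrected atlas CT values.
6. **Evaluation** — MAE in HU over the entire body and bone/fat/muscle
   regions, with leave-one-out and train/test drivers.
7. **Phantom** — a seeded synthetic pelvis-like cohort generator (paired
   CT / water / fat volumes, ground-truth labels, landmarks, smooth
   deformations, bias fields, Rician noise) so the whole pipeline runs and
   is tested without patient data.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py` with the property-based
acceptance criteria; the end-to-end leave-one-out test on six 96×96×48
phantoms takes ~10 minutes on one CPU.

## CLI

All stages are exposed through one entry point:

```bash
atlas-sct make-phantoms --n 6 --out cohortdir/            # synthetic cohort
atlas-sct build-atlas --cohort cohortdir/cohort.yaml --out atlasdir/
atlas-sct synthesize --atlas atlasdir/ \
    --water w.nii.gz --fat f.nii.gz --landmarks lm.json --out sct.nii.gz
atlas-sct evaluate --cohort cohortdir/cohort.yaml --mode loo --out report.json
atlas-sct condition-ct --ct ct.nii.gz --water-std ws.nii.gz --out ct_c.nii.gz
atlas-sct register --fixed f.nii.gz --moving m.nii.gz --out field.nii.gz
atlas-sct propagate --atlas atlasdir/ --target wfe.nii.gz \
    --landmarks lm.json --out propdir/
```

Global flags: `--config params.yaml` (YAML/JSON overrides of the defaults in
`atlas_sct.config`), `--seed N`, `--log-level`, `--threads` (fusion kernel
only; results are thread-count invariant). Every run writes
`run_config.json` and `run.log` into its output directory. Exit codes:
0 success, 1 validation error, 2 I/O or format error.

Landmark files are JSON mappings of named physical points in mm, e.g.
`{"trochanter_l": [x, y, z], ...}`; phantom cohorts generate them
automatically.

## Conventions

- Volumes are NIfTI-1; geometry = spacing/origin/orientation with world
  mapping `origin + orientation @ (index * spacing)`. Volumes are reoriented
  to a canonical axis order at load (axial slices along axis 2, sagittal
  along axis 0). DICOM series input is supported when `pydicom` is
  installed.
- CT values are HU (out-of-support fill −1000); masks are {0,1}; label
  volumes use 0 background, 1 interior air, 2 fat, 3 muscle, 4 bone.
- Deformation fields are dense per-voxel displacements in mm on the fixed
  grid with pull-back semantics (`out(x) = moving(x + d(x))`), stored as
  4-D NIfTI.
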