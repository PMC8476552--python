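# scarmap

3D transmural scar assessment for late gadolinium-enhanced cardiac MR
(LGE-CMR).  `scarmap` takes a co-registered intensity volume and anatomy
labels (blood pool / myocardium / scar) of the left ventricle — isotropic
3D or thick-slice 2D — and produces:

* an **FWHM scar segmentation**: wall voxels at ≥ 0.45 of the
  slab-averaged maximum signal intensity are scar, with a second cutoff at
  0.67 splitting heterogeneous (border-zone) from dense (core) scar;
* an **isotropic reconstruction** of thick-slice segmentations via
  shape-based (signed-distance) interpolation, with per-slice acquisition
  shift correction;
* a **Laplace wall coordinate** s(x) — harmonic on the wall with s = 0 at
  the endocardium and s = 1 at the epicardium — whose gradient streamlines
  give point-wise endo–epi correspondences;
* a **transmurality map**: per epicardial vertex, wall thickness, scar
  thickness and their ratio TsM = scar / wall thickness ∈ [0, 1];
* **quantification**: scar areas at transmurality thresholds
  τ ∈ {0.1, …, 1.0}, scar volumes (total / heterogeneous / dense, cm³) and
  scar volume by wall-depth layer (bin boundaries at s = 0.33, 0.67, 0.97);
* **validation metrics**: Dice overlap, point-to-triangle Hausdorff
  distance, ICC(2,1), Pearson r, Mann–Whitney U.

It is aimed at researchers quantifying infarct scar architecture from
cardiac MR, e.g. for relating non-transmural scar extent to ventricular
tachycardia substrate.  Since clinical data cannot ship with the code, a
phantom generator provides LV-like anatomies (cylindrical annulus,
truncated ellipsoid, flat slab) with exact analytic transmurality — the
ground truth for every test.  See `docs/methods.md` for the model details.

## Worked example

`examples/01_phantom_to_transmurality_map.py` builds an annulus phantom
(inner radius 20 mm, wall 10 mm) with a scar sector of prescribed
transmural extent 0.5, hides the scar labels, and recovers everything from
the noisy image:

```
scar volume: 4.17 cm^3 (heterogeneous 0.00 + dense 4.17; analytic truth 4.24)
Laplace solve: 49 CG iterations, residual 9.8e-06
wall thickness: 9.95 mm (prescribed 10.0 mm) over 10240 vertices
mean transmurality inside the scar sector: 0.487 (prescribed 0.5); outside: 0.000
```

The FWHM segmentation recovers the scar volume to within ~2 % of the
analytic sector volume (all of it dense, as expected for a clean two-level
intensity model); traced wall thickness matches the prescribed 10 mm; and
the mean transmurality over the scar sector reproduces the prescribed
extent, with zero transmurality elsewhere.

`examples/02_thick_slice_recovery.py` runs the thick-slice route on an
ellipsoidal LV phantom:

```
thick-slice stack: 8 slices of 8.0 mm
wall Dice after 8 mm round trip: 0.937
transmurality ICC(2,1), upsampled vs reference: 0.953 over 13140 matched vertices
```

Even from the coarsest (8 mm) stack, the shape-based upsampling restores
the wall to Dice 0.94 and the per-vertex transmurality agrees with the
isotropic reference at ICC(2,1) ≈ 0.95.

## Command line

Each workflow stage is a subcommand of `scarmap`:

```sh
scarmap phantom --shape annulus -f 0.5 --spacing 0.75 --seed 7 -o demo
scarmap segment -i demo_image.nii.gz -s demo_labels.nii.gz \
        -o demo_scar.nii.gz --report volumes.json
scarmap map -s demo_scar.nii.gz -o map.ply --qc qc.json
scarmap quantify -m map.ply -o areas.csv
scarmap run -c config.yaml        # full pipeline from a YAML/JSON config
```

Volumes are NIfTI-1 (`.nii`/`.nii.gz`), meshes ASCII PLY with the
transmurality as a per-vertex property, tables CSV, reports JSON with a
provenance block (tool version, config hash, seed).  Exit codes: 0 success,
2 validation error, 3 numerical non-convergence.

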