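# Methods

## Problem and model

In ischemic cardiomyopathy, late gadolinium-enhanced cardiac MR (LGE-CMR)
shows infarct scar as hyperintense tissue in the left-ventricular wall.
Clinical 2D acquisitions have thick slices (≈1.5 × 1.5 × 8 mm), while 3D
sequences reach near-isotropic resolution (≈1.5 mm acquired, ≈0.7 mm
reconstructed) at a high acquisition and segmentation cost.  `scarmap`
implements a 3D transmural scar assessment that works from either input:

1. **Scar segmentation (FWHM).**  Within the myocardial mask, scar is the
   set of voxels whose raw signal intensity reaches a fraction of the
   maximum wall intensity — 0.45 for any scar, 0.67 for dense (core) scar,
   the band between them being heterogeneous (border-zone) scar.  The
   maximum is computed after averaging the signal over an ≈8 mm
   through-plane window (≈12 reconstructed slices) so that a single noisy
   voxel in a high-resolution acquisition cannot inflate the reference; raw
   intensities are compared against the threshold.  The maximum is global
   over the wall, making the operation operator-free.
2. **Isotropic reconstruction.**  Thick-slice segmentations are upsampled
   to isotropic resolution by shape-based interpolation: each label's
   binary mask is converted per slice to a signed Euclidean distance map
   (mm), distances are interpolated linearly along the through-plane axis,
   and each output voxel takes the most-interior label, with scar
   interpolated hierarchically inside the wall.  The converse
   (slab-averaging with a majority rule for labels) emulates thick-slice
   acquisitions for validation sweeps.
3. **Wall coordinate.**  The transmural depth coordinate s(x) solves the
   Laplace equation on the wall with s = 0 on the endocardium and s = 1 on
   the epicardium.  Its level sets define wall-depth layers; its gradient
   streamlines define point-wise endocardium–epicardium correspondences.
4. **Transmurality map (TsM).**  From each epicardial surface vertex a
   streamline is traced down the gradient to the endocardium.  Arc length =
   wall thickness; summed length of scar-labelled segments = scar
   thickness; their ratio is the transmurality, rendered on the epicardial
   surface.
5. **Quantification.**  Scar areas on the epicardial surface below each
   transmurality threshold τ ∈ {0.1, …, 1.0}; scar volumes split at the
   0.45/0.67 cutoffs; scar volume partitioned by wall depth with bin
   boundaries at s = 0.33, 0.67, 0.97 (endocardial, midwall, epicardial,
   and a thin subepicardial rim that is kept explicit rather than merged).

## Discretisation and numerical choices

**Grid conventions.**  Axis 2 is the through-plane (long-axis) direction;
voxel centres sit at `origin + index·spacing`; all physical quantities are
mm.  Labels are `0 = background, 1 = blood pool, 2 = myocardium, 3 = scar`,
with scar a subset of the wall (wall = {2, 3}).

**Boundary classification.**  Wall voxels 6-connected to blood form the
endocardial set, those 6-connected to background the epicardial set; a
voxel adjacent to both (possible in one-voxel walls) counts as endocardial,
keeping the s = 0 surface connected.  The basal truncation plane is the
topmost occupied slice; its through-plane faces get zero-flux treatment, as
do faces leaving the grid.  How a real ventricle's base should be treated
is genuinely open; zero flux makes the coordinate purely transmural there.

**Laplace solver.**  Anisotropic 7-point finite differences; symmetric
positive-definite system solved by Jacobi-preconditioned conjugate
gradients to a relative residual of 1e-5 (default).  Dirichlet conditions
are attached on the tissue interfaces: for a wall voxel with a blood or
background face-neighbour, the interface position along that axis is
estimated at sub-voxel accuracy as the 0.5-level crossing of the
1-voxel-Gaussian-smoothed binary mask (the same level set that defines the
extracted surfaces), and the boundary coupling gets the Shortley–Weller
weight 1/(α·h²).  This places the discrete boundary on the smooth anatomy
instead of the voxel staircase; on the 0.75 mm annulus phantom the solution
matches the closed form ln(r/a)/ln(b/a) to 0.018 (max over interior wall
voxels), versus ≈0.06 for the classical variant that pins values at
boundary-voxel centres (still available as `dirichlet="voxel"`, and exact
for degenerate one-voxel walls).  After solving, the first ring of blood /
background voxels receives reflected ghost values (−s̄ and 2−s̄ of the
adjacent wall) so that trilinear interpolation of s crosses 0 and 1 exactly
on the interfaces.

**Streamline tracing.**  First-order fixed-step integration of the
normalised negative gradient (trilinear interpolation), step = 0.25 × min
spacing.  A trace terminates at the ε = 0.02 level of s: the final segment
is cut at the ε-crossing and extended by ε/|∇s| to the s = 0 level, so the
stopping band does not truncate thickness (flat-slab thickness is exact to
one integration step).  Segments accrue to scar when their midpoint's
nearest voxel is scar.  Traces that stall in a flat gradient (e.g. on the
basal cut edge) or exceed a cap of 10 × an estimated mean wall thickness
are flagged invalid, excluded from maps and counted in the QC report.

**Surfaces.**  Marching cubes at level 0.5 on the 1-voxel-Gaussian-smoothed
binary mask (blood ∪ wall for the epicardium, blood for the endocardium),
vertices in mm.  The smoothing removes the staircase so that digital-sphere
areas converge to the analytic value (<3 % at 0.5 mm spacing); masks
touching the grid boundary stay open at the basal cut.  Scar areas count a
triangle when at least 2 of its 3 vertices satisfy the condition; "scar
area below τ" additionally requires scar presence (TsM > 0), since a
scar-free vertex trivially satisfies TsM < τ but is not scar (switchable
via `require_scar=False`).

**Resampling rules.**  Downsampling assigns each slab voxel the coarse
class (background / blood / wall) with the largest occupancy fraction, and
labels a wall voxel scar when scar occupies ≥ 0.5 of the wall fraction —
measured relative to wall occupancy so thin-wall slabs are not biased
toward background.  Upsampling extends the target grid half a slab beyond
the first/last slice centres (clamped interpolation) so round trips
preserve the anatomy's physical extent.  In-plane resolution is never
altered.  Slice-shift correction translates each slice by integer voxels,
either to the cross-section centroid of a reference 3D shell or to a
median-filtered trajectory of the stack's own wall centroids (which removes
isolated jumps and deliberately leaves any common global offset — a gauge
freedom — untouched).

**Statistics.**  ICC(2,1) (two-way random effects, absolute agreement,
single measurement) is computed from the ANOVA mean squares; Pearson r
(two-sided p from the t transform) and Mann–Whitney U (exact p by
enumeration for combined n ≤ 12 without ties, tie-corrected normal
approximation otherwise) are delegated to scipy.  The symmetric Hausdorff
distance is point-to-triangle (KD-tree broad phase over triangle centroids,
exact narrow phase), avoiding the mesh-resolution inflation of
point-to-vertex distances.

## Synthetic phantoms

Real LGE-CMR with expert segmentations is not redistributable, so all tests
run on phantoms with analytic ground truth:

* **Annulus** (default: r_endo = 20 mm, wall = 10 mm, height 24 mm, scar
  sector [0, π/2), 0.75 mm isotropic): its wall coordinate is
  ln(r/a)/ln(b/a) in closed form, streamlines are radial, and the
  prescribed transmural extent f is the exact transmurality inside the
  sector — the exact oracle for the solver, tracer and map.
* **Truncated ellipsoid** (endo semi-axes 20 × 20 × 40 mm, wall 8 mm, cut
  at 0.2 of the basal semi-axis, 1.0 mm): realistic apex-to-base geometry
  for the resampling and concordance checks.  Its truth transmurality is a
  surface-normal proxy, so it carries looser tolerances than the annulus.
* **Flat slab** (10 mm wall between blood and background): s is exactly
  linear in depth, giving exact expectations for thickness and for the
  layer fractions of a full-thickness scar (≈ bin widths 0.33/0.34/0.30/0.03).

Intensities are drawn per label (background 0.05, blood 0.6, healthy
myocardium 0.2 — emulating signal nulling — scar 1.0, in arbitrary units)
with additive Gaussian noise σ = 0.02 and a fixed seed; the seed affects
only the noise, never the geometry.  These defaults separate scar cleanly
at the 0.45 cutoff in the noise-free limit and are all overridable.

What the phantoms do *not* emulate: bias fields, motion and partial-k-space
artifacts, papillary muscles, trabeculation, right-ventricular anatomy,
intensity gradients within scar, and registration error between image and
segmentation.  Passing phantom tests therefore demonstrates correctness of
the geometry/PDE/quantification machinery under the stated intensity model,
not robustness to real-world acquisition artifacts.

## Problem sizes

Unit tests run the annulus at 1.5 mm spacing (with correspondingly wider,
voxel-size-justified tolerances); the end-to-end checks in
`tests/test_acceptance.py` and `scripts/acceptance.py` run the annulus at
0.75 mm (≈89 k wall voxels) and the ellipsoid at 1.0 mm (≈57 k wall
voxels), where the stated tolerances (0.02 on s, ±0.5 mm thickness, ±0.05
transmurality, Dice ≥ 0.9/0.95, ICC ≥ 0.9) are asserted directly.  The
whole demo pipeline completes in seconds on one CPU at these sizes.

## Known limitations

* The upsampling stands in for the (undescribed) topologic interpolation of
  the original workflow; equivalence is asserted only at the level of
  phantom-recovery metrics (Dice, ICC), not algorithmic identity.
* The wall must be a single 6-connected component joining both surfaces;
  the pipeline drops speck components after resampling, but genuinely
  disconnected anatomy is rejected.
* Transmurality is defined on the epicardial mesh; midwall-surface or
  endocardial-projection variants are not implemented.
* The slab-averaged maximum is global over the wall; a user wanting the
  classical operator-drawn hyperenhanced region can restrict the wall mask
  before calling `segment_scar`.
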