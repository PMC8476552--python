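"""Through-plane resampling of volumes and segmentations.

Thick-slice 2D acquisitions are emulated by slab-averaging a high-resolution
volume along the through-plane (long-axis) direction; anisotropic
segmentations are brought back to isotropic resolution with shape-based
interpolation of per-slice signed distance maps.  In-plane resolution is
never altered — only axis 2 is resampled, matching the acquisition geometry
of short-axis imaging.

Downsampling rule for labels: within each slab, each label's occupancy
fraction is computed per in-plane position; the voxel takes the coarse class
(background / blood / wall) with the largest fraction, and a wall voxel is
labelled scar when the scar fraction *within the wall occupancy* reaches the
slab threshold (default 0.5, a majority rule that does not bias thin-wall
slabs toward background).

Upsampling: per-label binary masks are converted slice-by-slice to signed
Euclidean distance maps (mm, negative inside), distances are linearly
interpolated along the through-plane axis to the target spacing, and each
output voxel takes the label whose interpolated distance is most interior.
The blood/wall/scar hierarchy is interpolated hierarchically so that scar
stays nested inside the wall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import (
    BACKGROUND,
    BLOOD,
    MYOCARDIUM,
    SCAR,
    ImageVolume,
    LabelVolume,
    Volume,
)

__all__ = [
    "ResampleSpec",
    "downsample_throughplane",
    "upsample_topologic",
    "correct_slice_shifts",
    "match_grid",
]

log = logging.getLogger(__name__)


@dataclass
class ResampleSpec:
    """Parameters for through-plane resampling."""

    scar_fraction_threshold: float = 0.5  # scar-within-wall slab majority rule

    def __post_init__(self) -> None:
        if not 0.0 < self.scar_fraction_threshold <= 1.0:
            raise ValueError("scar_fraction_threshold must be in (0, 1]")


def _slab_partition(n_slices: int, n_per_slab: int) -> list[slice]:
    return [slice(i, min(i + n_per_slab, n_slices)) for i in range(0, n_slices, n_per_slab)]


def downsample_throughplane(
    vol: Volume, target_thickness: float, spec: ResampleSpec | None = None
) -> Volume:
    """Reduce through-plane resolution to ``target_thickness`` mm by slab
    aggregation (mean for intensities, occupancy-fraction rule for labels).
    """
    spec = spec or ResampleSpec()
    dz = vol.spacing[2]
    if target_thickness < dz - 1e-9:
        raise ValueError(
            f"target thickness {target_thickness} mm is thinner than source spacing {dz} mm"
        )
    n_per = max(1, int(round(target_thickness / dz)))
    if n_per == 1:
        return vol
    slabs = _slab_partition(vol.shape[2], n_per)
    new_dz = n_per * dz
    if abs(new_dz - target_thickness) > 1e-9:
        log.info(
            "target thickness %.3f mm rounded to %d thin slices = %.3f mm",
            target_thickness, n_per, new_dz,
        )

    zs = vol.axis_coords(2)
    new_origin = (vol.origin[0], vol.origin[1], float(np.mean(zs[slabs[0]])))
    new_spacing = (vol.spacing[0], vol.spacing[1], new_dz)

    if isinstance(vol, ImageVolume):
        out = np.stack([vol.data[:, :, s].mean(axis=2) for s in slabs], axis=2)
        return ImageVolume(out, new_spacing, new_origin)

    labels = vol.labels
    out = np.empty(labels.shape[:2] + (len(slabs),), dtype=np.int16)
    for j, s in enumerate(slabs):
        slab = labels[:, :, s]
        frac = np.stack(
            [(slab == code).mean(axis=2) for code in (BACKGROUND, BLOOD, MYOCARDIUM, SCAR)],
            axis=0,
        )
        wall_frac = frac[MYOCARDIUM] + frac[SCAR]
        coarse = np.argmax(np.stack([frac[BACKGROUND], frac[BLOOD], wall_frac]), axis=0)
        sl = np.where(coarse == 2, MYOCARDIUM, coarse).astype(np.int16)
        with np.errstate(invalid="ignore", divide="ignore"):
            scar_in_wall = np.where(wall_frac > 0, frac[SCAR] / wall_frac, 0.0)
        sl[(coarse == 2) & (scar_in_wall >= spec.scar_fraction_threshold)] = SCAR
        out[:, :, j] = sl
    return LabelVolume(out, new_spacing, new_origin)


def _signed_distance_slices(mask: np.ndarray, spacing_xy) -> np.ndarray:
    """Per-slice 2D signed EDT in mm: negative inside, positive outside.

    Empty slices get a large positive distance so structures taper out
    between the last occupied slice and an empty neighbour.
    """
    nx, ny, nz = mask.shape
    big = float(np.hypot(nx * spacing_xy[0], ny * spacing_xy[1]))
    out = np.empty(mask.shape, dtype=np.float64)
    for k in range(nz):
        m = mask[:, :, k]
        if not m.any():
            out[:, :, k] = big
            continue
        inside = ndimage.distance_transform_edt(m, sampling=spacing_xy)
        outside = ndimage.distance_transform_edt(~m, sampling=spacing_xy)
        out[:, :, k] = outside - inside
    return out


def _interp_z(d: np.ndarray, z_src: np.ndarray, z_new: np.ndarray) -> np.ndarray:
    """Linear interpolation of a (nx, ny, nz) field along axis 2."""
    idx = np.interp(z_new, z_src, np.arange(len(z_src)))
    lo = np.floor(idx).astype(int)
    hi = np.minimum(lo + 1, len(z_src) - 1)
    w = idx - lo
    return d[:, :, lo] * (1.0 - w) + d[:, :, hi] * w


def upsample_topologic(seg: LabelVolume, target_spacing: float) -> LabelVolume:
    """Upsample an anisotropic segmentation to isotropic resolution by
    shape-based (signed-distance) interpolation with hierarchical nesting.

    Requires at least two slices and a through-plane spacing coarser than
    ``target_spacing``; raises on empty segmentations.  Output labels are a
    subset of the input label set and scar remains inside the wall.
    """
    if seg.shape[2] < 2:
        raise ValueError("single-slice input cannot be interpolated")
    if not (seg.labels != BACKGROUND).any():
        raise ValueError("empty segmentation")
    dz = seg.spacing[2]
    if target_spacing > dz + 1e-9:
        raise ValueError(
            f"target spacing {target_spacing} mm is coarser than source {dz} mm"
        )
    if abs(target_spacing - dz) < 1e-9:
        return seg

    # cover the full physical slab extent: each source slice represents a
    # slab of dz, so extend half a slab (minus half a target voxel) past the
    # first/last slice centres; interpolation clamps to the end slices there
    z_src = seg.axis_coords(2)
    half = max(0.0, (dz - target_spacing) / 2.0)
    z0 = z_src[0] - half
    n_new = int(np.floor((z_src[-1] + half - z0) / target_spacing)) + 1
    z_new = z0 + np.arange(n_new) * target_spacing
    sp_xy = seg.spacing[:2]

    d_wall = _interp_z(_signed_distance_slices(seg.wall_mask, sp_xy), z_src, z_new)
    d_blood = _interp_z(_signed_distance_slices(seg.blood_mask, sp_xy), z_src, z_new)
    d_scar = _interp_z(_signed_distance_slices(seg.scar_mask, sp_xy), z_src, z_new)

    out = np.full(d_wall.shape, BACKGROUND, dtype=np.int16)
    is_blood = (d_blood < 0) & (d_blood <= d_wall)
    is_wall = (d_wall < 0) & ~is_blood
    out[is_blood] = BLOOD
    out[is_wall] = MYOCARDIUM
    out[is_wall & (d_scar < 0)] = SCAR  # scar nested within wall

    spacing = (seg.spacing[0], seg.spacing[1], float(target_spacing))
    origin = (seg.origin[0], seg.origin[1], float(z0))
    return LabelVolume(out, spacing, origin)


def _wall_centroids(labels: np.ndarray) -> np.ndarray:
    """In-plane wall centroid (index units) per slice; NaN for empty slices."""
    nz = labels.shape[2]
    cents = np.full((nz, 2), np.nan)
    for k in range(nz):
        wall = (labels[:, :, k] == MYOCARDIUM) | (labels[:, :, k] == SCAR)
        if wall.any():
            cents[k] = ndimage.center_of_mass(wall)
    return cents


def correct_slice_shifts(seg2d: LabelVolume, reference_mesh=None) -> LabelVolume:
    """Correct in-plane acquisition shifts of a thick-slice stack by rigid
    per-slice translation (integer voxels).

    With a reference surface mesh (e.g. the epicardial shell from a 3D
    acquisition), each slice's wall centroid is aligned to the centroid of
    the mesh's cross-section at that slice height.  Without a reference,
    slices are aligned to a median-filtered trajectory of their own wall
    centroids, which removes isolated jumps but leaves any common global
    offset untouched.  Slices with an empty wall pass through unshifted.
    """
    cents = _wall_centroids(seg2d.labels)
    nz = seg2d.shape[2]
    targets = np.array(cents, copy=True)

    if reference_mesh is not None:
        tm = reference_mesh.as_trimesh()
        zs = seg2d.axis_coords(2)
        for k, z in enumerate(zs):
            section = tm.section(plane_origin=[0, 0, z], plane_normal=[0, 0, 1])
            if section is None:
                continue
            c_mm = section.vertices[:, :2].mean(axis=0)
            targets[k] = [
                (c_mm[0] - seg2d.origin[0]) / seg2d.spacing[0],
                (c_mm[1] - seg2d.origin[1]) / seg2d.spacing[1],
            ]
    else:
        valid = ~np.isnan(cents[:, 0])
        if valid.sum() >= 3:
            vc = cents[valid]
            smoothed = np.stack(
                [ndimage.median_filter(vc[:, i], size=3, mode="nearest") for i in (0, 1)],
                axis=1,
            )
            targets[valid] = smoothed

    out = seg2d.labels.copy()
    for k in range(nz):
        if np.isnan(cents[k, 0]) or np.isnan(targets[k, 0]):
            if np.isnan(cents[k, 0]):
                log.warning("slice %d has empty wall; passed through unshifted", k)
            continue
        shift = np.rint(targets[k] - cents[k]).astype(int)
        if shift[0] or shift[1]:
            out[:, :, k] = ndimage.shift(
                seg2d.labels[:, :, k], shift, order=0, mode="constant", cval=BACKGROUND
            )
    return seg2d.with_labels(out)


def match_grid(vol: Volume, reference: Volume) -> Volume:
    """Nearest-neighbour resample of ``vol`` onto the grid of ``reference``.

    Used to compare volumes whose grids differ (e.g. after a downsample →
    upsample round trip whose slab centres shifted the origin).
    """
    coords = [
        (reference.axis_coords(ax) - vol.origin[ax]) / vol.spacing[ax] for ax in range(3)
    ]
    grid = np.meshgrid(*coords, indexing="ij")
    idx = np.stack(grid)
    if isinstance(vol, LabelVolume):
        data = ndimage.map_coordinates(
            vol.labels, idx, order=0, mode="constant", cval=BACKGROUND
        )
        return LabelVolume(data, reference.spacing, reference.origin)
    data = ndimage.map_coordinates(vol.data, idx, order=1, mode="nearest")
    return ImageVolume(data, reference.spacing, reference.origin)
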