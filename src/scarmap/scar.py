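"""Full-width-half-maximum scar segmentation and volume accounting.

Scar is detected inside the myocardial mask as the voxels whose raw signal
intensity reaches a fixed fraction of the maximum wall intensity — 0.45 for
any scar, with an optional second cutoff at 0.67 splitting it into
heterogeneous (border-zone, [0.45, 0.67) of max) and dense (core, >= 0.67)
tissue.

The maximum itself is computed after slab-averaging the signal over an
~8 mm through-plane window (about 12 reconstructed slices), which protects
the reference maximum from single-voxel noise spikes in high-resolution 3D
acquisitions; the per-voxel comparison against the threshold always uses
the raw, unaveraged intensities.  Windows are truncated (mean over available
voxels) at the volume edges so the threshold is not deflated near apex or
base.  The maximum is taken globally over the whole wall mask, making the
operation operator-free and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import MYOCARDIUM, SCAR, ImageVolume, LabelVolume, same_grid

__all__ = ["ScarCriteria", "ScarVolumes", "slab_averaged_max", "segment_scar", "scar_volumes"]


@dataclass
class ScarCriteria:
    """Signal-intensity cutoffs (fractions of the slab-averaged maximum)."""

    cutoff: float = 0.45  # primary scar criterion
    dense_cutoff: float = 0.67  # dense (core) scar criterion
    slab_mm: float = 8.0  # through-plane extent of the max-SI averaging window
    slab_voxels: int | None = None  # explicit window size; overrides slab_mm

    def __post_init__(self) -> None:
        if not 0.0 < self.cutoff < self.dense_cutoff <= 1.0:
            raise ValueError("require 0 < cutoff < dense_cutoff <= 1")
        if self.slab_voxels is not None and self.slab_voxels < 1:
            raise ValueError("slab_voxels must be >= 1")

    def window_voxels(self, dz: float) -> int:
        if self.slab_voxels is not None:
            return self.slab_voxels
        if self.slab_mm < dz - 1e-9:
            raise ValueError(
                f"slab extent {self.slab_mm} mm is below the through-plane spacing {dz} mm"
            )
        return max(1, int(round(self.slab_mm / dz)))


@dataclass
class ScarVolumes:
    """Scar and wall volumes in cm^3 (total = heterogeneous + dense)."""

    total_cm3: float
    heterogeneous_cm3: float
    dense_cm3: float
    wall_cm3: float
    healthy_cm3: float

    def as_dict(self) -> dict[str, float]:
        return {
            "total_scar_cm3": self.total_cm3,
            "heterogeneous_scar_cm3": self.heterogeneous_cm3,
            "dense_scar_cm3": self.dense_cm3,
            "wall_cm3": self.wall_cm3,
            "healthy_cm3": self.healthy_cm3,
        }


def slab_averaged_max(
    img: ImageVolume, wall_mask: np.ndarray, criteria: ScarCriteria | None = None
) -> float:
    """Maximum over the wall of the through-plane slab-averaged intensity.

    Each voxel's intensity is replaced by the mean over a through-plane
    window of the criteria's slab extent (truncated at the volume edges);
    the maximum of these averaged values over the wall mask is returned.
    """
    if not np.any(wall_mask):
        raise ValueError("empty wall mask")
    criteria = criteria or ScarCriteria()
    w = criteria.window_voxels(img.spacing[2])
    if w == 1:
        avg = img.data
    else:
        kernel = np.ones(w)
        num = ndimage.convolve1d(img.data, kernel, axis=2, mode="constant", cval=0.0)
        den = ndimage.convolve1d(
            np.ones(img.shape[2]), kernel, mode="constant", cval=0.0
        )
        avg = num / den[None, None, :]
    return float(avg[wall_mask].max())


def segment_scar(
    img: ImageVolume,
    seg: LabelVolume,
    criteria: ScarCriteria | None = None,
) -> tuple[LabelVolume, np.ndarray, np.ndarray]:
    """FWHM scar segmentation within the myocardial mask.

    Returns the relabelled volume (wall voxels at or above
    ``cutoff * max_SI`` become scar, the rest myocardium; non-wall labels
    untouched) together with the (heterogeneous, dense) mask pair from the
    double-cutoff criterion.  Invariant under global intensity rescaling,
    since the thresholds scale with the maximum.
    """
    if not same_grid(img, seg):
        raise ValueError("image and segmentation grids do not match")
    criteria = criteria or ScarCriteria()
    wall = seg.wall_mask
    max_si = slab_averaged_max(img, wall, criteria)
    thr = criteria.cutoff * max_si
    thr_dense = criteria.dense_cutoff * max_si

    scar = wall & (img.data >= thr)
    dense = wall & (img.data >= thr_dense)
    hetero = scar & ~dense

    out = seg.labels.copy()
    out[wall] = MYOCARDIUM
    out[scar] = SCAR
    return seg.with_labels(out), hetero, dense


def scar_volumes(seg: LabelVolume, dense_mask: np.ndarray | None = None) -> ScarVolumes:
    """Voxel-count volumes in cm^3; enforces total = heterogeneous + dense."""
    vv = seg.voxel_volume_mm3 / 1000.0
    n_scar = int(seg.scar_mask.sum())
    n_wall = int(seg.wall_mask.sum())
    if dense_mask is not None:
        n_dense = int((dense_mask & seg.scar_mask).sum())
    else:
        n_dense = 0
    return ScarVolumes(
        total_cm3=n_scar * vv,
        heterogeneous_cm3=(n_scar - n_dense) * vv,
        dense_cm3=n_dense * vv,
        wall_cm3=n_wall * vv,
        healthy_cm3=(n_wall - n_scar) * vv,
    )
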