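"""Classification of wall-boundary voxels into endocardial, epicardial and
basal-cut sets.

The Laplace wall coordinate needs Dirichlet conditions attached to the two
wall surfaces: s = 0 where the wall meets the blood pool (endocardium) and
s = 1 where it meets the surrounding background (epicardium).  This module
identifies those voxel sets by 6-connected face adjacency.  Wall voxels on
the basal truncation plane (the topmost occupied through-plane slice) that
touch neither surface form the *cut* set and receive zero-flux treatment in
the solver.

Precedence for voxels adjacent to both blood and background (possible in
walls one voxel thick): endocardium wins, keeping the s = 0 surface
connected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import BACKGROUND, BLOOD, LabelVolume

__all__ = ["BoundaryClassification", "classify_boundaries"]

log = logging.getLogger(__name__)

# 6-connectivity structuring element
_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


@dataclass
class BoundaryClassification:
    """Disjoint boolean masks over the grid; each is a subset of the wall."""

    endo_mask: np.ndarray
    epi_mask: np.ndarray
    cut_mask: np.ndarray
    basal_slice: int

    @property
    def n_endo(self) -> int:
        return int(self.endo_mask.sum())

    @property
    def n_epi(self) -> int:
        return int(self.epi_mask.sum())

    @property
    def n_cut(self) -> int:
        return int(self.cut_mask.sum())


def classify_boundaries(seg: LabelVolume) -> BoundaryClassification:
    """Partition wall-boundary voxels into endo / epi / basal-cut sets.

    Raises
    ------
    ValueError
        If the wall is empty, or has no endocardial or no epicardial
        face-adjacency (an anatomically invalid ventricle).
    """
    wall = seg.wall_mask
    if not wall.any():
        raise ValueError("empty wall: no myocardium/scar voxels")

    blood = seg.labels == BLOOD
    bg = seg.labels == BACKGROUND

    near_blood = ndimage.binary_dilation(blood, structure=_FACE_STRUCT)
    near_bg = ndimage.binary_dilation(bg, structure=_FACE_STRUCT)

    endo = wall & near_blood
    epi = wall & near_bg & ~endo  # endo precedence over epi

    if not endo.any():
        raise ValueError("no endocardial boundary: wall has no blood-pool adjacency")
    if not epi.any():
        raise ValueError("no epicardial boundary: wall has no background adjacency")

    both = wall & near_blood & near_bg
    if both.any():
        log.info(
            "%d wall voxel(s) adjacent to both blood and background; "
            "assigned to the endocardial set",
            int(both.sum()),
        )

    # basal cut plane = largest-index occupied through-plane slice
    occupied = np.flatnonzero(wall.any(axis=(0, 1)))
    basal = int(occupied[-1])
    cut = np.zeros_like(wall)
    cut[:, :, basal] = wall[:, :, basal] & ~endo[:, :, basal] & ~epi[:, :, basal]

    return BoundaryClassification(endo_mask=endo, epi_mask=epi, cut_mask=cut, basal_slice=basal)


def wall_components(seg: LabelVolume) -> int:
    """Number of 6-connected components of the wall (diagnostic)."""
    _, n = ndimage.label(seg.wall_mask, structure=_FACE_STRUCT)
    return int(n)


def keep_largest_wall_component(seg: LabelVolume) -> LabelVolume:
    """Remove wall specks, keeping only the largest 6-connected wall component.

    Voxels in discarded components are relabelled background.  Useful after
    resampling, which can occasionally detach single-voxel islands.
    """
    lab, n = ndimage.label(seg.wall_mask, structure=_FACE_STRUCT)
    if n <= 1:
        return seg
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    out = seg.labels.copy()
    out[(lab > 0) & (lab != keep)] = BACKGROUND
    log.info("dropped %d wall speck component(s)", n - 1)
    return seg.with_labels(out)
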