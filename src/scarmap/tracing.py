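"""Endo–epi correspondences and the transmurality map.

From every epicardial surface vertex, a streamline of the wall coordinate is
traced by integrating the normalised negative gradient of s (trilinear
interpolation, fixed-step first-order integration, step = 0.25 × minimum
voxel spacing by default) until the endocardium is reached.  The polyline's
arc length is the local wall thickness; the summed length of scar-labelled
segments (a segment counts as scar when its midpoint's nearest voxel is
scar) is the scar thickness; and their ratio is the transmurality TsM — the
fraction of wall thickness covered by scar.

A trace terminates when s drops below ``eps_endo`` (with a final linear
extrapolation to the s = 0 level so thickness is not truncated by the
stopping band) or when it crosses into the blood pool.  Traces exceeding a
length cap (10 × an estimated median wall thickness) or stalling in a flat
gradient — e.g. vertices on the basal cut edge — are flagged invalid and
excluded from maps but counted for QC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .laplace import PotentialField
from .surface import SurfaceMesh
from .volumes import BLOOD, SCAR

__all__ = ["CorrespondenceSet", "TransmuralityMap", "trace_correspondences", "transmurality_map"]


@dataclass
class CorrespondenceSet:
    """Per-epicardial-vertex streamline summaries (and optional polylines)."""

    lengths_mm: np.ndarray
    scar_lengths_mm: np.ndarray
    valid: np.ndarray
    step_mm: float
    paths: list[np.ndarray] | None = None  # polylines (k_i, 3) in mm, if stored

    @property
    def n_invalid(self) -> int:
        return int((~self.valid).sum())

    def qc_report(self) -> dict:
        v = self.valid
        return {
            "n_vertices": int(v.size),
            "n_invalid": self.n_invalid,
            "invalid_fraction": float((~v).mean()) if v.size else 0.0,
            "median_wall_thickness_mm": float(np.median(self.lengths_mm[v])) if v.any() else float("nan"),
        }


@dataclass
class TransmuralityMap:
    """Wall thickness, scar thickness and their ratio per epicardial vertex."""

    wall_thickness_mm: np.ndarray
    scar_thickness_mm: np.ndarray
    tsm: np.ndarray
    valid: np.ndarray

    def masked_tsm(self) -> np.ndarray:
        """TsM with invalid vertices as NaN."""
        out = self.tsm.copy()
        out[~self.valid] = np.nan
        return out


def _interp(vol: np.ndarray, ijk: np.ndarray, order: int) -> np.ndarray:
    return ndimage.map_coordinates(vol, ijk.T, order=order, mode="nearest")


def trace_correspondences(
    fld: PotentialField,
    epi_mesh: SurfaceMesh,
    step_frac: float = 0.25,
    eps_endo: float = 0.02,
    max_length_mm: float | None = None,
    store_paths: bool = False,
) -> CorrespondenceSet:
    """Trace a wall-crossing streamline from every epicardial vertex.

    All vertices are advanced simultaneously; each trace accrues arc length
    and scar-segment length until it terminates, stalls or exceeds the cap.
    """
    spacing = np.asarray(fld.spacing)
    origin = np.asarray(fld.origin)
    step = step_frac * float(spacing.min())
    labels = fld.seg.labels

    if max_length_mm is None:
        # crude thickness scale: wall volume / epicardial area, floored
        thick_est = fld.wall_mask.sum() * float(np.prod(spacing)) / max(
            epi_mesh.area_mm2, 1e-9
        )
        max_length_mm = 10.0 * max(thick_est, 2.0 * float(spacing.max()))
    max_steps = int(np.ceil(max_length_mm / step))

    gx, gy, gz = np.gradient(fld.s, *spacing)

    pos = epi_mesh.vertices.copy()  # mm
    n = len(pos)
    lengths = np.zeros(n)
    scar_len = np.zeros(n)
    finished = np.zeros(n, dtype=bool)
    valid = np.ones(n, dtype=bool)
    path_log = [pos.copy()] if store_paths else None

    def to_idx(p):
        return (p - origin) / spacing

    active = np.arange(n)
    for _ in range(max_steps):
        if active.size == 0:
            break
        ijk = to_idx(pos[active])
        g = np.stack(
            [_interp(gx, ijk, 1), _interp(gy, ijk, 1), _interp(gz, ijk, 1)], axis=1
        )
        gn = np.linalg.norm(g, axis=1)
        stalled = gn < 1e-10
        if stalled.any():
            idx = active[stalled]
            valid[idx] = False
            finished[idx] = True
        ok = ~stalled
        act = active[ok]
        if act.size == 0:
            active = active[~finished[active]]
            continue
        direction = -g[ok] / gn[ok, None]
        s_prev = _interp(fld.s, to_idx(pos[act]), 1)
        new = pos[act] + step * direction
        s_new = _interp(fld.s, to_idx(new), 1)
        new_lab = _interp(labels, to_idx(new), 0)

        reached = s_new < eps_endo
        hit_blood = (new_lab == BLOOD) & ~reached
        # partial step up to the eps-crossing, then extrapolate eps -> 0
        frac = np.ones(act.size)
        denom = s_prev - s_new
        safe = reached & (denom > 1e-12)
        frac[safe] = np.clip((s_prev[safe] - eps_endo) / denom[safe], 0.0, 1.0)
        extra = np.zeros(act.size)
        extra[reached] = np.clip(eps_endo / gn[ok][reached], 0.0, 2.0 * step)
        seg_len = frac * step + extra

        mid = pos[act] + 0.5 * seg_len[:, None] * direction
        mid_lab = _interp(labels, to_idx(mid), 0)
        lengths[act] += seg_len
        scar_len[act] += seg_len * (mid_lab == SCAR)
        pos[act] = pos[act] + (frac * step)[:, None] * direction
        if store_paths:
            snap = path_log[-1].copy()
            snap[act] = pos[act]
            path_log.append(snap)

        done = act[reached | hit_blood]
        finished[done] = True
        active = active[~finished[active]]

    if active.size:
        valid[active] = False  # exceeded the length cap

    paths = None
    if store_paths:
        stack = np.stack(path_log)  # (steps+1, n, 3)
        paths = [stack[:, i, :] for i in range(n)]

    return CorrespondenceSet(
        lengths_mm=lengths, scar_lengths_mm=scar_len, valid=valid, step_mm=step, paths=paths
    )


def transmurality_map(corrs: CorrespondenceSet) -> TransmuralityMap:
    """Per-vertex transmurality from the traced correspondences."""
    if not corrs.valid.any():
        raise ValueError("no valid correspondences to map")
    wall = corrs.lengths_mm
    scar = np.minimum(corrs.scar_lengths_mm, wall)
    with np.errstate(invalid="ignore", divide="ignore"):
        tsm = np.where(wall > 0, scar / wall, 0.0)
    return TransmuralityMap(
        wall_thickness_mm=wall,
        scar_thickness_mm=scar,
        tsm=np.clip(tsm, 0.0, 1.0),
        valid=corrs.valid.copy(),
    )
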