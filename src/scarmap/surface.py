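"""Surface extraction and mesh I/O.

The transmurality map lives on the epicardial surface, extracted as a
marching-cubes isosurface of the binary anatomy.  The binary mask is lightly
Gaussian-smoothed (default sigma = 1 voxel) before contouring at level 0.5,
which removes the voxel staircase so that surface areas and vertex positions
converge to the underlying smooth geometry; set ``smooth_sigma=0`` for the
raw binary isosurface.

Meshes are stored as ASCII PLY with an optional per-vertex scalar property
(used for the transmurality value).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .volumes import LabelVolume

__all__ = ["SurfaceMesh", "extract_surface", "write_ply", "read_ply"]


@dataclass
class SurfaceMesh:
    """Triangle mesh in physical (mm) coordinates with optional vertex scalars."""

    vertices: np.ndarray  # (n, 3) float
    faces: np.ndarray  # (m, 3) int
    vertex_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("faces index nonexistent vertices")
        if self.vertex_values is not None:
            self.vertex_values = np.asarray(self.vertex_values, dtype=np.float64)
            if len(self.vertex_values) != len(self.vertices):
                raise ValueError("vertex_values length must match vertices")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @property
    def area_mm2(self) -> float:
        return float(self.as_trimesh().area)

    @property
    def face_areas_mm2(self) -> np.ndarray:
        return self.as_trimesh().area_faces


def _isosurface(mask: np.ndarray, spacing, origin, smooth_sigma: float) -> SurfaceMesh:
    if not mask.any():
        raise ValueError("empty mask: no surface to extract")
    vol = mask.astype(np.float64)
    if smooth_sigma > 0:
        # mode="nearest" keeps surfaces that touch the grid boundary open
        # (no spurious closure at the basal cut)
        vol = ndimage.gaussian_filter(vol, sigma=smooth_sigma, mode="nearest")
    verts, faces, _, _ = measure.marching_cubes(vol, level=0.5, spacing=spacing)
    verts = verts + np.asarray(origin)[None, :]
    return SurfaceMesh(vertices=verts, faces=faces)


def extract_surface(
    seg: LabelVolume, which: str = "epi", smooth_sigma: float = 1.0
) -> SurfaceMesh:
    """Extract the endocardial or epicardial surface of the ventricle.

    ``which="epi"`` contours the wall-or-interior mask (blood + wall), whose
    outer boundary is the epicardium; ``which="endo"`` contours the blood
    pool, whose boundary is the endocardium.  Vertices are returned in mm
    physical coordinates.  Surfaces touching the last through-plane slice
    remain open at the basal cut.
    """
    if which == "epi":
        mask = seg.blood_mask | seg.wall_mask
    elif which == "endo":
        mask = seg.blood_mask
    else:
        raise ValueError(f"which must be 'endo' or 'epi', got {which!r}")
    return _isosurface(mask, seg.spacing, seg.origin, smooth_sigma)


def write_ply(mesh: SurfaceMesh, path: str | Path, value_name: str = "transmurality") -> Path:
    """Write an ASCII PLY, including the per-vertex scalar when present."""
    path = Path(path)
    has_val = mesh.vertex_values is not None
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {len(mesh.vertices)}",
        "property float x",
        "property float y",
        "property float z",
    ]
    if has_val:
        lines.append(f"property float {value_name}")
    lines += [
        f"element face {len(mesh.faces)}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        if has_val:
            for v, s in zip(mesh.vertices, mesh.vertex_values):
                fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f} {s:.6f}\n")
        else:
            for v in mesh.vertices:
                fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
    return path


def read_ply(path: str | Path) -> SurfaceMesh:
    """Read an ASCII PLY written by :func:`write_ply`."""
    path = Path(path)
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ValueError(f"{path}: not a PLY file")
        n_vert = n_face = 0
        vert_props: list[str] = []
        element = None
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if tok[0] == "element":
                element = tok[1]
                if element == "vertex":
                    n_vert = int(tok[2])
                elif element == "face":
                    n_face = int(tok[2])
            elif tok[0] == "property" and element == "vertex" and tok[1] != "list":
                vert_props.append(tok[2])
            elif tok[0] == "end_header":
                break
        verts = np.empty((n_vert, len(vert_props)))
        for i in range(n_vert):
            verts[i] = [float(x) for x in fh.readline().split()]
        faces = np.empty((n_face, 3), dtype=np.int64)
        for i in range(n_face):
            tok = fh.readline().split()
            faces[i] = [int(x) for x in tok[1:4]]
    values = verts[:, 3] if len(vert_props) > 3 else None
    return SurfaceMesh(vertices=verts[:, :3], faces=faces, vertex_values=values)
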