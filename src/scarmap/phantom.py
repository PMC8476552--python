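"""Synthetic left-ventricle phantoms with analytic ground truth.

Real LGE-CMR with expert segmentations is not redistributable, so tests and
demos run on phantoms that emulate the imaging inputs: a truncated LV-like
wall surrounding a blood pool, with a scar sector of prescribed transmural
extent, rasterised to a label volume, plus a two-level intensity model with
additive Gaussian noise (bright scar on nulled healthy myocardium).

Two shapes are provided:

* ``annulus`` — a cylindrical ring (inner radius ``r_endo``, wall thickness
  ``wall_thickness``) spanning the full through-plane extent.  Its Laplace
  wall coordinate is known in closed form, s(r) = ln(r/a)/ln(b/a), its
  streamlines are radial, and the prescribed transmural extent ``f`` is the
  exact transmurality everywhere inside the scar sector — the exact oracle.
* ``ellipsoid`` — a truncated ellipsoidal shell, apex down, cut at a basal
  plane; closer to real LV geometry.  Its ground-truth transmurality is
  defined along the surface-normal proxy and is approximate, so it serves
  as the realism check with looser tolerances.

A flat-slab phantom (:func:`make_slab_phantom`) is also provided: its wall
coordinate is exactly linear in depth, which makes layer-partition and
thickness checks trivial to verify.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volumes import BACKGROUND, BLOOD, MYOCARDIUM, SCAR, ImageVolume, LabelVolume

__all__ = ["PhantomSpec", "PhantomTruth", "make_phantom", "make_slab_phantom", "slice_stack"]


@dataclass
class PhantomSpec:
    """Parameters of the synthetic ventricle.

    Geometry is in mm; angles in radians; the scar sector covers azimuths
    ``[theta1, theta2)`` with transmural extent ``f`` measured from the
    endocardium (0 = no scar, 1 = full thickness).
    """

    shape: str = "annulus"  # "annulus" | "ellipsoid"
    r_endo: float = 20.0  # annulus inner radius
    height: float = 24.0  # annulus height
    endo_semiaxes: tuple[float, float, float] = (20.0, 20.0, 40.0)  # ellipsoid
    basal_fraction: float = 0.2  # ellipsoid: cut at z = basal_fraction * c_epi
    wall_thickness: float = 10.0
    theta1: float = 0.0
    theta2: float = math.pi / 2
    transmural_extent: float = 0.5
    scar_z_range: tuple[float, float] | None = None  # mm; None = full extent
    spacing: tuple[float, float, float] = (0.75, 0.75, 0.75)
    margin_voxels: int = 3
    # intensity model (arbitrary units); scar is hyperintense, healthy nulled
    mu_background: float = 0.05
    mu_blood: float = 0.6
    mu_healthy: float = 0.2
    mu_scar: float = 1.0
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.transmural_extent <= 1.0:
            raise ValueError("transmural_extent must be in [0, 1]")
        if self.wall_thickness <= 2 * max(self.spacing):
            raise ValueError(
                f"wall thickness {self.wall_thickness} mm not resolvable at "
                f"spacing {self.spacing} (need > 2 * max spacing)"
            )
        if self.mu_scar <= self.mu_healthy:
            raise ValueError("mu_scar must exceed mu_healthy")
        if self.shape not in ("annulus", "ellipsoid"):
            raise ValueError(f"unknown phantom shape {self.shape!r}")


def _ellipsoid_volume_below(semiaxes, z: float) -> float:
    """Volume of the ellipsoid region with height coordinate <= z (mm^3)."""
    a, b, c = semiaxes
    z = float(np.clip(z, -c, c))
    return math.pi * a * b * (z - z**3 / (3 * c**2) + 2 * c / 3)


@dataclass
class PhantomTruth:
    """Analytic ground truth for a generated phantom."""

    shape: str
    wall_thickness_mm: float
    transmural_extent: float
    theta1: float
    theta2: float
    scar_z_range: tuple[float, float]
    wall_volume_cm3: float
    scar_volume_cm3: float
    r_endo: float | None = None
    r_epi: float | None = None
    exact: bool = True  # annulus truth is exact; ellipsoid is a normal-ray proxy

    def in_sector(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points (n, 3 mm) inside the scar sector footprint."""
        pts = np.atleast_2d(points)
        theta = np.mod(np.arctan2(pts[:, 1], pts[:, 0]), 2 * math.pi)
        t1 = self.theta1 % (2 * math.pi)
        t2 = self.theta2 % (2 * math.pi)
        if t1 <= t2:
            in_theta = (theta >= t1) & (theta < t2)
        else:
            in_theta = (theta >= t1) | (theta < t2)
        z0, z1 = self.scar_z_range
        return in_theta & (pts[:, 2] >= z0) & (pts[:, 2] <= z1)

    def transmurality_at(self, points: np.ndarray) -> np.ndarray:
        """Ground-truth transmurality at surface points: f in sector, else 0."""
        return np.where(self.in_sector(points), self.transmural_extent, 0.0)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {k: v for k, v in self.__dict__.items()}
        payload["scar_z_range"] = list(self.scar_z_range)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return path


def _sector_mask(x, y, theta1, theta2) -> np.ndarray:
    theta = np.mod(np.arctan2(y, x), 2 * math.pi)
    t1 = theta1 % (2 * math.pi)
    t2 = theta2 % (2 * math.pi)
    if t1 <= t2:
        return (theta >= t1) & (theta < t2)
    return (theta >= t1) | (theta < t2)


def _annulus_labels(spec: PhantomSpec):
    dx, dy, dz = spec.spacing
    r_epi = spec.r_endo + spec.wall_thickness
    half = r_epi + spec.margin_voxels * max(dx, dy)
    nx = int(math.ceil(2 * half / dx))
    ny = int(math.ceil(2 * half / dy))
    nz = max(2, int(round(spec.height / dz)))
    origin = (-(nx - 1) / 2 * dx, -(ny - 1) / 2 * dy, 0.0)

    xs = origin[0] + np.arange(nx) * dx
    ys = origin[1] + np.arange(ny) * dy
    zs = origin[2] + np.arange(nz) * dz
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    R = np.hypot(X, Y)

    labels = np.full((nx, ny, nz), BACKGROUND, dtype=np.int16)
    blood2d = R < spec.r_endo
    wall2d = (R >= spec.r_endo) & (R < r_epi)
    r_scar = spec.r_endo + spec.transmural_extent * spec.wall_thickness
    scar2d = wall2d & (R < r_scar) & _sector_mask(X, Y, spec.theta1, spec.theta2)

    z0, z1 = spec.scar_z_range if spec.scar_z_range is not None else (zs[0], zs[-1])
    for k, z in enumerate(zs):
        sl = np.full((nx, ny), BACKGROUND, dtype=np.int16)
        sl[blood2d] = BLOOD
        sl[wall2d] = MYOCARDIUM
        if z0 <= z <= z1:
            sl[scar2d] = SCAR
        labels[:, :, k] = sl

    seg = LabelVolume(labels, spec.spacing, origin)
    h = zs[-1] - zs[0] + dz  # physical slab height covered by voxels
    sector = (spec.theta2 - spec.theta1) % (2 * math.pi) or 2 * math.pi
    scar_h = min(z1, zs[-1]) - max(z0, zs[0]) + dz
    wall_vol = math.pi * (r_epi**2 - spec.r_endo**2) * h
    scar_vol = 0.5 * sector * (r_scar**2 - spec.r_endo**2) * scar_h
    truth = PhantomTruth(
        shape="annulus",
        wall_thickness_mm=spec.wall_thickness,
        transmural_extent=spec.transmural_extent,
        theta1=spec.theta1,
        theta2=spec.theta2,
        scar_z_range=(float(z0), float(z1)),
        wall_volume_cm3=wall_vol / 1000.0,
        scar_volume_cm3=scar_vol / 1000.0,
        r_endo=spec.r_endo,
        r_epi=r_epi,
        exact=True,
    )
    return seg, truth


def _ellipsoid_labels(spec: PhantomSpec):
    dx, dy, dz = spec.spacing
    ae, be, ce = spec.endo_semiaxes
    w = spec.wall_thickness
    epi = (ae + w, be + w, ce + w)
    z_cut = spec.basal_fraction * epi[2]

    half_x = epi[0] + spec.margin_voxels * dx
    half_y = epi[1] + spec.margin_voxels * dy
    nx = int(math.ceil(2 * half_x / dx))
    ny = int(math.ceil(2 * half_y / dy))
    z_lo = -epi[2] - spec.margin_voxels * dz
    nz = int(math.ceil((z_cut - z_lo) / dz))
    origin = (-(nx - 1) / 2 * dx, -(ny - 1) / 2 * dy, z_lo)

    xs = origin[0] + np.arange(nx) * dx
    ys = origin[1] + np.arange(ny) * dy
    zs = origin[2] + np.arange(nz) * dz
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")

    def rho(semi):
        a, b, c = semi
        return (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2

    inside_endo = rho(spec.endo_semiaxes) < 1.0
    inside_epi = rho(epi) < 1.0
    labels = np.full((nx, ny, nz), BACKGROUND, dtype=np.int16)
    labels[inside_epi & ~inside_endo] = MYOCARDIUM
    labels[inside_endo] = BLOOD

    f = spec.transmural_extent
    semi_f = (ae + f * w, be + f * w, ce + f * w)
    scar = (
        (labels == MYOCARDIUM)
        & (rho(semi_f) < 1.0)
        & _sector_mask(X, Y, spec.theta1, spec.theta2)
    )
    z0, z1 = spec.scar_z_range if spec.scar_z_range is not None else (zs[0], zs[-1])
    scar &= (Z >= z0) & (Z <= z1)
    labels[scar] = SCAR

    seg = LabelVolume(labels, spec.spacing, origin)
    wall_vol = _ellipsoid_volume_below(epi, z_cut) - _ellipsoid_volume_below(
        spec.endo_semiaxes, z_cut
    )
    sector = (spec.theta2 - spec.theta1) % (2 * math.pi) or 2 * math.pi
    scar_vol = (
        (sector / (2 * math.pi))
        * (_ellipsoid_volume_below(semi_f, z_cut) - _ellipsoid_volume_below(spec.endo_semiaxes, z_cut))
    )
    truth = PhantomTruth(
        shape="ellipsoid",
        wall_thickness_mm=w,
        transmural_extent=f,
        theta1=spec.theta1,
        theta2=spec.theta2,
        scar_z_range=(float(z0), float(z1)),
        wall_volume_cm3=wall_vol / 1000.0,
        scar_volume_cm3=scar_vol / 1000.0,
        exact=False,
    )
    return seg, truth


def render_intensities(seg: LabelVolume, spec: PhantomSpec) -> ImageVolume:
    """Draw per-label intensities with additive Gaussian noise (seeded)."""
    rng = np.random.default_rng(spec.seed)
    mu = np.array([spec.mu_background, spec.mu_blood, spec.mu_healthy, spec.mu_scar])
    data = mu[seg.labels]
    if spec.noise_sigma > 0:
        data = data + rng.normal(0.0, spec.noise_sigma, size=seg.shape)
    return ImageVolume(data, seg.spacing, seg.origin)


def make_phantom(spec: PhantomSpec) -> tuple[LabelVolume, ImageVolume, PhantomTruth]:
    """Rasterise the phantom and render its intensity volume.

    Labels are evaluated at voxel centres from the analytic geometry; the
    same spec and seed always reproduce the identical output, and the seed
    affects only the intensity noise, never the labels.
    """
    if spec.shape == "annulus":
        seg, truth = _annulus_labels(spec)
    else:
        seg, truth = _ellipsoid_labels(spec)
    img = render_intensities(seg, spec)
    return seg, img, truth


def make_slab_phantom(
    wall_thickness: float = 10.0,
    spacing: float = 0.5,
    ny: int = 12,
    nz: int = 12,
    full_scar: bool = False,
    pad_voxels: int = 3,
) -> LabelVolume:
    """Flat wall slab: blood below, wall in the middle, background above
    (stacked along axis 0).  The wall coordinate is exactly linear in depth.
    """
    n_wall = int(round(wall_thickness / spacing))
    nx = n_wall + 2 * pad_voxels
    labels = np.full((nx, ny, nz), BACKGROUND, dtype=np.int16)
    labels[:pad_voxels] = BLOOD
    labels[pad_voxels : pad_voxels + n_wall] = SCAR if full_scar else MYOCARDIUM
    return LabelVolume(labels, (spacing, spacing, spacing), (0.0, 0.0, 0.0))


def slice_stack(vol, thickness: float):
    """Emulate a thick-slice 2D acquisition of the same anatomy.

    Delegates to :func:`scarmap.resample.downsample_throughplane`; identity
    when ``thickness`` equals the current through-plane spacing.
    """
    from .resample import downsample_throughplane

    if not (np.isfinite(thickness) and thickness > 0):
        raise ValueError(f"slice thickness must be positive and finite, got {thickness}")
    if abs(thickness - vol.spacing[2]) < 1e-9:
        return vol
    return downsample_throughplane(vol, thickness)
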