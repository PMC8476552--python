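"""Validation and concordance statistics.

Overlap (Dice), symmetric surface distance (Hausdorff, point-to-triangle),
intraclass correlation ICC(2,1), Pearson correlation, Mann–Whitney U and a
threshold-sweep correlation profile.  All p-values are two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh
from scipy import stats
from scipy.spatial import cKDTree

from .surface import SurfaceMesh

__all__ = [
    "dice",
    "max_surface_distance",
    "icc_2_1",
    "pearson_r",
    "mann_whitney_u",
    "threshold_sweep_correlation",
    "match_vertices",
]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask grids differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def _directed_max(points: np.ndarray, target: SurfaceMesh) -> float:
    # broad phase: candidate triangles by centroid KD-tree; narrow phase:
    # exact point-to-triangle distance on the candidates
    tris = target.as_trimesh().triangles
    tree = cKDTree(tris.mean(axis=1))
    k = min(8, len(tris))
    _, cand = tree.query(points, k=k)
    cand = np.atleast_2d(cand.reshape(len(points), k))
    pts_rep = np.repeat(points, k, axis=0)
    closest = trimesh.triangles.closest_point(tris[cand.ravel()], pts_rep)
    d = np.linalg.norm(closest - pts_rep, axis=1).reshape(len(points), k).min(axis=1)
    return float(d.max())


def max_surface_distance(a: SurfaceMesh, b: SurfaceMesh) -> float:
    """Symmetric Hausdorff distance (mm) between two surfaces.

    Vertex samples of each mesh are measured point-to-triangle against the
    other mesh (not point-to-vertex, which would inflate distances by the
    mesh resolution), and the larger directed maximum is returned.
    """
    if a.n_vertices == 0 or b.n_vertices == 0:
        raise ValueError("empty mesh")
    return max(_directed_max(a.vertices, b), _directed_max(b.vertices, a))


def icc_2_1(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is an (n subjects × k raters) matrix.  Computed from the
    two-way ANOVA mean squares as
    ``(MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))``.
    Returns NaN when the ratings carry no variance at all.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("ratings must be an (n >= 3) x (k >= 2) matrix")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings must be finite")
    n, k = x.shape
    grand = x.mean()
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    ss_rows = k * ((row_m - grand) ** 2).sum()
    ss_cols = n * ((col_m - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if abs(denom) < 1e-300:
        return float("nan")
    return float((msr - mse) / denom)


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation with a two-sided p (t, n−2 df).

    Returns (NaN, NaN) for constant input instead of raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1D vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_u(g1: np.ndarray, g2: np.ndarray) -> tuple[float, float]:
    """Mann–Whitney U (first group) with a two-sided p.

    Exact p by enumeration for combined n ≤ 12 without ties; normal
    approximation with tie correction otherwise (scipy backend).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([g1, g2])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (g1.size + g2.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(g1, g2, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class SweepCorrelation:
    profile: pd.DataFrame  # columns: threshold, r, p
    best_threshold: float
    best_r: float


def threshold_sweep_correlation(
    areas: pd.DataFrame, outcome: np.ndarray
) -> SweepCorrelation:
    """Correlate a per-subject outcome against scar areas at each threshold.

    ``areas`` has one row per subject and one column per threshold (column
    labels are the thresholds).  Returns the full r/p profile and the
    threshold maximising |r|.
    """
    outcome = np.asarray(outcome, dtype=float)
    if len(areas) != len(outcome):
        raise ValueError("subject lists do not match")
    if len(outcome) < 3:
        raise ValueError("need at least 3 subjects")
    rows = []
    for col in areas.columns:
        r, p = pearson_r(areas[col].to_numpy(), outcome)
        rows.append({"threshold": float(col), "r": r, "p": p})
    prof = pd.DataFrame(rows)
    finite = prof.dropna(subset=["r"])
    if finite.empty:
        return SweepCorrelation(prof, float("nan"), float("nan"))
    best = finite.loc[finite["r"].abs().idxmax()]
    return SweepCorrelation(prof, float(best["threshold"]), float(best["r"]))


def match_vertices(a: SurfaceMesh, b: SurfaceMesh) -> np.ndarray:
    """Index into ``b``'s vertices of the nearest neighbour of each vertex
    of ``a`` (used to pair per-vertex values across two reconstructions)."""
    tree = cKDTree(b.vertices)
    _, idx = tree.query(a.vertices)
    return idx
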