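import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from scarmap.metrics import (
    dice,
    icc_2_1,
    mann_whitney_u,
    match_vertices,
    max_surface_distance,
    pearson_r,
    threshold_sweep_correlation,
)
from scarmap.surface import extract_surface
from scarmap.volumes import LabelVolume


# ---------------------------------------------------------------- dice
def test_dice_examples():
    a = np.zeros((10, 10, 2), dtype=bool)
    b = np.zeros_like(a)
    a[:5], b[:5] = True, True
    assert dice(a, b) == 1.0
    b[:] = False
    b[5:] = True
    assert dice(a, b) == 0.0
    # |A| = |B| = 100, overlap 50 -> 0.5
    a = np.zeros(200, dtype=bool).reshape(10, 10, 2)
    b = a.copy()
    a.ravel()[:100] = True
    b.ravel()[50:150] = True
    assert dice(a, b) == 0.5


def test_dice_empty_and_mismatch():
    empty = np.zeros((4, 4, 4), dtype=bool)
    assert dice(empty, empty) == 1.0
    with pytest.raises(ValueError, match="grids differ"):
        dice(empty, np.zeros((5, 4, 4), dtype=bool))


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    a=hnp.arrays(bool, (5, 5, 3)),
    b=hnp.arrays(bool, (5, 5, 3)),
)
def test_dice_bounded_and_symmetric(a, b):
    d = dice(a, b)
    assert 0.0 <= d <= 1.0
    assert d == dice(b, a)


# --------------------------------------------------- surface distance
def _sphere_mesh(radius, spacing=0.5):
    n = int(np.ceil(2 * (radius + 3 * spacing) / spacing))
    c = (n - 1) / 2 * spacing
    coords = np.arange(n) * spacing
    X, Y, Z = np.meshgrid(coords, coords, coords, indexing="ij")
    R = np.sqrt((X - c) ** 2 + (Y - c) ** 2 + (Z - c) ** 2)
    labels = np.zeros((n, n, n), dtype=np.int16)
    labels[R < radius] = 1
    labels[(R >= radius) & (R < radius + 2 * spacing)] = 2
    return extract_surface(LabelVolume(labels, (spacing,) * 3), "endo")


def test_hausdorff_identity_and_symmetry():
    m = _sphere_mesh(8.0, spacing=1.0)
    assert max_surface_distance(m, m) == 0.0
    m2 = _sphere_mesh(10.0, spacing=1.0)
    assert max_surface_distance(m, m2) == pytest.approx(
        max_surface_distance(m2, m)
    )


def test_hausdorff_concentric_spheres():
    import trimesh as tm

    from scarmap.surface import SurfaceMesh

    # analytically concentric spheres -> radial gap of exactly 2 mm
    a_t = tm.creation.icosphere(subdivisions=3, radius=10.0)
    b_t = tm.creation.icosphere(subdivisions=3, radius=12.0)
    a = SurfaceMesh(a_t.vertices, a_t.faces)
    b = SurfaceMesh(b_t.vertices, b_t.faces)
    assert max_surface_distance(a, b) == pytest.approx(2.0, abs=0.1)


# ------------------------------------------------------------- ICC(2,1)
def test_icc_duplicate_columns():
    x = np.arange(6.0).reshape(-1, 1)
    assert icc_2_1(np.hstack([x, x])) == pytest.approx(1.0)


def test_icc_absolute_agreement_penalty():
    x = np.arange(6.0).reshape(-1, 1)
    assert icc_2_1(np.hstack([x, x + 2.0])) < 1.0


def test_icc_small_matrix_oracle():
    # frozen from an independent two-way ANOVA mean-squares computation
    X = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 7.0], [8.0, 6.0]])
    assert icc_2_1(X) == pytest.approx(0.8125, abs=1e-10)


def test_icc_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    import pandas as pd

    rng = np.random.default_rng(7)
    X = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1))
    n, k = X.shape
    df = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": X.ravel(),
        }
    )
    ref = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
    expected = float(ref["ICC"].iloc[1])  # row 1 = absolute agreement, single rater
    assert icc_2_1(X) == pytest.approx(expected, abs=1e-10)


def test_icc_degenerate_returns_nan():
    assert np.isnan(icc_2_1(np.zeros((5, 2))))


def test_icc_input_validation():
    with pytest.raises(ValueError):
        icc_2_1(np.zeros((2, 2)))


# ------------------------------------------------------------- Pearson
def test_pearson_perfect_lines():
    x = np.array([1.0, 2, 3, 4, 5])
    r, p = pearson_r(x, 2 * x + 1)
    assert r == pytest.approx(1.0)
    r, _ = pearson_r(x, -x)
    assert r == pytest.approx(-1.0)


def test_pearson_formula_oracle():
    x = np.array([2.0, 5, 1, 8, 4])
    y = np.array([3.0, 7, 2, 9, 5])
    r, _ = pearson_r(x, y)
    # direct covariance formula
    expected = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
        np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
    )
    assert r == pytest.approx(expected, abs=1e-12)


def test_pearson_constant_input_flagged():
    r, p = pearson_r(np.ones(5), np.arange(5.0))
    assert np.isnan(r) and np.isnan(p)


# -------------------------------------------------------- Mann-Whitney
def test_mw_identical_groups():
    g = np.array([1.0, 2, 3, 4])
    u, _ = mann_whitney_u(g, g)
    assert u == len(g) ** 2 / 2


def test_mw_complete_separation():
    u, _ = mann_whitney_u([1.0, 2, 3], [10.0, 11])
    assert u in (0.0, 6.0)


def test_mw_exact_enumeration_oracle():
    g1, g2 = (1.0, 3.0, 5.0), (2.0, 4.0)
    u, p = mann_whitney_u(g1, g2)
    # brute force over all C(5,3) rank assignments
    n1 = len(g1)
    us = np.array(
        [sum(c) - n1 * (n1 + 1) / 2 for c in itertools.combinations(range(1, 6), n1)]
    )
    p_exact = min(1.0, 2 * min((us <= u).mean(), (us >= u).mean()))
    assert u == 3.0
    assert p == pytest.approx(p_exact, abs=1e-10)


def test_mw_empty_group_rejected():
    with pytest.raises(ValueError, match="non-empty"):
        mann_whitney_u([], [1.0])


# --------------------------------------------- threshold sweep profile
def _area_table(rng, n_subjects=20):
    import pandas as pd

    taus = np.round(np.arange(0.1, 1.01, 0.1), 2)
    base = rng.gamma(2.0, 2.0, size=(n_subjects, 1))
    growth = np.cumsum(rng.uniform(0.1, 0.5, size=(n_subjects, len(taus))), axis=1)
    return pd.DataFrame(base + growth, columns=taus)


def test_sweep_planted_signal():
    rng = np.random.default_rng(0)
    areas = _area_table(rng)
    outcome = 3.0 * areas[0.2].to_numpy()
    res = threshold_sweep_correlation(areas, outcome)
    assert res.best_threshold == pytest.approx(0.2)
    assert res.best_r == pytest.approx(1.0)


def test_sweep_null_outcome():
    rng = np.random.default_rng(1)
    areas = _area_table(rng)
    outcome = rng.permutation(areas[0.5].to_numpy())
    res = threshold_sweep_correlation(areas, outcome)
    assert np.isfinite(res.best_r)
    assert len(res.profile) == areas.shape[1]


def test_sweep_recovers_driving_threshold_across_replicates():
    """Outcome driven by the tau = 0.3 column plus noise: the argmax
    threshold lands within +/-0.1 of 0.3 in >= 90% of seeded replicates."""
    hits = 0
    n_rep = 100
    for seed in range(n_rep):
        rng = np.random.default_rng(seed)
        areas = _area_table(rng)
        outcome = 2.0 * areas[0.3].to_numpy() + rng.normal(0, 0.3, size=len(areas))
        res = threshold_sweep_correlation(areas, outcome)
        hits += abs(res.best_threshold - 0.3) <= 0.1 + 1e-9
    assert hits >= 0.9 * n_rep


def test_sweep_too_few_subjects():
    import pandas as pd

    with pytest.raises(ValueError, match="3 subjects"):
        threshold_sweep_correlation(pd.DataFrame({0.1: [1.0, 2.0]}), np.array([1.0, 2.0]))


# ------------------------------------------------------ vertex matching
def test_match_vertices_identity():
    m = _sphere_mesh(8.0, spacing=1.0)
    idx = match_vertices(m, m)
    np.testing.assert_array_equal(idx, np.arange(m.n_vertices))
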