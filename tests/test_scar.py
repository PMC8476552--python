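import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scarmap.metrics import dice
from scarmap.phantom import PhantomSpec, make_phantom
from scarmap.resample import downsample_throughplane, match_grid, upsample_topologic
from scarmap.scar import ScarCriteria, scar_volumes, segment_scar, slab_averaged_max
from scarmap.volumes import ImageVolume, LabelVolume, MYOCARDIUM, SCAR


def _wall_volume(shape=(6, 6, 24), spacing=(1.0, 1.0, 1.0)):
    return LabelVolume(np.full(shape, MYOCARDIUM, dtype=np.int16), spacing)


def test_constant_image_max_is_value():
    seg = _wall_volume()
    img = ImageVolume(np.full(seg.shape, 7.5), seg.spacing)
    assert slab_averaged_max(img, seg.wall_mask) == pytest.approx(7.5)


def test_single_bright_voxel_is_window_averaged():
    seg = _wall_volume()
    data = np.zeros(seg.shape)
    data[3, 3, 12] = 120.0
    img = ImageVolume(data, seg.spacing)
    crit = ScarCriteria(slab_voxels=12)
    assert slab_averaged_max(img, seg.wall_mask, crit) == pytest.approx(120.0 / 12)


def test_window_of_one_slice_reduces_to_plain_max():
    seg = _wall_volume(spacing=(1.5, 1.5, 8.0))
    rng = np.random.default_rng(0)
    img = ImageVolume(rng.random(seg.shape), seg.spacing)
    crit = ScarCriteria(slab_mm=8.0)  # window = 1 slice at 8 mm spacing
    assert slab_averaged_max(img, seg.wall_mask, crit) == pytest.approx(img.data.max())


def test_empty_wall_raises():
    seg = _wall_volume()
    img = ImageVolume(np.zeros(seg.shape), seg.spacing)
    with pytest.raises(ValueError, match="empty"):
        slab_averaged_max(img, np.zeros(seg.shape, dtype=bool))


def test_cutoffs_applied_to_max():
    """max_SI = 100 -> scar threshold 45, dense threshold 67."""
    seg = _wall_volume()
    data = np.full(seg.shape, 100.0)
    data[0, 0, :] = 44.9
    data[1, 1, :] = 45.0
    data[2, 2, :] = 66.9
    data[3, 3, :] = 67.0
    img = ImageVolume(data, seg.spacing)
    out, hetero, dense = segment_scar(img, seg, ScarCriteria(slab_voxels=1))
    assert out.labels[0, 0, 0] == MYOCARDIUM
    assert out.labels[1, 1, 0] == SCAR and hetero[1, 1, 0] and not dense[1, 1, 0]
    assert out.labels[2, 2, 0] == SCAR and hetero[2, 2, 0]
    assert out.labels[3, 3, 0] == SCAR and dense[3, 3, 0]


@settings(deadline=None, max_examples=20, derandomize=True)
@given(scale=st.floats(min_value=1e-3, max_value=1e3))
def test_rescaling_invariance(scale):
    seg = _wall_volume(shape=(5, 5, 6))
    rng = np.random.default_rng(42)
    data = rng.random(seg.shape)
    out1, _, d1 = segment_scar(ImageVolume(data, seg.spacing), seg)
    out2, _, d2 = segment_scar(ImageVolume(data * scale, seg.spacing), seg)
    np.testing.assert_array_equal(out1.labels, out2.labels)
    np.testing.assert_array_equal(d1, d2)


def test_scar_mask_monotone_in_cutoff():
    seg = _wall_volume(shape=(8, 8, 8))
    rng = np.random.default_rng(3)
    img = ImageVolume(rng.random(seg.shape), seg.spacing)
    prev = None
    for c1 in (0.2, 0.45, 0.6):
        out, _, _ = segment_scar(img, seg, ScarCriteria(cutoff=c1, dense_cutoff=0.9))
        mask = out.scar_mask
        if prev is not None:
            assert (mask <= prev).all()  # raising the cutoff never adds voxels
        prev = mask


def test_double_cutoff_partitions_single(annulus):
    _, seg, img, _ = annulus
    out, hetero, dense = segment_scar(img, seg)
    np.testing.assert_array_equal(hetero | dense, out.scar_mask)
    assert not (hetero & dense).any()


def test_phantom_scar_dice(annulus):
    spec, seg, img, _ = annulus
    hidden = seg.with_labels(np.where(seg.labels == SCAR, MYOCARDIUM, seg.labels))
    out, _, _ = segment_scar(img, hidden)
    assert dice(out.scar_mask, seg.scar_mask) >= 0.95


def test_grid_mismatch_rejected(annulus):
    _, seg, img, _ = annulus
    other = ImageVolume(np.zeros((4, 4, 4)), (1, 1, 1))
    with pytest.raises(ValueError, match="grid"):
        segment_scar(other, seg)


def test_volume_unit_conversion():
    labels = np.full((10, 10, 10), SCAR, dtype=np.int16)
    seg = LabelVolume(labels, (1.0, 1.0, 1.0))
    vols = scar_volumes(seg)
    assert vols.total_cm3 == pytest.approx(1.0)
    assert vols.wall_cm3 == pytest.approx(1.0)


def test_no_scar_volumes():
    seg = _wall_volume()
    vols = scar_volumes(seg)
    assert vols.total_cm3 == 0.0
    assert vols.healthy_cm3 == vols.wall_cm3
    assert vols.total_cm3 == vols.heterogeneous_cm3 + vols.dense_cm3


def test_phantom_scar_volume_analytic(annulus):
    _, seg, _, truth = annulus
    vols = scar_volumes(seg)
    assert vols.total_cm3 == pytest.approx(truth.scar_volume_cm3, rel=0.04)


def test_coarsening_never_shrinks_measured_scar(annulus):
    """Partial-volume inflation: thick-slice acquisitions report more scar."""
    _, seg, img, _ = annulus
    fine = scar_volumes(seg).total_cm3
    for thickness in (6.0, 9.0):
        seg2d = downsample_throughplane(seg, thickness)
        up = upsample_topologic(seg2d, seg.spacing[2])
        coarse = scar_volumes(up).total_cm3
        assert coarse >= 0.99 * fine  # never decreases (1% voxelisation slack)
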