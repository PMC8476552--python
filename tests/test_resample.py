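import numpy as np
import pytest

from scarmap.metrics import dice
from scarmap.phantom import PhantomSpec, make_phantom
from scarmap.resample import (
    correct_slice_shifts,
    downsample_throughplane,
    match_grid,
    upsample_topologic,
)
from scarmap.volumes import BLOOD, MYOCARDIUM, SCAR, ImageVolume, LabelVolume, VALID_LABELS


def _column_stack(labels_per_slice):
    """Two identical slabs of constant 4x4 slices with the given labels."""
    arr = np.stack(
        [np.full((4, 4), lab, dtype=np.int16) for lab in labels_per_slice * 2], axis=2
    )
    return LabelVolume(arr, (1.0, 1.0, 1.0))


def test_unanimous_scar_slab():
    vol = _column_stack([SCAR] * 12)
    down = downsample_throughplane(vol, 12.0)
    assert (down.labels == SCAR).all()


def test_half_scar_slab_is_scar():
    # 6/12 scar within an all-wall slab -> scar by the >= 0.5 majority rule
    vol = _column_stack([SCAR] * 6 + [MYOCARDIUM] * 6)
    down = downsample_throughplane(vol, 12.0)
    assert (down.labels == SCAR).all()
    # one slice less scar -> myocardium
    vol2 = _column_stack([SCAR] * 5 + [MYOCARDIUM] * 7)
    assert (downsample_throughplane(vol2, 12.0).labels == MYOCARDIUM).all()


def test_scar_fraction_relative_to_wall():
    # slab mostly blood, thin wall that is all scar: wall loses the coarse
    # vote only if blood dominates, but scar-in-wall stays 1.0
    vol = _column_stack([SCAR] * 5 + [BLOOD] * 7)
    assert (downsample_throughplane(vol, 12.0).labels == BLOOD).all()
    vol2 = _column_stack([SCAR] * 7 + [BLOOD] * 5)
    assert (downsample_throughplane(vol2, 12.0).labels == SCAR).all()


def test_intensity_slab_mean():
    data = np.stack([np.full((4, 4), v, dtype=float) for v in (10, 30, 10, 30)], axis=2)
    img = ImageVolume(data, (1.0, 1.0, 1.0))
    down = downsample_throughplane(img, 2.0)
    assert np.allclose(down.data, 20.0)


def test_downsample_rejects_thinner_target(annulus):
    _, seg, _, _ = annulus
    with pytest.raises(ValueError, match="thinner"):
        downsample_throughplane(seg, 0.5 * seg.spacing[2])


def test_upsample_constant_stack_reproduces_pattern(annulus):
    _, seg, _, _ = annulus
    # annulus is z-constant: any slice pattern should be reproduced exactly
    thick = downsample_throughplane(seg, 6.0)
    up = upsample_topologic(thick, 1.5)
    for k in range(up.shape[2]):
        np.testing.assert_array_equal(up.labels[:, :, k], thick.labels[:, :, 0])


def test_upsample_isotropic_noop(annulus):
    _, seg, _, _ = annulus
    assert upsample_topologic(seg, seg.spacing[2]) is seg


def test_upsample_rejects_empty():
    vol = LabelVolume(np.zeros((4, 4, 4), dtype=np.int16), (1, 1, 8))
    with pytest.raises(ValueError, match="empty"):
        upsample_topologic(vol, 1.0)


def test_round_trip_recovers_wall(annulus):
    _, seg, _, _ = annulus
    down = downsample_throughplane(seg, 7.5)
    up = match_grid(upsample_topologic(down, seg.spacing[2]), seg)
    assert dice(up.wall_mask, seg.wall_mask) >= 0.90
    # label-set closure and scar-in-wall nesting
    assert set(np.unique(up.labels)) <= set(VALID_LABELS)
    assert not (up.scar_mask & ~up.wall_mask).any()


def test_round_trip_dice_improves_with_thinner_slices():
    spec = PhantomSpec(
        shape="ellipsoid", wall_thickness=8.0, transmural_extent=0.6,
        spacing=(1.0, 1.0, 1.0), noise_sigma=0.0,
    )
    seg, _, _ = make_phantom(spec)
    dices = []
    for thick in (8.0, 4.0, 2.0):
        down = downsample_throughplane(seg, thick)
        up = match_grid(upsample_topologic(down, seg.spacing[2]), seg)
        dices.append(dice(up.wall_mask, seg.wall_mask))
    assert dices[0] <= dices[1] <= dices[2]
    assert dices[0] >= 0.90


def test_shift_correction_identity(annulus):
    _, seg, _, _ = annulus
    thick = downsample_throughplane(seg, 6.0)
    out = correct_slice_shifts(thick)
    np.testing.assert_array_equal(out.labels, thick.labels)


def test_shift_correction_recovers_injected_shift(annulus):
    _, seg, _, _ = annulus
    thick = downsample_throughplane(seg, 6.0)
    shifted = thick.labels.copy()
    k = thick.shape[2] // 2
    shifted[:, :, k] = np.roll(thick.labels[:, :, k], 3, axis=0)
    out = correct_slice_shifts(thick.with_labels(shifted))
    # recovered to within one voxel of the original slice
    from scarmap.metrics import dice as _dice

    assert _dice(out.labels[:, :, k] > 0, thick.labels[:, :, k] > 0) > 0.95


def test_shift_correction_gauge_freedom(annulus):
    _, seg, _, _ = annulus
    thick = downsample_throughplane(seg, 6.0)
    rolled = thick.with_labels(np.roll(thick.labels, 2, axis=0))
    out = correct_slice_shifts(rolled)
    # a common shift of all slices leaves relative alignment unchanged
    np.testing.assert_array_equal(out.labels, rolled.labels)
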