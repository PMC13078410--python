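"""Segmentation, disc-summation volumes, and derived ventricular function."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtcine.errors import ConfigError, EmptySeriesError
from rtcine.io_formats import SeriesMetadata
from rtcine.volumetry import (
    MaskStack,
    chamber_volume,
    lv_mass,
    segment_chamber,
    ventricular_function,
)

from conftest import static_config


def _meta(slab=10.0, ps=2.0):
    return SeriesMetadata(frame_duration=33.0, pixel_spacing=(ps, ps),
                          slice_thickness=slab, n_slices=1, frames_per_slice=1)


def _disk_mask(shape, center, radius):
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    return (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius**2


# ---------------------------------------------------------------------------
# chamber_volume
# ---------------------------------------------------------------------------


def test_cylinder_of_disks_gives_textbook_volume():
    """10 stacked 400*pi mm^2 disks at 10 mm slabs: 125.66 mL."""
    mask = _disk_mask((64, 64), (32, 32), 10)  # ~400*pi mm^2 at 2 mm pixels
    # trim/pad to exactly 100*pi px = 400*pi mm^2
    target = int(round(100 * np.pi))
    idx = np.flatnonzero(mask.ravel())
    mask = np.zeros(64 * 64, dtype=bool)
    mask[idx[:target]] = True
    mask = mask.reshape(64, 64)
    stack = MaskStack(masks=[mask] * 10, metadata=_meta())
    assert chamber_volume(stack) == pytest.approx(125.66, abs=0.1)


def test_half_ellipsoid_disc_summation_matches_closed_form():
    """a=b=25 mm, c=80 mm half-ellipsoid sliced at 10 mm: (2/3)*pi*a*b*c."""
    masks = []
    for k in range(8):
        z = (k + 0.5) * 10.0
        radius_mm = 25.0 * np.sqrt(max(0.0, 1 - (z / 80.0) ** 2))
        masks.append(_disk_mask((96, 96), (48, 48), radius_mm / 2.0))
    volume = chamber_volume(MaskStack(masks=masks, metadata=_meta()))
    closed_form = (2 / 3) * np.pi * 25 * 25 * 80 / 1000.0  # 104.7 mL
    assert volume == pytest.approx(closed_form, rel=0.05)


def test_empty_stack_rejected():
    with pytest.raises(EmptySeriesError):
        chamber_volume(MaskStack(masks=[np.zeros((8, 8), dtype=bool)], metadata=_meta()))


def test_volume_invariant_to_in_plane_translation():
    mask = _disk_mask((64, 64), (20, 20), 8)
    shifted = np.roll(np.roll(mask, 11, axis=0), -5, axis=1)
    v1 = chamber_volume(MaskStack(masks=[mask], metadata=_meta()))
    v2 = chamber_volume(MaskStack(masks=[shifted], metadata=_meta()))
    assert v1 == v2


def test_volume_additive_over_slices():
    mask = _disk_mask((64, 64), (32, 32), 9)
    one = chamber_volume(MaskStack(masks=[mask], metadata=_meta()))
    three = chamber_volume(MaskStack(masks=[mask] * 3, metadata=_meta()))
    assert three == pytest.approx(3 * one)


# ---------------------------------------------------------------------------
# segment_chamber
# ---------------------------------------------------------------------------


def test_noiseless_phantom_mid_slice_dice(static_phantom):
    series, truth = static_phantom
    k, j = 2, 0
    seed = truth.seed_pixel(k, j, "LV")
    result = segment_chamber(series.voxels[k, j], seed)
    true_mask = truth.cavity_mask(k, j, "LV")
    dice = 2 * (result.mask & true_mask).sum() / (result.mask.sum() + true_mask.sum())
    assert not result.flagged
    assert dice >= 0.95


def test_papillary_holes_are_filled():
    image = np.full((48, 48), 0.1)
    image[10:38, 10:38] = 1.0
    image[20:24, 20:24] = 0.1  # papillary muscle inside the pool
    with_holes = segment_chamber(image, (12, 12), include_papillary=False)
    filled = segment_chamber(image, (12, 12), include_papillary=True)
    assert filled.mask.sum() > with_holes.mask.sum()
    assert filled.mask[21, 21] and not with_holes.mask[21, 21]


def test_seed_in_myocardium_is_flagged(static_phantom):
    series, truth = static_phantom
    k, j = 2, 0
    r, c = truth.seed_pixel(k, j, "LV")
    true_mask = truth.cavity_mask(k, j, "LV")
    col = c
    while true_mask[r, col]:  # walk out of the cavity into the wall
        col += 1
    result = segment_chamber(series.voxels[k, j], (r, col + 1))
    assert result.flagged


def test_seed_outside_image_rejected():
    with pytest.raises(ConfigError):
        segment_chamber(np.zeros((8, 8)), (10, 10))


def test_endocardial_must_lie_inside_epicardial():
    endo = _disk_mask((32, 32), (16, 16), 8)
    epi = _disk_mask((32, 32), (16, 16), 5)  # smaller than endo: invalid
    with pytest.raises(ConfigError):
        MaskStack(masks=[endo], metadata=_meta(), epicardial=[epi])


# ---------------------------------------------------------------------------
# ventricular_function / lv_mass
# ---------------------------------------------------------------------------


def test_function_from_typical_resting_volumes():
    res = ventricular_function(edv=170.0, esv=72.0, heart_rate=56.0)
    assert res.sv == pytest.approx(98.0)
    assert res.ef == pytest.approx(57.6, abs=0.05)


def test_cardiac_output_at_vigorous_exercise():
    res = ventricular_function(edv=116.0, esv=0.0, heart_rate=136.0)  # SV 116 mL
    assert res.co == pytest.approx(15.8, abs=0.05)


def test_zero_stroke_volume_limits():
    res = ventricular_function(edv=100.0, esv=100.0, heart_rate=60.0)
    assert (res.sv, res.ef, res.co) == (0.0, 0.0, 0.0)


def test_esv_above_edv_rejected():
    with pytest.raises(ConfigError):
        ventricular_function(edv=100.0, esv=120.0, heart_rate=60.0)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    edv=st.floats(min_value=1.0, max_value=500.0),
    frac=st.floats(min_value=0.0, max_value=1.0),
    hr=st.floats(min_value=20.0, max_value=220.0),
)
def test_ejection_fraction_is_bounded(edv, frac, hr):
    res = ventricular_function(edv=edv, esv=edv * frac, heart_rate=hr)
    assert 0.0 <= res.ef <= 100.0
    assert res.sv == pytest.approx(edv - edv * frac, rel=1e-9, abs=1e-9)


def test_lv_mass_examples():
    assert lv_mass(200.0, 100.0) == pytest.approx(105.0)
    assert lv_mass(150.0, 150.0) == 0.0
    with pytest.raises(ConfigError):
        lv_mass(100.0, 150.0)


def test_lv_mass_from_phantom_truth_masks(static_phantom):
    """Epicardial minus endocardial rasterised truth volumes times 1.05 g/mL
    recovers the programmed wall mass within rasterisation tolerance."""
    series, truth = static_phantom
    meta = series.metadata
    endo = chamber_volume(
        MaskStack(masks=truth.reference_masks(truth.config.edv_lv, "LV"), metadata=meta)
    )
    epi = chamber_volume(MaskStack(masks=truth.reference_epicardial_masks(), metadata=meta))
    mass = lv_mass(epi, endo)
    assert mass == pytest.approx(1.05 * truth.wall_volume_lv_ml, rel=0.06)
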