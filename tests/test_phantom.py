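"""Phantom generator: determinism, programmed truth, and analytic volumes."""

import numpy as np
import pytest

from rtcine.errors import ConfigError
from rtcine.phantom import (
    PhantomConfig,
    default_navigator_line,
    generate_cine_phantom,
    generate_flow_phantom,
    generate_repeatability_cohort,
    volume_waveform_fraction,
)
from rtcine.navigator import NavigatorLine, extract_navigator_trace
from rtcine.volumetry import MaskStack, chamber_volume

from conftest import small_config, static_config


def test_same_seed_is_bit_identical():
    kwargs = dict(n_slices=2, frames_per_slice=60, respiratory_rate=40.0)
    s1, t1 = generate_cine_phantom(small_config(seed=7, **kwargs))
    s2, t2 = generate_cine_phantom(small_config(seed=7, **kwargs))
    assert np.array_equal(s1.voxels, s2.voxels)
    assert all(np.array_equal(a, b) for a, b in zip(t1.peaks, t2.peaks))
    s3, _ = generate_cine_phantom(small_config(seed=8, **kwargs))
    assert not np.array_equal(s1.voxels, s3.voxels)


def test_no_motion_gives_constant_trace_and_empty_truth():
    cfg = static_config()  # respiratory amplitude and noise both zero
    series, truth = generate_cine_phantom(cfg)
    line = NavigatorLine(*default_navigator_line(cfg))
    trace = extract_navigator_trace(series, line)
    assert np.allclose(trace.signal, trace.signal[:, :1])
    assert all(len(p) == 0 for p in truth.peaks)
    assert all(len(v) == 0 for v in truth.valleys)


def test_volume_waveform_attains_extremes_and_is_smooth():
    phase = np.linspace(0, 1, 10_001)
    w = volume_waveform_fraction(phase)
    assert w[0] == pytest.approx(0.0, abs=1e-12)  # ED at phase 0
    assert w.max() == pytest.approx(1.0, abs=1e-6)  # ES at the systolic fraction
    assert abs(np.argmax(w) / 10_000 - 1 / 3) < 1e-3
    assert np.all((w >= 0) & (w <= 1))


@pytest.mark.parametrize("volume_key", ["edv_lv", "esv_lv"])
def test_rasterized_cavity_volume_shrinks_toward_analytic(volume_key):
    """Disc-summation of the rasterised truth masks reproduces the analytic
    half-ellipsoid volume, with the in-plane error shrinking at finer pixels."""
    errors = {}
    for ps, mat in ((2.0, (88, 72)), (1.0, (176, 144))):
        cfg = static_config(n_slices=15, edv_lv=170.0, esv_lv=72.0, edv_rv=172.0,
                            esv_rv=80.0, pixel_spacing=ps, matrix_size=mat)
        series, truth = generate_cine_phantom(cfg)
        prog = getattr(cfg, volume_key)
        masks = truth.reference_masks(prog, "LV")
        vol = chamber_volume(MaskStack(masks=masks, metadata=series.metadata))
        errors[ps] = abs(vol / prog - 1.0)
    assert errors[2.0] < 0.05
    assert errors[1.0] < errors[2.0] + 1e-9
    if volume_key == "edv_lv":
        assert errors[2.0] < 0.03


def test_respiratory_event_count_matches_rate(small_phantom):
    _, truth = small_phantom
    cfg = truth.config
    duration_s = cfg.frames_per_slice * cfg.frame_duration / 1000.0
    expected = int(duration_s * cfg.respiratory_rate / 60.0)
    for peaks in truth.peaks:
        assert expected - 1 <= len(peaks) <= expected + 1


def test_truth_event_lists_strictly_increase(small_phantom):
    _, truth = small_phantom
    for lists in (truth.peaks, truth.valleys, truth.ed_frames, truth.es_frames):
        for arr in lists:
            assert np.all(np.diff(arr) > 0)


def test_invalid_configs_rejected():
    with pytest.raises(ConfigError):  # ESV >= EDV
        generate_cine_phantom(small_config(esv_lv=80.0, edv_lv=70.0))
    with pytest.raises(ConfigError):  # cardiac cycle < 4 frames
        generate_cine_phantom(small_config(heart_rate=500.0))
    with pytest.raises(ConfigError):  # acquisition shorter than a breath
        generate_cine_phantom(small_config(frames_per_slice=60, respiratory_rate=15.0))


# ---------------------------------------------------------------------------
# flow phantom
# ---------------------------------------------------------------------------


def test_flow_phantom_no_regurgitation_has_zero_backward_truth():
    series, truth = generate_flow_phantom(small_config(), venc=150, peak_velocity=100)
    assert truth.backward_volume_ml == 0.0
    assert truth.forward_volume_ml > 0


def test_flow_phantom_below_venc_never_wraps():
    cfg = small_config(noise_sigma=0.0)
    series, truth = generate_flow_phantom(cfg, venc=150, peak_velocity=120)
    assert not truth.wrapped_mask.any()
    # recovered pixel-centre peak equals the programmed peak within voxelisation
    v = series.phase / np.pi * 150.0
    sampled_peak = v.max()
    r_min2 = 2.0 * (cfg.pixel_spacing / 2.0) ** 2  # nearest pixel centre to axis
    profile_at_centre = 120.0 * (1 - r_min2 / 12.0**2)
    frame_phase = (np.arange(30) + 0.5) / 30
    temporal_peak = np.max(np.sin(3 * np.pi * frame_phase[frame_phase < 1 / 3]))
    assert sampled_peak == pytest.approx(profile_at_centre * temporal_peak, rel=0.01)


def test_flow_phantom_wraps_exactly_above_venc():
    cfg = small_config(noise_sigma=0.0)
    series, truth = generate_flow_phantom(cfg, venc=150, peak_velocity=1.2 * 150)
    assert truth.wrapped_mask.any()
    # wrapped pixels are exactly those whose phase flipped sign
    apparent = series.phase / np.pi * 150.0
    flipped = (apparent < 0) & truth.roi_mask[None]
    assert np.array_equal(flipped.any(axis=0), truth.wrapped_mask.any(axis=0))


def test_flow_phantom_rejects_bad_parameters():
    cfg = small_config()
    with pytest.raises(ConfigError):
        generate_flow_phantom(cfg, venc=-1, peak_velocity=100)
    with pytest.raises(ConfigError):
        generate_flow_phantom(cfg, venc=150, peak_velocity=0)
    with pytest.raises(ConfigError):
        generate_flow_phantom(cfg, venc=150, peak_velocity=100, regurgitant_fraction=1.0)


# ---------------------------------------------------------------------------
# repeated-session cohort
# ---------------------------------------------------------------------------


def test_cohort_zero_within_noise_gives_identical_sessions():
    cohort = generate_repeatability_cohort(50, sigma_between=3.0, sigma_within=0.0,
                                           grand_mean=90.0, seed=0)
    assert np.array_equal(cohort.wide["session_1"], cohort.wide["session_2"])
    assert cohort.theoretical_cr == 0.0
    assert cohort.theoretical_icc == 1.0


def test_cohort_no_between_subject_variance_gives_near_zero_icc():
    from rtcine.stats import icc_a1

    cohort = generate_repeatability_cohort(10_000, sigma_between=0.0, sigma_within=1.0,
                                           grand_mean=90.0, seed=0)
    assert abs(icc_a1(cohort.matrix)) < 0.03
    assert cohort.theoretical_icc == 0.0
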