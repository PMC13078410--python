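"""Shared fixtures: scaled-down phantoms reused across the suite.

The validation phantoms use 6 slices with proportionally scaled chamber
volumes (so the chambers fit the shorter stack) while keeping the study
acquisition conditions: 300 frames/slice at 33 ms, ~15 breaths/min, default
noise and apical attenuation.
"""

from __future__ import annotations

import numpy as np
import pytest

from rtcine.navigator import (
    NavigatorLine,
    detect_respiratory_events,
    extract_navigator_trace,
)
from rtcine.phantom import PhantomConfig, default_navigator_line, generate_cine_phantom
from rtcine.sorting import SortingConfig, align_slices, select_cardiac_phases

SMALL = dict(
    n_slices=6,
    frames_per_slice=300,
    edv_lv=70.0,
    esv_lv=30.0,
    edv_rv=72.0,
    esv_rv=33.0,
)


def small_config(seed: int = 1, **overrides) -> PhantomConfig:
    params = {**SMALL, "seed": seed, **overrides}
    return PhantomConfig(**params)


def static_config(seed: int = 1, **overrides) -> PhantomConfig:
    """A short, motion-free, noise-free phantom for geometry-only tests."""
    params = dict(
        frames_per_slice=8,
        respiratory_rate=240.0,
        respiratory_amplitude=0.0,
        noise_sigma=0.0,
        seed=seed,
    )
    params.update(SMALL)
    params.update(overrides)
    params.setdefault("n_slices", 6)
    return PhantomConfig(**params)


def run_sort_chain(series, truth, window_half_width: int, phase: str = "expiration"):
    """Navigator -> events -> anchors -> windowed ED/ES selection, seeded from truth."""
    start, end = default_navigator_line(truth.config)
    trace = extract_navigator_trace(series, NavigatorLine(start, end))
    events = detect_respiratory_events(trace)
    cfg = SortingConfig(respiratory_phase=phase, window_half_width=window_half_width)
    anchors = align_slices(events, cfg)
    seeds = [
        truth.seed_pixel(k, int(anchors[k]), "LV") for k in range(series.n_slices)
    ]
    stack = select_cardiac_phases(series, anchors, cfg, seeds)
    return events, anchors, seeds, stack


@pytest.fixture(scope="session")
def small_phantom():
    """One scaled-down breathing phantom shared across tests (seed 1)."""
    return generate_cine_phantom(small_config(seed=1))


@pytest.fixture(scope="session")
def static_phantom():
    """Motion-free noiseless phantom for segmentation/volumetry geometry tests."""
    return generate_cine_phantom(static_config())


@pytest.fixture(scope="session")
def sorted_small_phantom(small_phantom):
    series, truth = small_phantom
    events, anchors, seeds, stack = run_sort_chain(series, truth, window_half_width=7)
    return series, truth, events, anchors, seeds, stack


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
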