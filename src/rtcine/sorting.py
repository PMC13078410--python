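"""Retrospective cardiac/respiratory frame sorting.

Given per-slice respiratory events, every slice is aligned to one
respiratory phase (its anchor frame), and the end-diastolic and end-systolic
frames are selected within a proximity window around the anchor: ED is the
frame maximising the blood-pool area, ES the frame minimising it.  The
default half-widths follow the acquisition stage: +/-7 frames (462 ms at
33 ms temporal resolution) at rest, +/-5 frames (330 ms) during exercise,
when the shorter cardiac cycle keeps a full beat within the narrower
window.  A manual override table reproduces an operator-driven workflow
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, NoRespiratoryEventsError
from .io_formats import RealTimeSeries
from .navigator import RespiratoryEvents
from .volumetry import segment_chamber

DEFAULT_WINDOW_REST = 7  # frames, -7..+7 = 462 ms at 33 ms/frame
DEFAULT_WINDOW_EXERCISE = 5  # frames, -5..+5 = 330 ms


@dataclass(frozen=True)
class SortingConfig:
    respiratory_phase: str = "expiration"  # or "inspiration"
    window_half_width: int = DEFAULT_WINDOW_REST
    cardiac_selection: str = "area-auto"  # or "manual-override"
    override_table: dict[int, tuple[int, int]] | None = None  # slice -> (ED, ES)

    def __post_init__(self):
        if self.window_half_width < 1:
            raise ConfigError("window_half_width must be >= 1")
        if self.respiratory_phase not in ("expiration", "inspiration"):
            raise ConfigError(f"unknown respiratory phase {self.respiratory_phase!r}")

    def window_span_ms(self, frame_duration_ms: float) -> float:
        """Temporal span of the proximity window: (2w) x frame duration."""
        return 2 * self.window_half_width * frame_duration_ms


@dataclass
class SliceSelection:
    slice_index: int
    anchor_frame: int
    ed_frame: int
    es_frame: int
    area_series_mm2: np.ndarray  # blood-pool area over the window frames
    window_frames: np.ndarray
    overridden: bool = False


@dataclass
class SortedStack:
    slices: list[SliceSelection]
    respiratory_phase: str

    def frame_table(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "slice": s.slice_index,
                    "anchor": s.anchor_frame,
                    "ed_frame": s.ed_frame,
                    "es_frame": s.es_frame,
                    "overridden": s.overridden,
                }
                for s in self.slices
            ]
        )


def align_slices(events: RespiratoryEvents, config: SortingConfig) -> np.ndarray:
    """Anchor frame per slice: the event of the requested respiratory phase
    nearest the temporal midpoint of that slice's acquisition."""
    per_slice = events.of_phase(config.respiratory_phase)
    mid = (events.frames_per_slice - 1) / 2.0
    anchors = np.empty(len(per_slice), dtype=int)
    missing = [k for k, ev in enumerate(per_slice) if len(ev) == 0]
    if missing:
        raise NoRespiratoryEventsError(missing)
    for k, ev in enumerate(per_slice):
        anchors[k] = int(ev[np.argmin(np.abs(ev - mid))])
    return anchors


def blood_pool_area(
    image: np.ndarray,
    seed: tuple[int, int],
    pixel_area_mm2: float,
    threshold_quantile: float = 0.5,
) -> tuple[float, bool]:
    """Area (mm^2) of the connected bright region grown from a chamber seed.

    Returns (area, flagged); a seed on background yields a zero-area flagged
    result.
    """
    result = segment_chamber(image, seed, threshold_quantile=threshold_quantile)
    return result.area_mm2(pixel_area_mm2), result.flagged


def select_cardiac_phases(
    series: RealTimeSeries,
    anchors: np.ndarray,
    config: SortingConfig,
    seed_points: list[tuple[int, int]],
    threshold_quantile: float = 0.5,
) -> SortedStack:
    """Pick ED/ES per slice within the proximity window around each anchor.

    ED maximises and ES minimises the blood-pool area over the window
    ``[anchor - w, anchor + w]`` (clipped at series bounds).  Ties resolve to
    the frame closer to the anchor, then to the earlier frame.  When a
    manual override table supplies (ED, ES) for a slice, it wins verbatim.
    """
    if len(anchors) != series.n_slices or len(seed_points) != series.n_slices:
        raise ConfigError("anchors and seed_points must cover every slice")
    w = config.window_half_width
    f = series.frames_per_slice
    selections = []
    for k in range(series.n_slices):
        anchor = int(anchors[k])
        lo, hi = max(0, anchor - w), min(f - 1, anchor + w)
        frames = np.arange(lo, hi + 1)
        if frames.size == 0:
            raise ConfigError(f"empty proximity window for slice {k}")
        override = (config.override_table or {}).get(k)
        measured = [
            blood_pool_area(
                series.voxels[k, j],
                seed_points[k],
                series.metadata.pixel_area,
                threshold_quantile,
            )
            for j in frames
        ]
        areas = np.array([a for a, _ in measured])
        flags = np.array([f for _, f in measured])
        if config.cardiac_selection == "manual-override" and override is None:
            raise ConfigError(f"manual-override selection but no override for slice {k}")
        if override is not None:
            ed, es = int(override[0]), int(override[1])
            selections.append(
                SliceSelection(k, anchor, ed, es, areas, frames, overridden=True)
            )
            continue
        # flagged frames (degenerate or leaking segmentations) cannot win the
        # area criterion unless every frame in the window is flagged
        valid = ~flags if not flags.all() else np.ones_like(flags)
        ed = _argbest(frames[valid], areas[valid], anchor, best="max")
        es = _argbest(frames[valid], areas[valid], anchor, best="min")
        selections.append(SliceSelection(k, anchor, ed, es, areas, frames))
    return SortedStack(slices=selections, respiratory_phase=config.respiratory_phase)


def _argbest(frames: np.ndarray, areas: np.ndarray, anchor: int, best: str) -> int:
    target = areas.max() if best == "max" else areas.min()
    candidates = frames[areas == target]
    dist = np.abs(candidates - anchor)
    candidates = candidates[dist == dist.min()]
    return int(candidates.min())  # earliest frame on a residual tie


__all__ = [
    "SortingConfig",
    "SortedStack",
    "SliceSelection",
    "align_slices",
    "blood_pool_area",
    "select_cardiac_phases",
    "DEFAULT_WINDOW_REST",
    "DEFAULT_WINDOW_EXERCISE",
]
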