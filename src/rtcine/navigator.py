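"""Respiratory self-gating from a navigator line.

A 1D line is placed over a moving tissue interface (diaphragm/liver or chest
wall); the mean image intensity sampled along that line, plotted against
frame index, traces the respiratory cycle of each slice.  Local maxima of
the trace mark end-expiration, local minima end-inspiration.  Slices with a
weak trace (typically apical, where respiratory motion is small) are flagged
low-confidence and inherit events propagated from the nearest reliable
slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from skimage.draw import line as draw_line

from .errors import ConfigError
from .io_formats import RealTimeSeries


@dataclass(frozen=True)
class NavigatorLine:
    """A line segment in pixel coordinates applied to every slice of a stack."""

    start: tuple[int, int]  # (row, col)
    end: tuple[int, int]

    def pixels(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = shape
        for r, c in (self.start, self.end):
            if not (0 <= r < rows and 0 <= c < cols):
                raise ConfigError(f"navigator endpoint {(r, c)} outside image {shape}")
        rr, cc = draw_line(self.start[0], self.start[1], self.end[0], self.end[1])
        return rr, cc


@dataclass
class NavigatorTrace:
    """Per-slice mean navigator intensity versus frame index."""

    signal: np.ndarray  # (n_slices, frames_per_slice)
    sampling_interval_ms: float

    def __post_init__(self):
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if not np.all(np.isfinite(self.signal)):
            raise ConfigError("navigator trace must be finite")

    @property
    def n_slices(self) -> int:
        return self.signal.shape[0]

    @property
    def n_frames(self) -> int:
        return self.signal.shape[1]


@dataclass
class RespiratoryEvents:
    """Detected end-expiration (peaks) and end-inspiration (valleys) frames."""

    peaks: list[np.ndarray]
    valleys: list[np.ndarray]
    confidence: list[str]  # "high" | "low" per slice
    frames_per_slice: int

    def of_phase(self, phase: str) -> list[np.ndarray]:
        if phase == "expiration":
            return self.peaks
        if phase == "inspiration":
            return self.valleys
        raise ConfigError(f"unknown respiratory phase {phase!r}")


def extract_navigator_trace(series: RealTimeSeries, line: NavigatorLine) -> NavigatorTrace:
    """Mean intensity along the rasterised line, per slice and frame."""
    rr, cc = line.pixels(series.voxels.shape[2:])
    signal = series.voxels[:, :, rr, cc].mean(axis=2)
    return NavigatorTrace(signal=signal, sampling_interval_ms=series.metadata.frame_duration)


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x.astype(float), pad, mode="reflect")
    return np.convolve(xp, kernel, mode="same")[pad : pad + len(x)]


def _refine_extremum(signal: np.ndarray, idx: int, halfwidth: int) -> int:
    """Relocate an extremum to the vertex of a local least-squares parabola.

    The raw argmax of a slowly varying trace jitters by several frames under
    noise (the extremum is locally flat); fitting a quadratic over a wide
    neighbourhood averages the noise down and recovers the true extremum to
    about a frame.
    """
    current = idx
    for _ in range(2):  # second pass recentres the window on the first vertex
        lo = max(0, current - halfwidth)
        hi = min(len(signal), current + halfwidth + 1)
        x = np.arange(lo, hi, dtype=float)
        if len(x) < 5:
            return current
        coeffs = np.polyfit(x - current, signal[lo:hi], 2)
        if coeffs[0] == 0:
            return current
        vertex = -coeffs[1] / (2.0 * coeffs[0])
        if not np.isfinite(vertex) or abs(vertex) > halfwidth:
            return current
        current = int(np.clip(round(current + vertex), 0, len(signal) - 1))
    return current


def _refine_harmonic(
    signal: np.ndarray, idx: int, omega: float, kind: str
) -> int:
    """Relocate an extremum by least-squares cosine fit at the breathing frequency.

    Fits ``a cos(omega t) + b sin(omega t) + c`` over one full period centred
    on the event and returns the analytic extremum (peak or valley) nearest
    the original detection.  Averaging over ~a period of samples reduces the
    frame jitter of weak (e.g. apical) traces well below one frame.
    """
    period = 2.0 * np.pi / omega
    hw = int(round(period))  # one full period either side of the event
    lo = max(0, idx - hw)
    hi = min(len(signal), idx + hw + 1)
    t = np.arange(lo, hi, dtype=float)
    if len(t) < 8:
        return idx
    design = np.column_stack([np.cos(omega * t), np.sin(omega * t), np.ones_like(t)])
    (a, b, _), *_ = np.linalg.lstsq(design, signal[lo:hi], rcond=None)
    amplitude = np.hypot(a, b)
    if amplitude == 0:
        return idx
    phi = np.arctan2(b, a)  # fitted signal = R cos(omega t - phi) + c
    target = phi if kind == "p" else phi + np.pi
    m = np.round((omega * idx - target) / (2.0 * np.pi))
    t_star = (target + 2.0 * np.pi * m) / omega
    if not np.isfinite(t_star) or abs(t_star - idx) > hw:
        return idx
    return int(np.clip(round(t_star), 0, len(signal) - 1))


def _enforce_alternation(
    peaks: np.ndarray, valleys: np.ndarray, trace: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Keep the most extreme event of each same-type run so peaks and valleys
    strictly alternate; plateau ties resolve to the earliest frame."""
    events = [(int(f), "p") for f in peaks] + [(int(f), "v") for f in valleys]
    events.sort()
    kept: list[tuple[int, str]] = []
    for f, kind in events:
        if kept and kept[-1][1] == kind:
            prev = kept[-1][0]
            if kind == "p":
                better = trace[f] > trace[prev]
            else:
                better = trace[f] < trace[prev]
            if better:
                kept[-1] = (f, kind)
        else:
            kept.append((f, kind))
    new_peaks = np.array([f for f, k in kept if k == "p"], dtype=int)
    new_valleys = np.array([f for f, k in kept if k == "v"], dtype=int)
    return new_peaks, new_valleys


def detect_respiratory_events(
    trace: NavigatorTrace,
    smooth_window: int = 5,
    min_prominence: float = 0.2,
    min_separation_s: float = 1.0,
) -> RespiratoryEvents:
    """Detect respiratory extrema in every slice of a navigator trace.

    The trace is moving-average smoothed (default 5 frames, 165 ms at 33 ms
    temporal resolution -- enough to suppress cardiac-frequency ripple while
    preserving respiratory extremes), then peaks/valleys are found with a
    prominence gate of ``min_prominence`` times the per-slice trace range and
    a minimum separation of ``min_separation_s``.  A slice whose smoothed
    trace range falls below ``min_prominence`` times the median range across
    slices is marked low-confidence: its own trace is considered unreliable
    and events are propagated from the nearest high-confidence slice by
    periodic extension of that slice's event times (shifted by the
    inter-slice acquisition offset).
    """
    if trace.n_frames < 3:
        raise ConfigError("trace must have at least 3 frames")
    if smooth_window < 1:
        raise ConfigError("smooth_window must be >= 1")
    dt_s = trace.sampling_interval_ms / 1000.0
    distance = max(1, int(round(min_separation_s / dt_s)))

    smoothed = np.vstack([_smooth(trace.signal[k], smooth_window) for k in range(trace.n_slices)])
    # candidate extrema (and the confidence gate) use a heavier low-pass at
    # the respiratory time scale: it keeps noise bumps below the prominence
    # gate on weak traces and keeps noise from inflating the trace range of
    # slices with little respiratory signal.  Event positions are then
    # refined on the lightly smoothed trace.
    coarse_all = np.vstack(
        [_smooth(smoothed[k], max(smooth_window, distance // 3)) for k in range(trace.n_slices)]
    )
    ranges = coarse_all.max(axis=1) - coarse_all.min(axis=1)
    median_range = float(np.median(ranges))
    low = ranges < min_prominence * median_range if median_range > 0 else ranges >= 0

    candidates: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    all_spacings: list[np.ndarray] = []
    for k in range(trace.n_slices):
        if low[k]:
            continue
        coarse = coarse_all[k]
        prom = min_prominence * ranges[k]
        p, _ = find_peaks(coarse, prominence=prom, distance=distance)
        v, _ = find_peaks(-coarse, prominence=prom, distance=distance)
        p, v = _enforce_alternation(p, v, coarse)
        candidates[k] = (p, v)
        if len(p) > 1:
            all_spacings.append(np.diff(p))
        if len(v) > 1:
            all_spacings.append(np.diff(v))
    # the respiratory period is shared across the sequentially acquired stack;
    # pooling the inter-event spacings gives a far more stable estimate than
    # the 1-3 spacings any single slice provides
    pooled = np.concatenate(all_spacings) if all_spacings else np.array([])

    peaks_per_slice: list[np.ndarray] = []
    valleys_per_slice: list[np.ndarray] = []
    confidence: list[str] = []
    for k in range(trace.n_slices):
        if low[k]:
            peaks_per_slice.append(np.array([], dtype=int))
            valleys_per_slice.append(np.array([], dtype=int))
            confidence.append("low")
            continue
        p, v = candidates[k]
        if pooled.size:
            omega = 2.0 * np.pi / float(np.median(pooled))
            for _ in range(2):  # second pass refines with recentred windows
                p = np.array(
                    sorted({_refine_harmonic(smoothed[k], i, omega, "p") for i in p}), dtype=int
                )
                v = np.array(
                    sorted({_refine_harmonic(smoothed[k], i, omega, "v") for i in v}), dtype=int
                )
        else:
            refine_hw = max(2, distance)
            p = np.array(
                sorted({_refine_extremum(smoothed[k], i, refine_hw) for i in p}), dtype=int
            )
            v = np.array(
                sorted({_refine_extremum(-smoothed[k], i, refine_hw) for i in v}), dtype=int
            )
        p, v = _enforce_alternation(p, v, smoothed[k])
        peaks_per_slice.append(p)
        valleys_per_slice.append(v)
        confidence.append("high")

    events = RespiratoryEvents(
        peaks=peaks_per_slice,
        valleys=valleys_per_slice,
        confidence=confidence,
        frames_per_slice=trace.n_frames,
    )
    _propagate_to_low_confidence(events)
    return events


def _propagate_to_low_confidence(events: RespiratoryEvents) -> None:
    """Fill event lists of low-confidence slices from the nearest high-confidence
    slice, extending its events periodically (median inter-event interval)
    across the sequential acquisition timeline."""
    high = [k for k, c in enumerate(events.confidence) if c == "high"]
    if not high:
        return
    f = events.frames_per_slice
    for k, conf in enumerate(events.confidence):
        if conf == "high":
            continue
        ref = min(high, key=lambda h: abs(h - k))
        for attr in ("peaks", "valleys"):
            ref_events = getattr(events, attr)[ref]
            if len(ref_events) == 0:
                continue
            if len(ref_events) >= 2:
                period = float(np.median(np.diff(ref_events)))
            else:
                continue  # cannot extrapolate a period from a single event
            # global frame index of reference events, extended periodically
            g0 = ref * f + float(ref_events[0])
            lo, hi = k * f, k * f + f - 1
            n_lo = int(np.floor((lo - g0) / period)) - 1
            n_hi = int(np.ceil((hi - g0) / period)) + 1
            frames = []
            for n in range(n_lo, n_hi + 1):
                j = int(round(g0 + n * period)) - k * f
                if 0 <= j < f:
                    frames.append(j)
            getattr(events, attr)[k] = np.array(sorted(set(frames)), dtype=int)
        # re-impose alternation on the propagated lists
        p, v = events.peaks[k], events.valleys[k]
        merged = sorted([(int(x), "p") for x in p] + [(int(x), "v") for x in v])
        keep_p, keep_v, last = [], [], None
        for frame, kind in merged:
            if kind == last:
                continue
            (keep_p if kind == "p" else keep_v).append(frame)
            last = kind
        events.peaks[k] = np.array(keep_p, dtype=int)
        events.valleys[k] = np.array(keep_v, dtype=int)


__all__ = [
    "NavigatorLine",
    "NavigatorTrace",
    "RespiratoryEvents",
    "extract_navigator_trace",
    "detect_respiratory_events",
]
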