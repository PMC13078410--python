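"""Aortic flow quantification from 2D phase-contrast series.

Velocity is encoded in image phase: v = venc * phase / pi, with venc the
velocity mapped to +/-pi.  The flow curve through a region of interest is
the velocity integral over the ROI area per frame; integrating the positive
and negative parts over one cardiac cycle gives forward and backward flow
volumes, and the descending/ascending aorta net-flow ratio indexes the
fraction of output directed to the lower body.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, label as nd_label

from .errors import ConfigError, DataError, MissingVencError
from .io_formats import FlowSeries


@dataclass
class FlowROI:
    """A labelled vessel ROI: one static mask applied to all frames, or a
    (frame, row, col) stack of per-frame masks."""

    label: str  # "aAo" | "dAo"
    mask: np.ndarray
    sign: int = 1  # +1 | -1: positive through-plane flow direction

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.sign not in (1, -1):
            raise ConfigError("sign must be +1 or -1")
        if self.mask.ndim not in (2, 3):
            raise ConfigError("mask must be 2D (static) or 3D (per-frame)")
        if self.mask.ndim == 2 and self.mask.sum() == 0:
            raise DataError("ROI mask is empty")

    def frame_mask(self, frame: int) -> np.ndarray:
        m = self.mask if self.mask.ndim == 2 else self.mask[frame]
        if m.sum() == 0:
            raise DataError(f"ROI mask empty at frame {frame}")
        return m


def phase_to_velocity(
    phase: np.ndarray,
    venc: float,
    roi: np.ndarray | None = None,
    unwrap: bool = False,
) -> np.ndarray:
    """Map phase (radians, (-pi, pi]) to velocity in cm/s: v = venc * phase / pi.

    With ``unwrap`` and an ROI, a single wrap is corrected inside the ROI:
    pixels whose sign opposes the dominant ROI flow direction, whose phase
    magnitude exceeds 0.8 pi, and which abut near-limit pixels of the
    dominant sign are shifted by 2 pi toward the dominant direction.  Pixels
    with |phase| < 0.8 pi are never altered.
    """
    if venc is None or venc <= 0:
        raise MissingVencError("venc must be a positive velocity limit in cm/s")
    phase = np.asarray(phase, dtype=float)
    corrected = phase.copy()
    if unwrap and roi is not None:
        roi = np.asarray(roi, dtype=bool)
        frames = corrected[None] if corrected.ndim == 2 else corrected
        for frame in frames:
            inside = frame[roi]
            if inside.size == 0:
                continue
            dominant = np.sign(inside.sum())
            if dominant == 0:
                continue
            near_limit = roi & (np.abs(frame) > 0.8 * np.pi)
            opposing = near_limit & (np.sign(frame) == -dominant)
            support = binary_dilation(near_limit & (np.sign(frame) == dominant))
            # correct whole connected clusters of opposing-sign pixels that
            # abut the +/-venc boundary, not just their outermost ring
            labels, n_components = nd_label(opposing)
            wrapped = np.zeros_like(opposing)
            for lab in range(1, n_components + 1):
                component = labels == lab
                if (component & support).any():
                    wrapped |= component
            frame[wrapped] += 2.0 * np.pi * dominant
        corrected = frames[0] if corrected.ndim == 2 else frames
    return venc * corrected / np.pi


def flow_curve(
    velocity: np.ndarray, roi: FlowROI, pixel_area_mm2: float
) -> np.ndarray:
    """Q(t) in mL/s: sign * sum over ROI pixels of v (cm/s) * pixel area (mm^2).

    1 cm/s over 1 mm^2 is 0.01 mL/s.
    """
    velocity = np.asarray(velocity, dtype=float)
    if velocity.ndim != 3:
        raise ConfigError("velocity must be a (frame, row, col) stack")
    q = np.empty(velocity.shape[0])
    for j in range(velocity.shape[0]):
        m = roi.frame_mask(j)
        q[j] = roi.sign * velocity[j][m].sum() * pixel_area_mm2 * 0.01
    return q


@dataclass
class FlowResult:
    label: str
    q_ml_s: np.ndarray  # flow curve over the cycle
    forward_ml: float  # per cycle
    backward_ml: float  # per cycle, positive magnitude
    net_ml: float  # forward - backward

    def __post_init__(self):
        assert np.isclose(self.net_ml, self.forward_ml - self.backward_ml)


def flow_volumes(q_ml_s: np.ndarray, frame_duration_ms: float, label: str = "aAo") -> FlowResult:
    """Integrate a one-cycle flow curve into forward/backward/net volumes (mL)."""
    if frame_duration_ms <= 0:
        raise ConfigError("frame duration must be > 0")
    q = np.asarray(q_ml_s, dtype=float)
    dt_s = frame_duration_ms / 1000.0
    forward = float(np.clip(q, 0.0, None).sum() * dt_s)
    backward = float(np.clip(-q, 0.0, None).sum() * dt_s)
    return FlowResult(
        label=label, q_ml_s=q, forward_ml=forward, backward_ml=backward,
        net_ml=forward - backward,
    )


def dao_aao_ratio(net_dao_ml: float, net_aao_ml: float) -> float:
    """Net descending-to-ascending aortic flow ratio; requires aAo net > 0."""
    if net_aao_ml <= 0:
        raise DataError("dAo/aAo ratio undefined for nonpositive ascending net flow")
    return net_dao_ml / net_aao_ml


def quantify_flow(
    series: FlowSeries,
    roi: FlowROI,
    unwrap: bool = False,
    background_mask: np.ndarray | None = None,
) -> FlowResult:
    """End-to-end quantification of one ROI in a flow series.

    Optionally subtracts a constant background-phase (eddy-current) offset
    estimated as the mean velocity within a user-supplied static-tissue mask.
    """
    static_roi = roi.mask if roi.mask.ndim == 2 else roi.mask.any(axis=0)
    velocity = phase_to_velocity(series.phase, series.metadata.venc, roi=static_roi, unwrap=unwrap)
    if background_mask is not None:
        bg = np.asarray(background_mask, dtype=bool)
        velocity = velocity - velocity[:, bg].mean()
    q = flow_curve(velocity, roi, series.metadata.pixel_area)
    return flow_volumes(q, series.metadata.frame_duration, label=roi.label)


__all__ = [
    "FlowROI",
    "FlowResult",
    "phase_to_velocity",
    "flow_curve",
    "flow_volumes",
    "dao_aao_ratio",
    "quantify_flow",
]
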