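"""Synthetic beating-and-breathing phantoms with programmed ground truth.

The cine phantom emulates a free-breathing, sequentially acquired real-time
short-axis stack: two ventricular chambers modelled as truncated-ellipsoid
shells whose cavities oscillate between end-diastolic and end-systolic
volumes at the programmed heart rate, embedded in a torso (soft tissue,
lungs, bright subdiaphragmatic liver) that translates along the
superior-inferior axis with respiration.  Slice k's frames are acquired at
global times ``(k * frames_per_slice + j) * frame_duration``, so the
respiratory phase is not synchronised across slices -- exactly the
misalignment the retrospective sorting stage must undo.

The respiratory excursion is tapered linearly from the base to the apex of
the stack, mimicking the weak navigator signal of apical slices, and every
generated series comes with a :class:`PhantomTruth` holding the analytic
volume waveforms, true respiratory event frames, true ED/ES frames, and
rasterised truth masks.

All lengths are mm, times ms (durations) or s (waveforms), volumes mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_formats import FlowSeries, RealTimeSeries, SeriesMetadata

# Tissue intensity levels (arbitrary units, blood-normalised bright-blood contrast)
INTENSITY = {
    "air": 0.05,
    "tissue": 0.30,
    "lung": 0.12,
    "liver": 0.80,
    "myocardium": 0.45,
    "blood": 1.00,
}

LV_WALL_MM = 9.0
RV_WALL_MM = 4.0
RV_SEMI_AXIS_X_MM = 40.0  # fixed septal-to-free-wall in-plane half width
LONG_AXIS_FRACTION = 0.98  # LV long axis as a fraction of the stack coverage
# (the stack is planned to cover the whole heart, so the apex falls just
# inside the most apical slice, which keeps a small cavity cross-section)
RV_LONG_AXIS_FRACTION = 0.8
SYSTOLIC_FRACTION = 1.0 / 3.0  # systole occupies the first third of the R-R interval
LIVER_INTERFACE_Y_MM = 48.0  # nominal lung-liver interface position (inferior > 0)


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the cine phantom; defaults reproduce the study conditions
    (free-breathing real-time acquisition: 300 frames/slice at 33 ms, 10 mm
    contiguous slices, resting heart rate 56 beats/min, ~15 breaths/min)."""

    heart_rate: float = 56.0  # beats/min
    respiratory_rate: float = 15.0  # breaths/min
    n_slices: int = 15
    frames_per_slice: int = 300
    frame_duration: float = 33.0  # ms
    matrix_size: tuple[int, int] = (88, 72)  # rows x cols
    pixel_spacing: float = 2.0  # mm, isotropic in-plane
    slice_thickness: float = 10.0  # mm
    slice_gap: float = 0.0  # mm
    edv_lv: float = 170.0  # mL
    esv_lv: float = 72.0
    edv_rv: float = 172.0
    esv_rv: float = 80.0
    respiratory_amplitude: float = 8.0  # mm peak superior-inferior translation
    apical_signal_attenuation: float = 0.2  # respiratory amplitude factor at the apex
    noise_sigma: float = 0.05  # fraction of blood signal
    seed: int = 0

    def validate(self) -> None:
        if self.heart_rate <= 0 or self.respiratory_rate <= 0:
            raise ConfigError("heart_rate and respiratory_rate must be > 0")
        if not (0 <= self.esv_lv < self.edv_lv) or not (0 <= self.esv_rv < self.edv_rv):
            raise ConfigError("each ventricle requires 0 <= ESV < EDV")
        if not (0 <= self.apical_signal_attenuation <= 1):
            raise ConfigError("apical_signal_attenuation must lie in [0, 1]")
        if self.respiratory_amplitude < 0 or self.noise_sigma < 0:
            raise ConfigError("respiratory_amplitude and noise_sigma must be >= 0")
        if self.n_slices < 1 or self.frames_per_slice < 2:
            raise ConfigError("need at least 1 slice and 2 frames per slice")
        acq_s = self.frames_per_slice * self.frame_duration / 1000.0
        if acq_s < 60.0 / self.respiratory_rate:
            raise ConfigError(
                "frames_per_slice x frame_duration must cover at least one respiratory cycle"
            )
        frames_per_beat = 60.0 / self.heart_rate * 1000.0 / self.frame_duration
        if frames_per_beat < 4:
            raise ConfigError(
                f"cardiac cycle spans only {frames_per_beat:.1f} frames (< 4): "
                "ED and ES would be indistinguishable"
            )

    @property
    def slab(self) -> float:
        return self.slice_thickness + self.slice_gap

    def metadata(self) -> SeriesMetadata:
        return SeriesMetadata(
            frame_duration=self.frame_duration,
            pixel_spacing=(self.pixel_spacing, self.pixel_spacing),
            slice_thickness=self.slice_thickness,
            slice_gap=self.slice_gap,
            n_slices=self.n_slices,
            frames_per_slice=self.frames_per_slice,
        )


def volume_waveform_fraction(phase: np.ndarray) -> np.ndarray:
    """Normalised contraction w(phase) in [0, 1]: 0 at ED (phase 0), 1 at ES.

    Raised-cosine systole over the first third of the R-R interval, raised-
    cosine diastolic refilling over the remainder; smooth with unambiguous
    extremes.
    """
    s = SYSTOLIC_FRACTION
    ph = np.mod(phase, 1.0)
    return np.where(
        ph < s,
        0.5 * (1.0 - np.cos(np.pi * ph / s)),
        0.5 * (1.0 + np.cos(np.pi * (ph - s) / (1.0 - s))),
    )


class _Geometry:
    """Analytic scene model shared by the rasteriser and the truth object."""

    def __init__(self, cfg: PhantomConfig):
        self.cfg = cfg
        rows, cols = cfg.matrix_size
        ps = cfg.pixel_spacing
        coverage = cfg.n_slices * cfg.slab
        self.c_lv = LONG_AXIS_FRACTION * coverage
        self.c_lv_epi = self.c_lv + LV_WALL_MM
        self.c_rv = RV_LONG_AXIS_FRACTION * coverage
        self.c_rv_epi = self.c_rv + RV_WALL_MM

        # half-ellipsoid: V = (2/3) pi a^2 c  (circular LV cross-section)
        self.a_lv_ed = np.sqrt(3.0 * cfg.edv_lv * 1000.0 / (2.0 * np.pi * self.c_lv))
        self.a_lv_epi = self.a_lv_ed + LV_WALL_MM
        # RV: flattened half-ellipsoid, V = (2/3) pi ax ay c with ax fixed
        self.rv_ax = RV_SEMI_AXIS_X_MM
        self.rv_ay_ed = cfg.edv_rv * 1000.0 * 3.0 / (2.0 * np.pi * self.rv_ax * self.c_rv)
        self.rv_ay_epi = self.rv_ay_ed + RV_WALL_MM

        self.lv_center = (0.0, 18.0)  # (y, x) mm
        self.rv_center = (
            -(self.a_lv_epi + self.rv_ay_ed + RV_WALL_MM + 2.0),
            self.lv_center[1] - 10.0,
        )

        # pixel-centre and 2x-supersampled coordinate grids (mm)
        self.y_px = (np.arange(rows) - (rows - 1) / 2.0) * ps
        self.x_px = (np.arange(cols) - (cols - 1) / 2.0) * ps
        self.y_sub = ((np.arange(2 * rows) + 0.5) / 2.0 - 0.5 - (rows - 1) / 2.0) * ps
        self.x_sub = ((np.arange(2 * cols) + 0.5) / 2.0 - 0.5 - (cols - 1) / 2.0) * ps
        self.Ys, self.Xs = np.meshgrid(self.y_sub, self.x_sub, indexing="ij")

    def lv_cavity_radius(self, volume_ml: float) -> float:
        return np.sqrt(3.0 * volume_ml * 1000.0 / (2.0 * np.pi * self.c_lv))

    def rv_cavity_ay(self, volume_ml: float) -> float:
        return volume_ml * 1000.0 * 3.0 / (2.0 * np.pi * self.rv_ax * self.c_rv)

    @staticmethod
    def _zscale(z: float, c: float) -> float:
        return float(np.sqrt(max(0.0, 1.0 - (z / c) ** 2)))

    def slice_z(self, k: int) -> float:
        return (k + 0.5) * self.cfg.slab

    def wall_volume_lv_ml(self) -> float:
        """Analytic LV myocardial shell volume (fixed epicardial surface)."""
        v_epi = (2.0 / 3.0) * np.pi * self.a_lv_epi**2 * self.c_lv_epi
        v_endo = (2.0 / 3.0) * np.pi * self.a_lv_ed**2 * self.c_lv
        return (v_epi - v_endo) / 1000.0

    def _ellipse(self, cy, cx, ay, ax):
        if ay <= 0 or ax <= 0:
            return np.zeros_like(self.Ys, dtype=bool)
        return ((self.Ys - cy) / ay) ** 2 + ((self.Xs - cx) / ax) ** 2 <= 1.0

    def _structures(self, k: int, v_lv_ml: float, v_rv_ml: float, shift: float):
        """Boolean masks on the supersampled grid for one slice/frame."""
        z = self.slice_z(k)
        d = shift
        torso = self._ellipse(-d, 0.0, 80.0, 66.0)
        lungs = self._ellipse(-48.0 - d, 42.0, 26.0, 18.0) | self._ellipse(
            -48.0 - d, -42.0, 26.0, 18.0
        )
        liver = (self.Ys >= LIVER_INTERFACE_Y_MM - d) & torso

        s_lv = self._zscale(z, self.c_lv)
        s_lv_epi = self._zscale(z, self.c_lv_epi)
        s_rv = self._zscale(z, self.c_rv)
        s_rv_epi = self._zscale(z, self.c_rv_epi)

        a_lv = self.lv_cavity_radius(v_lv_ml)
        rv_ay = self.rv_cavity_ay(v_rv_ml)

        lv_cav = self._ellipse(self.lv_center[0] - d, self.lv_center[1], a_lv * s_lv, a_lv * s_lv)
        lv_epi = self._ellipse(
            self.lv_center[0] - d,
            self.lv_center[1],
            self.a_lv_epi * s_lv_epi,
            self.a_lv_epi * s_lv_epi,
        )
        rv_cav = self._ellipse(
            self.rv_center[0] - d, self.rv_center[1], rv_ay * s_rv, self.rv_ax * s_rv
        )
        rv_epi = self._ellipse(
            self.rv_center[0] - d,
            self.rv_center[1],
            self.rv_ay_epi * s_rv_epi,
            (self.rv_ax + RV_WALL_MM) * s_rv_epi,
        )
        return torso, lungs, liver, lv_cav, lv_epi, rv_cav, rv_epi

    def render(self, k: int, v_lv_ml: float, v_rv_ml: float, shift: float) -> np.ndarray:
        """Noise-free frame at pixel resolution (2x2 supersampled partial volume)."""
        torso, lungs, liver, lv_cav, lv_epi, rv_cav, rv_epi = self._structures(
            k, v_lv_ml, v_rv_ml, shift
        )
        img = np.full(self.Ys.shape, INTENSITY["air"], dtype=np.float32)
        img[torso] = INTENSITY["tissue"]
        img[lungs] = INTENSITY["lung"]
        img[liver] = INTENSITY["liver"]
        img[rv_epi] = INTENSITY["myocardium"]
        img[rv_cav] = INTENSITY["blood"]
        img[lv_epi] = INTENSITY["myocardium"]
        img[lv_cav] = INTENSITY["blood"]
        rows, cols = self.cfg.matrix_size
        return img.reshape(rows, 2, cols, 2).mean(axis=(1, 3))

    def mask(self, k: int, v_lv_ml: float, v_rv_ml: float, shift: float, which: str) -> np.ndarray:
        """Rasterised truth mask (pixel counted if >= half covered)."""
        torso, lungs, liver, lv_cav, lv_epi, rv_cav, rv_epi = self._structures(
            k, v_lv_ml, v_rv_ml, shift
        )
        sel = {"lv_endo": lv_cav, "lv_epi": lv_epi, "rv_endo": rv_cav, "rv_epi": rv_epi}[which]
        rows, cols = self.cfg.matrix_size
        frac = sel.reshape(rows, 2, cols, 2).mean(axis=(1, 3))
        return frac >= 0.5


@dataclass
class PhantomTruth:
    """Programmed ground truth accompanying a generated phantom series."""

    config: PhantomConfig
    peaks: list[np.ndarray]  # per-slice end-expiration frame indices
    valleys: list[np.ndarray]  # per-slice end-inspiration frame indices
    ed_frames: list[np.ndarray]  # per-slice true end-diastolic frame indices
    es_frames: list[np.ndarray]  # per-slice true end-systolic frame indices
    lv_volume: np.ndarray  # (n_slices, frames_per_slice) mL
    rv_volume: np.ndarray
    resp_shift_mm: np.ndarray  # (n_slices, frames_per_slice)
    wall_volume_lv_ml: float
    forward_volume_ml: float | None = None  # flow phantoms only
    backward_volume_ml: float | None = None
    peak_velocity_cm_s: float | None = None
    roi_mask: np.ndarray | None = None
    wrapped_mask: np.ndarray | None = None
    _geom: _Geometry | None = field(default=None, repr=False)

    # ---- helpers -----------------------------------------------------------
    def seed_pixel(self, slice_index: int, frame_index: int, ventricle: str = "LV"):
        """(row, col) pixel at the chamber centre of a given slice/frame."""
        g = self._geom
        cy, cx = g.lv_center if ventricle.upper() == "LV" else g.rv_center
        d = self.resp_shift_mm[slice_index, frame_index]
        rows, cols = self.config.matrix_size
        ps = self.config.pixel_spacing
        row = int(round((cy - d) / ps + (rows - 1) / 2.0))
        col = int(round(cx / ps + (cols - 1) / 2.0))
        return row, col

    def cavity_mask(self, slice_index: int, frame_index: int, ventricle: str = "LV"):
        g = self._geom
        which = "lv_endo" if ventricle.upper() == "LV" else "rv_endo"
        return g.mask(
            slice_index,
            self.lv_volume[slice_index, frame_index],
            self.rv_volume[slice_index, frame_index],
            self.resp_shift_mm[slice_index, frame_index],
            which,
        )

    def reference_masks(self, volume_ml: float, ventricle: str = "LV") -> list[np.ndarray]:
        """Per-slice rasterised cavity masks at a prescribed cavity volume,
        without respiratory shift (a synchronous reference stack, as if every
        slice were captured at the same cardiac phase)."""
        g = self._geom
        which = "lv_endo" if ventricle.upper() == "LV" else "rv_endo"
        v_lv = volume_ml if ventricle.upper() == "LV" else self.config.edv_lv
        v_rv = volume_ml if ventricle.upper() == "RV" else self.config.edv_rv
        return [g.mask(k, v_lv, v_rv, 0.0, which) for k in range(self.config.n_slices)]

    def reference_epicardial_masks(self) -> list[np.ndarray]:
        """Per-slice rasterised LV epicardial masks (fixed outer surface)."""
        g = self._geom
        return [
            g.mask(k, self.config.edv_lv, self.config.edv_rv, 0.0, "lv_epi")
            for k in range(self.config.n_slices)
        ]

    def epicardial_mask(self, slice_index: int, frame_index: int):
        g = self._geom
        return g.mask(
            slice_index,
            self.lv_volume[slice_index, frame_index],
            self.rv_volume[slice_index, frame_index],
            self.resp_shift_mm[slice_index, frame_index],
            "lv_epi",
        )


def default_navigator_line(config: PhantomConfig):
    """A navigator line crossing the lung-liver interface, away from the heart."""
    rows, cols = config.matrix_size
    ps = config.pixel_spacing
    a = config.respiratory_amplitude
    y0 = LIVER_INTERFACE_Y_MM - a - 6.0
    y1 = LIVER_INTERFACE_Y_MM + a + 8.0
    x = -20.0  # medial enough that the elliptical torso spans the line at all shifts
    r0 = int(np.clip(round(y0 / ps + (rows - 1) / 2.0), 0, rows - 1))
    r1 = int(np.clip(round(y1 / ps + (rows - 1) / 2.0), 0, rows - 1))
    c = int(np.clip(round(x / ps + (cols - 1) / 2.0), 0, cols - 1))
    return (r0, c), (r1, c)


def _event_frames(config: PhantomConfig, slice_index: int, phase_offset: float) -> np.ndarray:
    """Frames of slice k where the respiratory sinusoid attains the extremum at
    angle ``phase_offset`` (pi/2 for peaks, 3 pi/2 for valleys)."""
    omega = 2.0 * np.pi * config.respiratory_rate / 60.0
    dt = config.frame_duration / 1000.0
    f = config.frames_per_slice
    t0, t1 = slice_index * f * dt, (slice_index * f + f - 1) * dt
    m_lo = int(np.floor((omega * t0 - phase_offset) / (2 * np.pi))) - 1
    m_hi = int(np.ceil((omega * t1 - phase_offset) / (2 * np.pi))) + 1
    out = []
    for m in range(m_lo, m_hi + 1):
        t = (phase_offset + 2 * np.pi * m) / omega
        j = int(round(t / dt)) - slice_index * f
        if 0 <= j < f:
            out.append(j)
    return np.array(sorted(set(out)), dtype=int)


def _cardiac_frames(config: PhantomConfig, slice_index: int, phase: float) -> np.ndarray:
    """Frames of slice k nearest the cardiac phase ``phase`` (0 = ED, 1/3 = ES)."""
    t_rr = 60.0 / config.heart_rate
    dt = config.frame_duration / 1000.0
    f = config.frames_per_slice
    t0, t1 = slice_index * f * dt, (slice_index * f + f - 1) * dt
    m_lo = int(np.floor(t0 / t_rr)) - 1
    m_hi = int(np.ceil(t1 / t_rr)) + 1
    out = []
    for m in range(m_lo, m_hi + 1):
        t = (m + phase) * t_rr
        j = int(round(t / dt)) - slice_index * f
        if 0 <= j < f:
            out.append(j)
    return np.array(sorted(set(out)), dtype=int)


def generate_cine_phantom(config: PhantomConfig) -> tuple[RealTimeSeries, PhantomTruth]:
    """Generate a sequential-slice free-breathing real-time cine stack with truth.

    Seeded generation is reproducible bit-for-bit.
    """
    config.validate()
    geom = _Geometry(config)
    rng = np.random.default_rng(config.seed)
    k_n, f_n = config.n_slices, config.frames_per_slice
    rows, cols = config.matrix_size
    dt = config.frame_duration / 1000.0

    if k_n > 1:
        taper = 1.0 + (config.apical_signal_attenuation - 1.0) * np.arange(k_n) / (k_n - 1)
    else:
        taper = np.ones(1)

    times = (np.arange(k_n)[:, None] * f_n + np.arange(f_n)[None, :]) * dt
    omega = 2.0 * np.pi * config.respiratory_rate / 60.0
    shift = config.respiratory_amplitude * taper[:, None] * np.sin(omega * times)

    w = volume_waveform_fraction(times * config.heart_rate / 60.0)
    lv_vol = config.edv_lv - (config.edv_lv - config.esv_lv) * w
    rv_vol = config.edv_rv - (config.edv_rv - config.esv_rv) * w

    voxels = np.empty((k_n, f_n, rows, cols), dtype=np.float32)
    for k in range(k_n):
        for j in range(f_n):
            voxels[k, j] = geom.render(k, lv_vol[k, j], rv_vol[k, j], shift[k, j])
    if config.noise_sigma > 0:
        voxels += rng.normal(
            0.0, config.noise_sigma * INTENSITY["blood"], voxels.shape
        ).astype(np.float32)

    has_resp = config.respiratory_amplitude * taper > 0
    peaks = [
        _event_frames(config, k, np.pi / 2) if has_resp[k] else np.array([], dtype=int)
        for k in range(k_n)
    ]
    valleys = [
        _event_frames(config, k, 3 * np.pi / 2) if has_resp[k] else np.array([], dtype=int)
        for k in range(k_n)
    ]
    ed = [_cardiac_frames(config, k, 0.0) for k in range(k_n)]
    es = [_cardiac_frames(config, k, SYSTOLIC_FRACTION) for k in range(k_n)]

    truth = PhantomTruth(
        config=config,
        peaks=peaks,
        valleys=valleys,
        ed_frames=ed,
        es_frames=es,
        lv_volume=lv_vol,
        rv_volume=rv_vol,
        resp_shift_mm=shift,
        wall_volume_lv_ml=geom.wall_volume_lv_ml(),
        _geom=geom,
    )
    return RealTimeSeries(voxels=voxels, metadata=config.metadata()), truth


# ---------------------------------------------------------------------------
# Phase-contrast flow phantom
# ---------------------------------------------------------------------------


def generate_flow_phantom(
    config: PhantomConfig,
    venc: float,
    peak_velocity: float,
    regurgitant_fraction: float = 0.0,
    vessel_radius_mm: float = 12.0,
    frames_per_cycle: int = 30,
) -> tuple[FlowSeries, PhantomTruth]:
    """Circular vessel with a parabolic through-plane velocity profile.

    The temporal waveform has a sinusoidal systolic forward lobe over the
    first third of the cycle and, when ``regurgitant_fraction > 0``, an
    early-diastolic backward lobe scaled so backward/forward volume equals
    the requested fraction.  Phase is velocity/venc*pi wrapped into
    (-pi, pi], i.e. velocities beyond venc alias.
    """
    config.validate()
    if venc <= 0:
        raise ConfigError("venc must be > 0")
    if peak_velocity <= 0:
        raise ConfigError("peak_velocity must be > 0")
    if not (0 <= regurgitant_fraction < 1):
        raise ConfigError("regurgitant_fraction must lie in [0, 1)")

    rng = np.random.default_rng(config.seed)
    rows, cols = config.matrix_size
    ps = config.pixel_spacing
    y = (np.arange(rows) - (rows - 1) / 2.0) * ps
    x = (np.arange(cols) - (cols - 1) / 2.0) * ps
    Y, X = np.meshgrid(y, x, indexing="ij")
    r2 = Y**2 + X**2
    roi = r2 <= vessel_radius_mm**2

    t_rr = 60.0 / config.heart_rate  # s
    phases = (np.arange(frames_per_cycle) + 0.5) / frames_per_cycle
    vb = 2.0 * regurgitant_fraction * peak_velocity
    v_peak_t = np.where(
        phases < 1 / 3,
        peak_velocity * np.sin(3 * np.pi * phases),
        np.where(
            phases < 1 / 2, -vb * np.sin(6 * np.pi * (phases - 1 / 3)), 0.0
        ),
    )

    profile = np.where(roi, 1.0 - r2 / vessel_radius_mm**2, 0.0)
    velocity = v_peak_t[:, None, None] * profile[None]  # cm/s
    phase_true = velocity / venc * np.pi
    wrapped_mask = np.abs(velocity) > venc

    phase = phase_true.copy()
    if config.noise_sigma > 0:
        phase = phase + rng.normal(0.0, config.noise_sigma, phase.shape)
    phase = np.angle(np.exp(1j * phase)).astype(np.float32)  # wrap into (-pi, pi]

    magnitude = np.where(roi, INTENSITY["blood"], INTENSITY["tissue"]).astype(np.float32)
    magnitude = np.repeat(magnitude[None], frames_per_cycle, axis=0)
    if config.noise_sigma > 0:
        magnitude = magnitude + rng.normal(0.0, config.noise_sigma, magnitude.shape).astype(
            np.float32
        )
        magnitude = np.clip(magnitude, 0.0, None)

    # analytic per-cycle volumes (mL): Q = 0.01 * (pi R^2 / 2) * v_peak(t)
    fwd = 0.01 * vessel_radius_mm**2 * peak_velocity * t_rr / 3.0
    bwd = 0.01 * vessel_radius_mm**2 * vb * t_rr / 6.0

    meta = SeriesMetadata(
        frame_duration=t_rr * 1000.0 / frames_per_cycle,
        pixel_spacing=(ps, ps),
        slice_thickness=config.slice_thickness,
        n_slices=1,
        frames_per_slice=frames_per_cycle,
        venc=venc,
    )
    series = FlowSeries(
        magnitude=magnitude, phase=phase, metadata=meta, frames_per_cycle=frames_per_cycle
    )
    truth = PhantomTruth(
        config=config,
        peaks=[],
        valleys=[],
        ed_frames=[],
        es_frames=[],
        lv_volume=np.zeros((1, 1)),
        rv_volume=np.zeros((1, 1)),
        resp_shift_mm=np.zeros((1, 1)),
        wall_volume_lv_ml=0.0,
        forward_volume_ml=fwd,
        backward_volume_ml=bwd,
        peak_velocity_cm_s=peak_velocity,
        roi_mask=roi,
        wrapped_mask=wrapped_mask,
    )
    return series, truth


# ---------------------------------------------------------------------------
# Repeated-session cohort simulator
# ---------------------------------------------------------------------------


@dataclass
class CohortTable:
    """Two-session cohort with its theoretical reliability quantities."""

    wide: pd.DataFrame  # columns: subject, session_1, session_2
    theoretical_icc: float  # sigma_b^2 / (sigma_b^2 + sigma_w^2)
    theoretical_cr: float  # 1.96 * sqrt(2) * sigma_w (measurand units)

    @property
    def long(self) -> pd.DataFrame:
        return self.wide.melt(
            id_vars="subject", var_name="session", value_name="value"
        ).sort_values(["subject", "session"], ignore_index=True)

    @property
    def matrix(self) -> np.ndarray:
        return self.wide[["session_1", "session_2"]].to_numpy()


def generate_repeatability_cohort(
    n_subjects: int,
    sigma_between: float,
    sigma_within: float,
    grand_mean: float,
    seed: int = 0,
) -> CohortTable:
    """Simulate paired-session measurements: value = grand mean + subject
    effect (SD sigma_between) + independent per-session noise (SD sigma_within)."""
    if n_subjects < 2:
        raise ConfigError("need at least 2 subjects")
    if sigma_between < 0 or sigma_within < 0:
        raise ConfigError("sigmas must be >= 0")
    rng = np.random.default_rng(seed)
    subject_effect = rng.normal(0.0, sigma_between, n_subjects)
    noise = rng.normal(0.0, sigma_within, (n_subjects, 2))
    values = grand_mean + subject_effect[:, None] + noise
    wide = pd.DataFrame(
        {
            "subject": np.arange(n_subjects),
            "session_1": values[:, 0],
            "session_2": values[:, 1],
        }
    )
    var_b, var_w = sigma_between**2, sigma_within**2
    icc = var_b / (var_b + var_w) if (var_b + var_w) > 0 else np.nan
    return CohortTable(
        wide=wide, theoretical_icc=icc, theoretical_cr=1.96 * np.sqrt(2.0) * sigma_within
    )


__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "CohortTable",
    "generate_cine_phantom",
    "generate_flow_phantom",
    "generate_repeatability_cohort",
    "default_navigator_line",
    "volume_waveform_fraction",
    "INTENSITY",
]
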