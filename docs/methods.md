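# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the toolkit, in the order the pipeline runs.

## Synthetic phantom

### Anatomy and contrast

The cine phantom is a 2D+t+slice scene rendered analytically per frame:

* **LV**: a circular-cross-section truncated half-ellipsoid cavity inside a
  myocardial shell with a fixed epicardial surface (wall 9 mm at
  end-diastole; the wall thickens as the cavity contracts, conserving the
  epicardial envelope). Cavity volume `V = (2/3)·π·a²·c` with the long
  semi-axis `c` fixed at 98 % of the stack coverage — the apex falls just
  inside the most apical slice, so every slice keeps a cavity
  cross-section, as a stack planned for whole-heart coverage would.
* **RV**: a flattened half-ellipsoid shell (semi-axes `a_x` fixed 40 mm,
  `a_y` volume-determined, wall 4 mm) placed anterior to the LV. A
  crescent-section RV would be more anatomical, but the flattened ellipsoid
  has a closed-form volume, and only the volume truth matters for the
  sorting and volumetry contracts.
* **Torso**: a soft-tissue ellipse containing two lung ellipses and a
  bright subdiaphragmatic (liver) compartment below a horizontal interface;
  tissue intensities are blood 1.0 > liver 0.8 > myocardium 0.45 >
  tissue 0.30 > lung 0.12 > air 0.05, the bright-blood bSSFP ordering.

Frames are rasterised with 2×2 supersampling (partial-volume edges) and
additive Gaussian noise on the magnitude image (`noise_sigma`, default 0.05
of the blood signal — adequate at this SNR; a Rician option is deferred).

### Motion

The cavity volume follows a raised-cosine waveform: systole occupies the
first third of the R–R interval (ED at phase 0, ES at phase 1/3), diastolic
refilling the remainder — smooth, with unambiguous extremes. The long axis
does not shorten through the cycle; contraction is purely in-plane.

The whole torso translates along the superior–inferior axis by
`A·sin(2π·RR·t/60)` with `A = respiratory_amplitude` (default 8 mm, a
typical free-breathing excursion) and `RR = respiratory_rate` (default 15
breaths/min, configurable). The translation is tapered linearly from 1 at
the base to `apical_signal_attenuation` (default 0.2) at the apex,
emulating the weak respiratory signal of apical slices.

Slices are "acquired" sequentially base→apex: slice k's frame j carries
global time `(k·frames_per_slice + j)·frame_duration` (defaults 300 frames
at 33 ms), so respiratory phase is deliberately unsynchronised across
slices. Ground truth (respiratory event frames, ED/ES frames, volume
waveforms, wall volume, per-frame torso shift, rasterised truth masks) is
computed analytically alongside.

### What the phantom does not emulate

No k-space/SENSE artifacts, no coil-sensitivity drift, no in-plane cardiac
translation or through-plane motion, no breathing irregularity (the
respiratory signal is a stationary sinusoid), no ECG. Passing tests
therefore demonstrate the correctness of the sorting/measurement chain
under idealised contrast and periodic motion, not robustness to arrhythmia,
variable breathing depth, or reconstruction artifacts.

### Flow phantom

A circular vessel (radius 12 mm) with a parabolic through-plane profile;
the temporal waveform has a sinusoidal systolic forward lobe over the first
third of the cycle and an optional early-diastolic backward lobe scaled so
backward/forward volume equals `regurgitant_fraction`. Phase is
`v/V_enc·π` wrapped into (−π, π], so programmed velocities beyond V_enc
alias exactly as in phase-contrast MRI. Analytic per-cycle forward volume:
`0.01·R²·v_peak·T_RR/3` mL.

### Cohort simulator

`value = grand_mean + N(0, σ_b) per subject + N(0, σ_w) per session`, two
sessions per subject; theoretical `ICC = σ_b²/(σ_b²+σ_w²)` and
`CR = 1.96·√2·σ_w` are returned with the table.

## Navigator and event detection

The navigator trace is the mean intensity over the rasterised line segment
(Bresenham pixels), per slice and frame. Detection proceeds in four steps:

1. moving-average smoothing, default 5 frames (165 ms) — removes
   cardiac-frequency ripple while preserving respiratory extremes;
2. candidate extrema via `scipy.signal.find_peaks` on a second,
   respiratory-time-scale moving average (one third of the minimum
   separation), with prominence ≥ `min_prominence` (default 0.2) of that
   slice's trace range and separation ≥ `min_separation` (default 1 s,
   i.e. breathing ≤ 60/min). The coarse trace also drives the confidence
   gate: a slice whose range falls below `min_prominence` × the median
   range across slices is marked low-confidence (using the coarse trace
   keeps noise from inflating the range of slices with little respiratory
   signal);
3. sub-frame refinement: each candidate is relocated to the analytic
   extremum of a least-squares cosine fit at the breathing frequency
   (pooled median inter-event spacing across slices — respiration is
   shared by the sequentially acquired stack) over ±0.65 periods, run
   twice with recentred windows. The raw argmax of a slowly varying noisy
   trace jitters by several frames because the extremum is locally flat;
   the harmonic fit averages noise over ~a period of samples and recovers
   the extremum to about a frame even on heavily attenuated apical traces
   (the Cramér–Rao bound for the weakest default slice is ≈0.8 frames);
4. alternation enforcement: among consecutive same-type events the most
   extreme survives; plateau ties resolve to the earliest frame.

Low-confidence slices inherit the nearest high-confidence slice's events,
extended periodically (median inter-event spacing) across the sequential
acquisition timeline and intersected with the slice's frame range; they are
flagged `low` in all outputs. Event indices are invariant to intensity
offset and positive scaling by construction (range-relative prominence).

Known limitation: an extremum within ~one minimum-separation of the trace
boundary has only a one-sided descent, halving its prominence; such events
are detected unreliably. They are irrelevant downstream because anchors use
the event nearest the slice's temporal midpoint.

## Sorting

The anchor of a slice is the event of the requested respiratory phase
nearest the temporal midpoint of that slice's acquisition (the rule when
several candidate events exist). Within `[anchor−w, anchor+w]` (clipped at
series bounds, never wrapped), ED maximises and ES minimises the
blood-pool area from seeded region growing; frames whose segmentation is
flagged (degenerate or leaking) cannot win unless all frames are flagged.
Ties resolve to the frame closer to the anchor, then to the earlier frame.
Default half-widths are 7 frames at rest (2·7·33 = 462 ms) and 5 during
exercise (330 ms); a per-slice manual override table wins verbatim,
reproducing an operator-driven workflow. The automated area criterion is
this package's surrogate for interactive ED/ES picking — chosen for
testability on phantoms.

Note that a rest window (±7 frames) is shorter than a resting cardiac cycle
(~32 frames at 56 beats/min): the true global ED/ES often lies outside the
searchable window by construction. Recovery is therefore validated against
the analytic volume extremum *within the same clipped window*; end-to-end
volume recovery tests use a window spanning one full cycle (half-width 17
at 56 beats/min), where the global extremes are reachable.

## Segmentation and volumetry

`segment_chamber` grows the connected bright region containing the seed
above an adaptive threshold placed `threshold_quantile` (default 0.5) of
the way between a dark and a bright reference. The bright reference is the
larger of the 41×41-pixel patch's 95th percentile and the 5×5 seed-core
median (so tiny apical cavities still anchor the reference to blood); the
dark reference starts at the patch's 10th percentile and is then
re-anchored to the median intensity of the 2-pixel ring around the
first-pass region — the full-width-at-half-maximum convention, which
removes the outward partial-volume bias a patch-wide dark reference (lung
signal) introduces. Interior holes are filled by default, counting
papillary/trabecular tissue as blood pool. Results are flagged (not
errored) when the seed falls below threshold or the region leaks to the
image border.

Chamber volume is disc summation: Σ area × (slice thickness + gap), with a
slice contributing iff its mask is nonempty; no partial-slab correction at
base or apex (the basal/apical inclusion rule is declared package
behaviour). Disc summation of a dome-shaped cavity at 10 mm slabs carries a
small resolution-independent overestimate from the slab straddling the
apex: ≈ +2.6 % at end-diastole and ≈ +3.8 % at end-systole for the default
geometry, within the 5 % tolerance used by the validation suite. SV/EF/CO
follow the standard formulas; the heart rate for CO is always supplied
explicitly (stage-mean HR paired with stage volumetry), never inferred from
images. LV mass = (epicardial − endocardial volume) × 1.05 g/mL.

## Flow quantification

`v = V_enc·φ/π`; Q(t) sums `v·pixel_area` over the ROI (static mask by
default, per-frame masks accepted); forward/backward volumes integrate the
positive/negative parts of Q over one cycle with
`Δt = R–R interval / frames_per_cycle` (30 frames per cycle). Backward flow
is reported as a positive magnitude and net = forward − backward (the two
usual "net flow" definitions coincide under these conventions, asserted in
tests). Optional single-wrap unwrapping corrects connected clusters of
opposing-sign pixels with |φ| > 0.8π that abut same-threshold pixels of the
dominant sign; velocities with |φ| < 0.8π are never altered. No
background-phase (eddy-current) correction is applied by default; a
constant offset can be estimated from a user-supplied static-tissue mask.

## Statistics

Sample SDs use n−1 throughout. Bland–Altman: d = value₁ − value₂, bias =
mean(d), limits of agreement = bias ± 1.96·SD(d); the group mean is the
mean over both sessions' values (the percentage base for CR is not
universally defined; both-session mean is this package's convention, and
the repeatability table also emits the session-1 mean, labelled).
ICC(A,1) is computed from the two-way ANOVA mean squares

```
ICC(A,1) = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)·(MS_C − MS_E))
```

clipped to [−1, 1]; a zero-variance matrix raises a named error. BH
adjustment is the step-up procedure (via statsmodels), applied per
parameter over the family of all pairwise comparisons in a table (the
family definition is configurable by construction — one call per family).
One-way repeated-measures ANOVA uses the standard subject/condition SS
decomposition with listwise deletion of incomplete subjects (as when a
stage is missing for some participants). Paired comparisons return the
two-sided paired t and the Pearson r of each condition pair.

## Validation problem sizes

The test-suite phantoms use 6 slices × 300 frames with proportionally
scaled chamber volumes (EDV/ESV 70/30 mL LV) so the chambers fit the
shorter stack; acquisition timing, noise, breathing and attenuation keep
their defaults. ED/ES recovery is scored over 20 seeds at heart rates
56/105/136 beats/min in the test suite (5 seeds per rate in the acceptance
script), end-to-end volume recovery over 3 seeds, flow conservation at
V_enc 150/200/250 cm/s, and ICC recovery on 10,000 simulated subjects. The
full 15-slice study geometry (EDV/ESV 170/72 mL) is exercised in the
rasterisation/volumetry tests, where no sorting is involved.

## Numerical conventions

All indices 0-based, intervals half-open; slice 0 is most basal; frame
times are frame-start times. Tie-breaks: earliest frame for plateau trace
extrema; anchor-nearest then earliest frame for equal blood-pool areas.
Window clipping at series bounds is silent in the API and logged by the
CLI. The canonical on-disk format is NIfTI-1 (x, y, slice, frame) plus a
JSON sidecar carrying timing/geometry (the sidecar is authoritative for
timing); DICOM directories are read classic single-frame, sorted by slice
position then trigger time, and DICOM export uses a 12-bit rescale.
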