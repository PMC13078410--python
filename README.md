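# rtcine

Exercise cardiac MRI toolkit: retrospective frame sorting of free-breathing
real-time cine series, biventricular volumetry, phase-contrast aortic flow
quantification, exercise heart-rate targeting, and inter-session precision
statistics — exercisable end-to-end on a synthetic beating-and-breathing
phantom with programmed ground truth.

## The problem

Quantifying heart function *during* bicycling exercise requires real-time
(non-gated, free-breathing) cine MRI: each short-axis slice is acquired
continuously for ~10 s (300 frames at 33 ms), so the slices of a stack are
aligned to neither the cardiac nor the respiratory cycle. Before volumetry
the frames must be sorted retrospectively:

1. a **navigator line** placed over the diaphragm or chest–lung interface
   yields a mean-intensity trace per slice that follows respiration;
2. **peaks** (end-expiration) and **valleys** (end-inspiration) of the trace
   are detected and every slice is aligned to one respiratory phase;
3. within a **proximity window** around that anchor (±7 frames/462 ms at
   rest, ±5 frames/330 ms during exercise), the end-diastolic (ED, maximal
   blood pool) and end-systolic (ES, minimal blood pool) frames are picked
   per slice.

The sorted ED/ES stacks feed standard disc-summation volumetry

```
EDV, ESV        [mL]      SV = EDV − ESV
EF = 100·SV/EDV [%]       CO = SV·HR/1000  [L/min]
LV mass = 1.05 g/mL · (V_epi − V_endo)
```

and are validated against 2D phase-contrast flow through the ascending
aorta, `v = V_enc·φ/π`, with forward/backward/net volumes per cardiac cycle
and the dAo/aAo net-flow ratio. Exercise stages target 60 % and 80 % of the
supine maximal heart rate `0.9·(211 − 0.64·age)`. Measurement precision is
summarised by Bland–Altman bias ± 1.96·SD limits of agreement, the
coefficient of repeatability `CR = 1.96·SD(d)/mean` (% of the group mean),
and the absolute-agreement intraclass correlation ICC(A,1).

The package is aimed at researchers developing or validating exercise MRI
stress-testing pipelines who need every stage testable without patient
data: the `phantom` module generates real-time cine stacks, phase-contrast
series, and repeated-session cohorts with analytic ground truth.

## Worked example

Generate a breathing, beating phantom; sort it; measure it:

```python
from rtcine import (PhantomConfig, generate_cine_phantom, NavigatorLine,
                    extract_navigator_trace, detect_respiratory_events,
                    SortingConfig, align_slices, select_cardiac_phases,
                    MaskStack, chamber_volume, segment_chamber,
                    ventricular_function)
from rtcine.phantom import default_navigator_line

config = PhantomConfig(n_slices=6, frames_per_slice=300, heart_rate=56,
                       edv_lv=70, esv_lv=30, edv_rv=72, esv_rv=33, seed=1)
series, truth = generate_cine_phantom(config)

line = NavigatorLine(*default_navigator_line(config))
events = detect_respiratory_events(extract_navigator_trace(series, line))
sort_cfg = SortingConfig(respiratory_phase="expiration", window_half_width=17)
anchors = align_slices(events, sort_cfg)
seeds = [truth.seed_pixel(k, int(anchors[k]), "LV") for k in range(series.n_slices)]
stack = select_cardiac_phases(series, anchors, sort_cfg, seeds)

volumes = {}
for phase, attr in (("EDV", "ed_frame"), ("ESV", "es_frame")):
    masks = [segment_chamber(series.voxels[s.slice_index, getattr(s, attr)],
                             seeds[s.slice_index]).mask for s in stack.slices]
    volumes[phase] = chamber_volume(MaskStack(masks=masks, metadata=series.metadata))

function = ventricular_function(volumes["EDV"], volumes["ESV"], heart_rate=56)
print(f"anchors (end-expiration frames): {[int(a) for a in anchors]}")
print(f"EDV {function.edv:.1f} mL  ESV {function.esv:.1f} mL  "
      f"SV {function.sv:.1f} mL  EF {function.ef:.1f}%  CO {function.co:.2f} L/min")
```

Output:

```
anchors (end-expiration frames): [152, 94, 157, 99, 164, 108]
EDV 69.9 mL  ESV 30.0 mL  SV 40.0 mL  EF 57.2%  CO 2.24 L/min
```

The programmed truth was EDV 70 mL / ESV 30 mL: the full chain (navigator →
event detection → respiratory alignment → windowed ED/ES selection → seeded
region-growing segmentation → disc summation) recovers both to well within
1 %. Each anchor sits on a true end-expiration frame of its slice even
though the six slices were "acquired" sequentially at unsynchronised
respiratory phases.

A command-line interface wraps the same stages for scripted runs:

```bash
rtcine targets --age 28.8                 # supine HRmax + 60/80% stage targets
rtcine simulate cine --out out --seed 1   # phantom series + truth tables
rtcine run config.yaml                    # configured multi-stage pipeline
rtcine repeatability --in sessions.csv --out table.csv
```

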