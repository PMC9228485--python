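# xylemflow

Quantitative imaging of water flow in the maize stem vascular system.

Water moves from roots to leaves through xylem vessels — dead, lignified
conduits a few to a few tens of microns wide. Inside a grass stem the
vessels run in parallel through internodes and interconnect densely in
nodal plexuses, where branching and merging (the elementary unit being a
Y-type junction) redistribute the transpiration stream. This package
implements the quantitative pipeline for studying that system with three
complementary imaging modalities and one scaling argument:

- **micro-PIV** (`xylemflow.piv`): velocity fields in Y-junction
  microchannels from tracer-particle image pairs, by multipass
  deformation cross-correlation (windows 128×32 → 32×8 px, 50 % overlap),
  three-point Gaussian subpixel peak fitting, two-stage vector validation
  (SNR ≥ 2, 7×7 normalised median test), ensemble averaging and
  profile extraction;
- **vessel morphometry** (`xylemflow.morphometry`): per-vessel area *S*,
  Crofton perimeter *P*, hydraulic diameter *D*<sub>h</sub> = 4*S*/*P*,
  moment-based ellipse fits, concentric-ring assignment in polar
  coordinates about the stem centre, and per-vessel Reynolds numbers;
- **contrast-enhanced MRI** (`xylemflow.mri`): the normalised flow-signal
  matrix
  *F*[i,t] = (S̄(stem<sub>it</sub>) − S̄(stem<sub>i0</sub>)) / S̄(air<sub>it</sub>)
  over an 18-slice × 19-timepoint series, and node/internode slice
  classification from its temporal slopes;
- **hydraulics** (`xylemflow.hydraulics`): the mean xylem velocity
  *U*₀ = *Q*/*S*, the Reynolds number Re = *U*₀*D*<sub>h</sub>/ν, the
  Reynolds-similarity match from plant vessels onto a 120 × 240 µm
  lab-on-a-chip microchannel, and the analytic rectangular-duct laminar
  profile used as an independent oracle for the PIV engine.

No public datasets exist for this system, so `xylemflow.synthgen`
generates seeded synthetic inputs with known ground truth for every
stage: tracer images (8-bit, ~3 px Gaussian spots, 0.02 particles/px²),
elliptical vessel phantoms in four concentric rings at 0.692 µm/px, and
MRI phantoms whose nodal slices accumulate signal as
S<sub>∞</sub>(1 − e<sup>−t/τ</sup>) while internode slices stay flat.

## Worked example

Measure a known uniform 8 px tracer shift and match the stem operating
point to the chip:

```python
import numpy as np
from xylemflow import hydraulics, piv, synthgen

field = synthgen.uniform_field(8.0, 0.0, shape=(64, 256))
pair = synthgen.make_particle_image_pair(field, seed=0)
vf = piv.multipass_piv(pair)
print(f"measured {np.mean(vf.u[vf.valid]):.4f} px/frame, "
      f"valid {vf.valid.mean():.0%}")

re_big = hydraulics.reynolds(221.5e-6, 46e-6)     # largest vessel
op = hydraulics.match_chip_operating_point(re_big, ratio_R=0.25)
print(f"Re = {re_big:.4f}; chip U = {op['U_chip']*1e3:.5f} mm/s; "
      f"Q1 = {op['Q1_ml_h']:.6f} mL/h, Q2 = {op['Q2_ml_h']:.6f} mL/h")
```

prints

```
measured 8.0001 px/frame, valid 98%
Re = 0.0117; chip U = 0.06368 mm/s; Q1 = 0.005282 mL/h, Q2 = 0.001320 mL/h
```

i.e. the engine recovers the 8 px shift to well under 0.1 px, the
largest stem vessels operate at Re ≈ 0.012, and driving the chip inlets
at those flow rates puts the microchannel at the same Reynolds number —
the similarity condition under which chip velocimetry speaks for the
plant.

The numbered drivers under `analysis/` run the full studies and write
their tables to `results/`: `01_stem_hydraulics.py` (operating points),
`02_piv_accuracy.py` (pixel-locking curve and mean-flow errors),
`03_vessel_morphometry.py` (ring morphometry and Re distributions),
`04_mri_flow_matrix.py` (space–time contrast map and classification),
`05_y_merge_profiles.py` (PIV profiles on the merge model at inlet
ratios 0.25/0.5/1). The `xylemflow` console script exposes the same
stages as subcommands (`synth`, `piv`, `morph`, `mri`, `hydro`, `demo`).

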