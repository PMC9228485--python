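# Methods

This note documents the models behind each module, the parameters that
matter, the numerical choices made where the design was open, and what
the synthetic phantoms do and do not establish about real data.

## PIV engine

**Model.** A velocity vector is estimated per interrogation window from
the zero-normalised cross-correlation (ZNCC) of the two frames: both
windows are mean-subtracted and the plane divided by `N·σa·σb`, which
makes the estimate insensitive to illumination offsets and gain. Lags
are searched within the half-window range. The displacement is the
integer lag of the primary peak plus, per axis, the three-point
log-Gaussian offset

    δ = (ln R₋₁ − ln R₊₁) / (2 ln R₋₁ + 2 ln R₊₁ − 4 ln R₀),

which is exact when the peak is a pure Gaussian (and particle images are
close to Gaussian). When any of the three samples is non-positive the
fit falls back to the parabolic vertex; plane values are floored at
1e-6 before taking logs.

**Multipass deformation.** Three passes shrink the window geometrically
128×32 → 64×16 → 32×8 px (height × width written as rows × columns:
windows are elongated along the flow, x, for dynamic range) at 50 %
overlap. After each pass the validated field is lightly smoothed
(Gaussian, σ = 0.5 nodes), densified to pixel resolution bilinearly with
constant extrapolation beyond the node hull, and used to warp frame B
toward frame A by bicubic interpolation, so the next pass measures only
the residual. The final grid spacing is the final window times
(1 − overlap), i.e. 16×4 px.

**Validation.** Two stages, in order: (i) SNR — the ratio of the primary
correlation peak to the highest peak outside a 3×3 exclusion zone — must
be ≥ 2; (ii) the normalised median test over a 7×7 node region: a
vector is an outlier if its deviation from the median of its valid
neighbours exceeds twice the median neighbour residual plus a 0.1 px
stabiliser, per component. Outliers are flagged and replaced by the
neighbourhood median. Detection uses only the input field, so the
two-stage pass is idempotent on its own output. Ensemble averaging takes
the per-node mean over valid vectors and keeps a node only if valid in
at least half the realisations.

**Measured performance** (recomputed by `analysis/02_piv_accuracy.py`
and `scripts/acceptance.py`): on 64×256 px synthetic pairs at default
seeding, the pixel-locking curve over 0.1–0.9 px shifts stays below
0.01 px mean absolute error, against the 0.1 px method budget, and the
relative ensemble-mean error is well under 1 % at 8 px and 4 % at 2 px
shifts. Windows straddling a wall or the image border lose particles
and may fail validation; profile statistics therefore use valid nodes
only. The suite reports both mean-absolute and RMS norms, since the
two differ when the error budget is quoted as a single number.

## Synthetic tracer images

Particles are seeded uniformly at 0.02 particles/px² over the image
extended by a margin of the maximum displacement plus the spot size, so
advection out of the frame is balanced by particles entering at the
inflow side and the per-area count is stationary between frames (the
margin construction is statistically equivalent to dropping and
replenishing at the inflow edge, and keeps the ground truth exact).
Frame-B positions are frame-A positions plus the field evaluated there —
first-order transport, adequate for the ≤ 8 px displacements studied.
Spots render as pixel-integrated Gaussians (erf differences) with e⁻²
diameter 3 px (2 µm tracers at ~1 µm/px, diffraction-broadened), peak
intensity 200, additive Gaussian noise σ = 2, quantised to 8 bits as a
camera would. Everything is driven by one `numpy` Generator per
(seed, params), so regeneration is bit-exact.

What the phantom omits: Brownian motion, out-of-plane loss, optical
point-spread variation, and background fluorescence gradients. Passing
the accuracy suite therefore bounds algorithmic error, not experimental
error; real micro-PIV data add those effects on top.

**Y-merge model.** The merge of two inlet streams is an explicit
analytic blend, not a Navier–Stokes solution: at the junction the two
half-channels carry independent parabolas with fluxes Q1 ≥ Q2
(R = Q2/Q1); a smoothstep ramp over the development length (default
800 px, where the real flow has relaxed) blends them into the
single-duct parabola. The transverse component follows from continuity,
so the field is divergence-free and the integrated flux is identical at
every station (Q1 + Q2 = Q = const). The model reproduces the
qualitative features — symmetry at R = 1, near-inlet peak shifted to the
higher-flux wall at R < 1, relaxation to a symmetric profile
downstream — but deliberately not the transient velocity overshoot
(≈ 2.5–3 U/U₀) of the real 3-D merging flow, which would require CFD
and is out of scope; the property suite (flux conservation, symmetry,
wall shift) stands in for it.

## Vessel morphometry

Area is the pixel count times pixel_size² (default 0.692 µm/px, the
optical-section calibration); holes inside a lumen are filled first,
because the lumen is the hydraulic cross-section. The perimeter uses the
Crofton 4-direction estimator: naive boundary-pixel counting
overestimates P — hence underestimates D_h = 4S/P — by up to ~27 % on
disks, so the estimator choice materially affects every downstream
Reynolds number and is pinned. On a rasterised disk of radius 50 px the
resulting D_h is within ~1 % of the true 100 px, and every measured
region satisfies the isoperimetric bound D_h ≤ 2√(S/π)(1 + 0.05), the
0.05 covering raster error.

Ellipse fits use second central moments with each pixel treated as a
unit square cell (point moments + 1/12), which removes most small-region
bias; axes are 2√eigenvalue, orientation is the major-axis eigenvector
angle from +x (y down) in [0, π). Physical coordinates are
(index + 0.5)·pixel_size.

Ring assignment works in polar coordinates about the stem centre —
by default the centroid of vessel centroids, since a "nominal centre"
is otherwise undefined; an explicit centre can be supplied. Ring edges
are preferably explicit radii; the quantile fallback (quartile breaks)
exists for phantoms. Radii exactly on an edge go to the inner ring, so
degenerate all-equal radii land in ring I.

The vessel phantom places non-overlapping ellipses at jittered polar
positions on rings of radius 100/200/300/400 px with semi-axes ≥ ~5 px
(≈ 8–40 µm hydraulic diameter at 0.692 µm/px). Below that size,
rasterisation alone puts several percent of error into moment-based
axes, so the percent-level recovery checks are meaningful only in this
regime; real stems also contain narrower protoxylem (down to
D_h ≈ 3.8 µm) whose shape parameters carry correspondingly larger
raster uncertainty — their Reynolds numbers are still well-defined via
4S/P.

## MRI flow-signal matrix

The normalisation is applied exactly as defined: for slice i and scan t,
F[i,t] = (mean stem intensity − its t = 0 baseline) / mean air intensity
at the same timepoint. The baseline is the first timepoint (not a
pre-contrast average) and the air mean divides per timepoint (no
temporal smoothing), so F[:,0] ≡ 0 by construction and a constant
intensity offset enters only through the air term. Non-positive air
means flag the slice and yield NaN rather than a silent division.
Masks are fixed per slice across timepoints (re-drawing per image is a
registration problem outside this scope).

Slices are classified by the least-squares slope of F over time:
above-threshold slopes are nodal plexuses (the gadolinium chelate cannot
cross vessel walls and accumulates where water takes the apoplastic
detour), flat traces are internodes. For phantoms the threshold defaults
to half the median positive slope; on real data the threshold must be
chosen explicitly, because the node/internode slope separation is not
known a priori.

The phantom uses 18 slices × 19 timepoints at 23 min, stem baseline 100,
air 25, water reference 180, node accumulation amplitude 40 with
τ = 90 min, Gaussian noise σ = 5 — values on an arbitrary scanner scale
chosen to have visible but not dominant noise (region-mean SNR is high
because masks average hundreds of pixels). Noiseless, internode rows of
F are exactly zero and node rows strictly increasing; with default
noise, classification accuracy over 200 seeded replicates is effectively
100 %, comfortably above the 95 % requirement. The phantom does not
model T1/T2 relaxation, coil inhomogeneity, or slice cross-talk; it
validates the normalisation and classification arithmetic, not MR
physics.

## Hydraulics

All internal computation is SI; converters for µm, µm/s and mL/h live at
the boundary, and functions warn when argument magnitudes suggest µm
passed as m (the Reynolds targets are sensitive to silent unit slips).
Key constants: ν = 8.74e-7 m²/s (water at 26 °C), chip outlet
120 × 240 µm (D_h = 160 µm), inlets 120 µm squares.

With the measured stem values U₀ = 221.5 µm/s and total lumen area
358,292.39 µm², the implied whole-plant flow is Q = U₀S ≈ 7.94e-11 m³/s
(≈ 0.29 mL/h), and the per-vessel Reynolds numbers over
D_h ∈ [3.8, 46] µm span ≈ 0.001–0.012. Matching a target Re on the chip
inverts Re = U·D_h/ν for the chip's hydraulic diameter and splits
Q = U·A between the inlets as Q1 = Q/(1+R), Q2 = RQ/(1+R).

Note that quoting chip Reynolds numbers with the D_h = 160 µm convention
gives values well below the 3–100 range sometimes associated with the
same velocities (e.g. 0.1 mm/s ↔ Re ≈ 0.018 under this convention);
the characteristic length behind such larger figures is not stated, so
the package uses the hydraulic diameter uniformly, for vessels and chip
alike, and flags rather than asserts any other convention.

**Rectangular-duct oracle.** The fully developed laminar profile is the
classical Fourier series over odd n of
(1/n³)[1 − cosh(nπy/2b)/cosh(nπa/2b)]cos(nπz/2b), evaluated with
exponential-form cosh ratios for numerical stability, normalised so the
cross-section mean equals U₀ on a 201×201 trapezoid grid. Convergence is
checked by re-evaluating at half the terms and requiring 0.1 % agreement
on the max/mean ratio (minimum 25 odd terms; 101 by default). The series
gives max/mean = 2.0964 for a square duct, 1.992 for the 1:2 chip outlet
— the "velocity maximum close to 2U₀" regime characteristic of these
ultra-slow flows — and tends to 1.5 in the parallel-plate limit. Walls
satisfy no-slip to < 1e-6·U₀. This analytic solution is the independent
reference the PIV engine is tested against.

## Pipeline and reproducibility

TIFF is the only raster interchange; tables are CSV with explicit
headers and '.' decimals, scalars JSON. Each run directory contains the
resolved YAML config and a manifest with the config hash, per-stage
outputs, SHA-256 checksums and wall time; deterministic stages reproduce
identical checksums on re-run. One global seed fans out per stage
through `SeedSequence(global_seed, crc32(stage_name))`, so a single
integer reproduces the whole demo.

## Problem sizes

Synthetic PIV studies use 64×256 px frames (one initial window tall,
two wide), 50 pairs per displacement for the subpixel sweep and 100 for
the 2 px/8 px operating points, and 20-pair ensembles for profile
recovery; these sizes put the Monte-Carlo error well below the
tolerances being checked while keeping each study in the
tens-of-seconds range. Ensemble convergence follows the expected 1/√N
law (checked at N = 10/40/160), so larger ensembles buy precision at
known cost.

## Known limitations

- The PIV engine is planar and two-component: no out-of-plane motion,
  stereo reconstruction, or Brownian correction.
- The merge model is kinematic; developing-flow maxima and vortical
  transverse transport in a real Y-junction are not reproduced.
- Morphometry consumes label images; segmentation of raw fluorescence
  stacks (done manually by an expert upstream) is out of scope, as is
  distinguishing metaxylem from protoxylem automatically.
- MRI masks are supplied, fixed per slice; no registration, no pulse-
  sequence modelling, no DICOM parsing.
- Whether a printed total lumen area counts lumen only or lumen plus
  wall depends on the upstream segmentation; results here are defined
  for lumen-only labels with holes filled.
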