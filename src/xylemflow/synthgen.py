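"""Seeded synthetic inputs with known ground truth for every pipeline stage.

Three families of phantoms:

* tracer-particle image pairs under a prescribed displacement field, for
  benchmarking the PIV engine (2 µm fluorescent tracers imaged at
  ~1 µm/px render as ~3 px Gaussian spots on an 8-bit camera);
* labelled vessel cross-sections — non-overlapping ellipses arranged in
  four concentric rings around a stem centre, emulating the layout of
  xylem vessels in a maize stem slice;
* contrast-enhanced MRI slice time-series in which nodal-plexus slices
  accumulate signal over time while internode slices do not.

Every generator is bit-reproducible under (seed, params).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import erf
from skimage.draw import ellipse as draw_ellipse

__all__ = [
    "DisplacementField",
    "uniform_field",
    "poiseuille_field",
    "make_y_merge_field",
    "ParticleImageParams",
    "ParticleImagePair",
    "make_particle_image_pair",
    "RingSpec",
    "default_ring_specs",
    "VesselPhantom",
    "make_vessel_phantom",
    "MriPhantomParams",
    "MriPhantomSeries",
    "make_mri_phantom",
]

RING_NAMES = ("I", "II", "III", "IV")


# --------------------------------------------------------------------------
# displacement fields
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DisplacementField:
    """A displacement field (dx, dy) in pixels over an (H, W) pixel domain.

    ``fn(x, y)`` takes arrays of positions in pixel units (x rightward
    along the flow, y downward) and returns ``(dx, dy)`` arrays.
    """

    shape: tuple[int, int]          # (H, W)
    fn: "callable"
    kind: str = "custom"

    def __call__(self, x, y):
        dx, dy = self.fn(np.asarray(x, float), np.asarray(y, float))
        return np.asarray(dx, float), np.asarray(dy, float)

    def max_displacement(self, n: int = 33) -> float:
        """Upper bound of |d| from a coarse grid sample."""
        H, W = self.shape
        xs, ys = np.meshgrid(np.linspace(0, W, n), np.linspace(0, H, n))
        dx, dy = self(xs, ys)
        if not (np.all(np.isfinite(dx)) and np.all(np.isfinite(dy))):
            raise ValueError("displacement field contains non-finite values")
        return float(np.hypot(dx, dy).max())


def uniform_field(dx: float, dy: float, shape: tuple[int, int]) -> DisplacementField:
    """Constant displacement everywhere."""

    def fn(x, y):
        return np.full_like(x, dx), np.full_like(y, dy)

    return DisplacementField(shape=shape, fn=fn, kind="uniform")


def poiseuille_field(
    u_max: float, shape: tuple[int, int], *, wall_margin: float = 0.0
) -> DisplacementField:
    """Plane Poiseuille flow along x with no-slip walls at y = m and y = H - m.

    The longitudinal component vanishes at the walls and peaks at
    ``u_max`` on the channel centreline; the transverse component is zero.
    """
    H, _ = shape
    y0, y1 = wall_margin, H - wall_margin
    h = y1 - y0

    def fn(x, y):
        s = np.clip((y - y0) / h, 0.0, 1.0)
        return u_max * 4.0 * s * (1.0 - s), np.zeros_like(y)

    return DisplacementField(shape=shape, fn=fn, kind="poiseuille")


@dataclass(frozen=True)
class YMergeGeometry:
    """Straight model duct downstream of a Y-junction, in pixels.

    The two inlet streams occupy the upper (higher-flux, ``Q1``) and
    lower (``Q2``) halves of the channel at the junction (x = 0) and
    relax to a single fully blended profile over ``development_length``.
    """

    height: int = 64
    length: int = 1024
    development_length: float = 800.0


def make_y_merge_field(
    ratio_R: float,
    mean_speed: float,
    geometry: YMergeGeometry | None = None,
) -> DisplacementField:
    """Analytic two-stream merge model for a Y-junction outlet channel.

    An explicit blend — NOT a Navier-Stokes solution: at the inlet the
    two streams carry independent parabolic profiles with fluxes
    ``Q1 >= Q2`` and ``R = Q2/Q1``; the profile relaxes smoothly to the
    single-duct parabola over the development length.  The transverse
    component follows from continuity, so the integrated longitudinal
    flux is identical at every station and the field is divergence-free.
    """
    if not 0 < ratio_R <= 1:
        raise ValueError(f"inlet flow ratio must lie in (0, 1], got {ratio_R}")
    geo = geometry or YMergeGeometry()
    H = float(geo.height)
    L = float(geo.development_length)
    q = mean_speed * H          # total flux per unit depth, px²/frame
    q1 = q / (1.0 + ratio_R)    # upper stream (higher flux)
    q2 = q - q1
    h = H / 2.0
    a1 = 6.0 * q1 / h**3
    a2 = 6.0 * q2 / h**3
    a_out = 6.0 * q / H**3

    def u_in(y):
        y = np.clip(y, 0.0, H)
        upper = a1 * y * (h - y)
        t = y - h
        lower = a2 * t * (h - t)
        return np.where(y <= h, upper, lower)

    def U_in(y):  # antiderivative of u_in from 0
        y = np.clip(y, 0.0, H)
        yc = np.minimum(y, h)
        up = a1 * (h * yc**2 / 2.0 - yc**3 / 3.0)
        t = np.clip(y - h, 0.0, h)
        low = a2 * (h * t**2 / 2.0 - t**3 / 3.0)
        return up + low

    def u_out(y):
        y = np.clip(y, 0.0, H)
        return a_out * y * (H - y)

    def U_out(y):
        y = np.clip(y, 0.0, H)
        return a_out * (H * y**2 / 2.0 - y**3 / 3.0)

    def fn(x, y):
        s = np.clip(x / L, 0.0, 1.0)
        w = 3.0 * s**2 - 2.0 * s**3
        dw = np.where((x > 0) & (x < L), (6.0 * s - 6.0 * s**2) / L, 0.0)
        u = (1.0 - w) * u_in(y) + w * u_out(y)
        v = -dw * (U_out(y) - U_in(y))
        return u, v

    return DisplacementField(shape=(geo.height, geo.length), fn=fn, kind="y-merge")


# --------------------------------------------------------------------------
# particle images
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ParticleImageParams:
    """Rendering parameters for synthetic tracer-particle images.

    ``diameter`` is the e^-2 Gaussian image diameter in pixels (2 µm
    tracers at 1 µm/px broaden to ~3 px); ``density`` is particles per
    pixel² (0.02 gives ~5 particles in a final 32x8 window);
    ``max_displacement`` bounds |d| and sets the seeding margin so
    particle density stays stationary between frames.
    """

    density: float = 0.02
    diameter: float = 3.0
    peak_intensity: float = 200.0
    noise_sigma: float = 2.0
    max_displacement: float = 8.0


@dataclass(frozen=True)
class ParticleImagePair:
    frame_a: np.ndarray      # uint8 (H, W)
    frame_b: np.ndarray      # uint8 (H, W)
    truth: DisplacementField
    params: ParticleImageParams
    seed: int


def _render_particles(
    positions: np.ndarray, shape: tuple[int, int], diameter: float, peak: float
) -> np.ndarray:
    """Render particles as pixel-integrated Gaussian spots.

    Pixel (j, i) covers [i, i+1) x [j, j+1); a particle at (x, y) with
    e^-2 diameter d has Gaussian sigma d/4 and its contribution to each
    pixel is the erf-difference integral of the Gaussian over the pixel,
    scaled so a pixel-centred particle's brightest pixel equals ``peak``.
    """
    H, W = shape
    img = np.zeros((H, W), float)
    if positions.size == 0:
        return img
    sigma = diameter / 4.0
    s2 = sigma * math.sqrt(2.0)
    half = int(math.ceil(3.0 * sigma + 1.0))
    # peak normalisation: integral over the centre pixel of a unit-peak 1-D Gaussian
    g0 = 0.5 * (erf(0.5 / s2) - erf(-0.5 / s2))
    amp = peak / (g0 * g0)

    xs, ys = positions[:, 0], positions[:, 1]
    keep = (xs > -half - 1) & (xs < W + half) & (ys > -half - 1) & (ys < H + half)
    xs, ys = xs[keep], ys[keep]
    if xs.size == 0:
        return img

    ix0 = np.floor(xs).astype(int)
    iy0 = np.floor(ys).astype(int)
    offs = np.arange(-half, half + 1)
    # (n, k) pixel index grids around each particle
    px = ix0[:, None] + offs[None, :]
    py = iy0[:, None] + offs[None, :]
    gx = 0.5 * (erf((px + 1 - xs[:, None]) / s2) - erf((px - xs[:, None]) / s2))
    gy = 0.5 * (erf((py + 1 - ys[:, None]) / s2) - erf((py - ys[:, None]) / s2))
    w = amp * gy[:, :, None] * gx[:, None, :]     # (n, k, k)
    pyc = np.clip(py, 0, H - 1)
    pxc = np.clip(px, 0, W - 1)
    valid = ((py >= 0) & (py < H))[:, :, None] & ((px >= 0) & (px < W))[:, None, :]
    flat_idx = (pyc[:, :, None] * W + pxc[:, None, :])[valid]
    np.add.at(img.ravel(), flat_idx, w[valid])
    return img


def make_particle_image_pair(
    field: DisplacementField,
    params: ParticleImageParams | None = None,
    seed: int = 0,
) -> ParticleImagePair:
    """Generate a synthetic tracer image pair under a displacement field.

    Particles are seeded uniformly over the image extended by a margin of
    ``max_displacement`` plus the spot radius, so particles advected out
    of frame are balanced by fresh ones entering at the inflow side and
    the per-area particle count stays stationary between frames.  Each
    particle's frame-b position is its frame-a position plus the field
    evaluated there (first-order transport, adequate for the <= 8 px
    displacements of interest).
    """
    p = params or ParticleImageParams()
    if p.density <= 0:
        raise ValueError(f"particle density must be positive, got {p.density}")
    if p.diameter < 2.0:
        raise ValueError(f"particle image diameter must be >= 2 px, got {p.diameter}")
    if p.noise_sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    H, W = field.shape
    dmax = field.max_displacement()   # also validates finiteness
    if dmax > p.max_displacement + 1e-9:
        raise ValueError(
            f"field displacement {dmax:.2f} px exceeds the stated bound "
            f"{p.max_displacement} px"
        )

    margin = math.ceil(p.max_displacement + p.diameter)
    n = int(round(p.density * (H + 2 * margin) * (W + 2 * margin)))
    if n == 0:
        raise ValueError("density yields zero particles on this domain")

    rng = np.random.default_rng(seed)
    pos_a = np.column_stack(
        [
            rng.uniform(-margin, W + margin, n),
            rng.uniform(-margin, H + margin, n),
        ]
    )
    dx, dy = field(pos_a[:, 0], pos_a[:, 1])
    pos_b = pos_a + np.column_stack([dx, dy])

    def finish(img: np.ndarray) -> np.ndarray:
        if p.noise_sigma > 0:
            img = img + rng.normal(0.0, p.noise_sigma, img.shape)
        return np.clip(np.rint(img), 0, 255).astype(np.uint8)

    frame_a = finish(_render_particles(pos_a, (H, W), p.diameter, p.peak_intensity))
    frame_b = finish(_render_particles(pos_b, (H, W), p.diameter, p.peak_intensity))
    return ParticleImagePair(frame_a=frame_a, frame_b=frame_b, truth=field,
                             params=p, seed=seed)


# --------------------------------------------------------------------------
# vessel phantoms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RingSpec:
    """One concentric ring of vessels: placement radius and size range."""

    radius: float                   # px from stem centre
    count: int
    semi_major: tuple[float, float] = (10.0, 28.0)   # px, uniform range
    axis_ratio: tuple[float, float] = (0.6, 1.0)     # b/a, uniform range


def default_ring_specs() -> list[RingSpec]:
    """Four rings (I inner .. IV outer) at 100/200/300/400 px.

    At the 0.692 µm/px calibration of the optical sections the sizes
    span vessel hydraulic diameters of roughly 8-40 µm, covering the
    metaxylem range observed for the studied stem.  Semi-axes are kept
    >= ~5 px so rasterisation error on moment-based axes stays below the
    percent level; narrower protoxylem (down to Dh 3.8 µm) exists in
    real stems but is below that raster-accuracy floor.
    """
    return [
        RingSpec(radius=100.0, count=8, semi_major=(8.0, 14.0)),
        RingSpec(radius=200.0, count=12, semi_major=(10.0, 20.0)),
        RingSpec(radius=300.0, count=16, semi_major=(12.0, 26.0)),
        RingSpec(radius=400.0, count=20, semi_major=(14.0, 30.0)),
    ]


@dataclass(frozen=True)
class VesselPhantom:
    label_image: np.ndarray     # int32 (H, W), 0 = background
    truth: pd.DataFrame         # label, ring, cx_px, cy_px, a_px, b_px, theta_rad
    pixel_size: float           # µm/px


def make_vessel_phantom(
    ring_specs: list[RingSpec] | None = None,
    seed: int = 0,
    pixel_size: float = 0.692,
    margin: int = 40,
    max_retries: int = 200,
) -> VesselPhantom:
    """Rasterise non-overlapping elliptical vessels in concentric rings.

    Vessels are placed at evenly spaced polar angles (with jittered
    angle and radius) around the stem centre; each is an ellipse with
    random semi-axes and orientation.  Overlapping placements are
    re-drawn up to ``max_retries`` times, after which generation fails —
    by construction the truth table rows correspond one-to-one to the
    consecutive positive labels of the image.
    """
    specs = ring_specs or default_ring_specs()
    if not specs:
        raise ValueError("ring_specs must be non-empty")
    rng = np.random.default_rng(seed)
    r_max = max(s.radius + s.semi_major[1] for s in specs)
    half = int(math.ceil(r_max)) + margin
    size = 2 * half + 1
    labels = np.zeros((size, size), np.int32)
    centre = float(half)

    rows = []
    label = 0
    for ring_idx, spec in enumerate(specs):
        ring_name = RING_NAMES[ring_idx % len(RING_NAMES)]
        for k in range(spec.count):
            placed = False
            for _ in range(max_retries):
                ang = 2.0 * math.pi * (k + rng.uniform(-0.25, 0.25)) / spec.count
                rad = spec.radius + rng.uniform(-0.05, 0.05) * spec.radius
                cx = centre + rad * math.cos(ang)
                cy = centre + rad * math.sin(ang)
                a = rng.uniform(*spec.semi_major)
                b = a * rng.uniform(*spec.axis_ratio)
                rot = rng.uniform(0.0, math.pi)
                # draw rotation is clockwise in the x-right/y-down frame;
                # truth stores the major-axis angle from +x in [0, pi)
                theta = (-rot) % math.pi
                rr, cc = draw_ellipse(cy, cx, b, a, shape=labels.shape,
                                      rotation=rot)
                if rr.size < 5:
                    continue
                if np.any(labels[rr, cc]):
                    continue
                label += 1
                labels[rr, cc] = label
                rows.append(
                    dict(label=label, ring=ring_name, cx_px=cx, cy_px=cy,
                         a_px=a, b_px=b, theta_rad=theta,
                         ring_radius_px=spec.radius)
                )
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place vessel {k} of ring {ring_name} "
                    f"without overlap after {max_retries} retries"
                )
    truth = pd.DataFrame(rows)
    return VesselPhantom(label_image=labels, truth=truth, pixel_size=pixel_size)


# --------------------------------------------------------------------------
# MRI phantoms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MriPhantomParams:
    """Contrast-accumulation phantom for a stem scanned every 23 min.

    Node slices accumulate stem-region signal following the saturating
    curve ``S_inf * (1 - exp(-t / tau))`` on top of the stem baseline;
    internode slices, the water reference and air stay time-constant in
    expectation.  Intensities are on an arbitrary scanner scale.
    """

    shape: tuple[int, int] = (48, 48)
    stem_base: float = 100.0
    water_mean: float = 180.0
    air_mean: float = 25.0
    accumulation_amplitude: float = 40.0   # S_inf, node slices
    tau_min: float = 90.0                  # accumulation time constant, min
    time_step_min: float = 23.0
    noise_sigma: float = 5.0
    # 1-based slice indices of nodal-plexus slices; the rest are internodes
    node_slices: tuple[int, ...] = (1, 2, 3, 4, 5, 14, 15, 16, 17, 18)


@dataclass(frozen=True)
class MriPhantomSeries:
    data: np.ndarray            # float32 (n_slices, n_times, H, W)
    masks: dict                 # name -> bool (n_slices, H, W)
    slice_class: np.ndarray     # str array, 'node' | 'internode'
    expected_stem_mean: np.ndarray    # (n_slices, n_times) noiseless truth
    params: MriPhantomParams
    seed: int

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    @property
    def times_min(self) -> np.ndarray:
        return np.arange(self.n_times) * self.params.time_step_min


def _default_masks(shape: tuple[int, int]) -> dict:
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    stem = (yy - H / 2) ** 2 + (xx - W / 2) ** 2 <= (min(H, W) / 4) ** 2
    water = (yy - H / 6) ** 2 + (xx - W / 6) ** 2 <= (min(H, W) / 10) ** 2
    # air: everything at least 2 px away from stem and water regions
    from scipy.ndimage import binary_dilation

    occupied = binary_dilation(stem | water, iterations=2)
    air = ~occupied
    return {"stem": stem, "water": water, "air": air}


def make_mri_phantom(
    n_slices: int = 18,
    n_times: int = 19,
    params: MriPhantomParams | None = None,
    seed: int = 0,
) -> MriPhantomSeries:
    """Generate the slice x time contrast-accumulation phantom.

    Default dimensions are 18 slices x 19 timepoints.  Requires at least
    one node and one internode slice among the first ``n_slices``.
    """
    p = params or MriPhantomParams()
    if n_slices < 2:
        raise ValueError("need at least 2 slices")
    if p.noise_sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    node_set = {i for i in p.node_slices if 1 <= i <= n_slices}
    if not node_set or len(node_set) == n_slices:
        raise ValueError("need at least one node and one internode slice")

    H, W = p.shape
    masks2d = _default_masks((H, W))
    if (masks2d["stem"] & masks2d["water"]).any() or (
        (masks2d["stem"] | masks2d["water"]) & masks2d["air"]
    ).any():
        raise ValueError("region masks overlap")

    slice_class = np.array(
        ["node" if (i + 1) in node_set else "internode" for i in range(n_slices)]
    )
    t = np.arange(n_times) * p.time_step_min
    accum = p.accumulation_amplitude * (1.0 - np.exp(-t / p.tau_min))
    expected = np.full((n_slices, n_times), p.stem_base)
    expected[slice_class == "node"] += accum

    rng = np.random.default_rng(seed)
    data = np.empty((n_slices, n_times, H, W), np.float32)
    base = np.where(masks2d["stem"], 0.0, np.where(masks2d["water"],
                    p.water_mean, p.air_mean))
    for i in range(n_slices):
        for k in range(n_times):
            frame = base + np.where(masks2d["stem"], expected[i, k], 0.0)
            if p.noise_sigma > 0:
                frame = frame + rng.normal(0.0, p.noise_sigma, (H, W))
            data[i, k] = np.maximum(frame, 0.0)

    masks = {name: np.broadcast_to(m, (n_slices, H, W)).copy()
             for name, m in masks2d.items()}
    return MriPhantomSeries(data=data, masks=masks, slice_class=slice_class,
                            expected_stem_mean=expected, params=p, seed=seed)
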