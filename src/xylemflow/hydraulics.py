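"""Flow-scaling mathematics for xylem vessels and chip microchannels.

Mean axial velocity from volumetric flow and total conducting area
(``U0 = Q / S``), the Reynolds number (``Re = U0 * Dh / nu``),
Reynolds-similarity matching of a plant operating point onto a Y-junction
microchannel chip, and the analytic rectangular-duct laminar profile used
as an oracle for the PIV engine.

All computations are in SI units internally.  Converters for the mixed
units that occur in practice (µm, µm/s, mL/h) live at the module boundary.
Functions warn loudly when an argument's magnitude suggests a unit slip
(e.g. a hydraulic diameter of ``46`` passed in metres instead of
``46e-6``), because the Reynolds targets are very sensitive to silent
mis-scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Kinematic viscosity of water at 26 degC, m^2/s.
NU_WATER_26C = 8.74e-7

# Unit converters (boundary only; internals are SI).
UM = 1e-6            # µm -> m
UM2 = 1e-12          # µm² -> m²
UM_PER_S = 1e-6      # µm/s -> m/s
ML_PER_H = 1.0 / 3.6e9   # m³/s -> mL/h is the inverse

__all__ = [
    "NU_WATER_26C",
    "FlowConditions",
    "DuctGeometry",
    "CHIP_OUTLET",
    "CHIP_INLET",
    "mean_velocity",
    "reynolds",
    "match_chip_operating_point",
    "rect_duct_profile",
    "m3s_to_ml_h",
    "ml_h_to_m3s",
]


def m3s_to_ml_h(q: float) -> float:
    """Convert a volumetric flow from m³/s to mL/h."""
    return q * 3.6e9


def ml_h_to_m3s(q: float) -> float:
    """Convert a volumetric flow from mL/h to m³/s."""
    return q / 3.6e9


def _warn_if_suspicious(name: str, value: float, limit: float, unit: str) -> None:
    if value > limit:
        warnings.warn(
            f"{name} = {value:g} {unit} is implausibly large; "
            f"did you pass µm where m are expected?",
            stacklevel=3,
        )


def mean_velocity(Q: float, S: float) -> float:
    """Mean flow velocity ``U0 = Q / S`` in m/s.

    Parameters
    ----------
    Q : volumetric flow through the conducting system, m³/s (>= 0).
    S : total conducting cross-sectional area, m² (> 0).
    """
    if S <= 0:
        raise ValueError(f"cross-sectional area must be positive, got {S}")
    if Q < 0:
        raise ValueError(f"volumetric flow must be non-negative, got {Q}")
    _warn_if_suspicious("S", S, 1.0, "m^2")
    return Q / S


def reynolds(U0: float, Dh: float, nu: float = NU_WATER_26C) -> float:
    """Reynolds number ``Re = U0 * Dh / nu`` (dimensionless).

    ``Dh = 0`` is allowed (degenerate conduit) and gives ``Re = 0``.
    """
    if U0 < 0 or Dh < 0:
        raise ValueError("velocity and hydraulic diameter must be non-negative")
    if nu <= 0:
        raise ValueError(f"kinematic viscosity must be positive, got {nu}")
    _warn_if_suspicious("Dh", Dh, 0.1, "m")
    _warn_if_suspicious("U0", U0, 10.0, "m/s")
    return U0 * Dh / nu


@dataclass(frozen=True)
class DuctGeometry:
    """Rectangular duct cross-section, SI units.

    The chip outlet of the Y-junction prototype is 120 x 240 µm
    (aspect 1:2); its inlets are 120 µm squares.
    """

    width: float   # m, the longer side unless square
    height: float  # m

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("duct sides must be positive")
        _warn_if_suspicious("duct side", max(self.width, self.height), 0.1, "m")

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def perimeter(self) -> float:
        return 2.0 * (self.width + self.height)

    @property
    def hydraulic_diameter(self) -> float:
        return 4.0 * self.area / self.perimeter

    @property
    def aspect_ratio(self) -> float:
        return max(self.width, self.height) / min(self.width, self.height)


#: Outlet duct of the Y-junction chip: 120 x 240 µm rectangle.
CHIP_OUTLET = DuctGeometry(width=240e-6, height=120e-6)
#: Inlet ducts of the chip: 120 µm squares.
CHIP_INLET = DuctGeometry(width=120e-6, height=120e-6)


@dataclass
class FlowConditions:
    """A self-consistent flow operating point in SI units.

    Any of ``U0`` may be derived from ``Q`` and ``S``; ``Re`` is always
    derived from ``U0``, ``Dh`` and ``nu``.
    """

    nu: float = NU_WATER_26C        # m²/s
    Q: float | None = None          # m³/s
    S: float | None = None          # m²
    U0: float | None = None         # m/s
    Dh: float | None = None         # m
    Re: float | None = field(default=None, init=False)

    def __post_init__(self) -> None:
        if self.U0 is None and self.Q is not None and self.S is not None:
            self.U0 = mean_velocity(self.Q, self.S)
        if self.U0 is not None and self.S is not None and self.Q is None:
            self.Q = self.U0 * self.S
        if self.U0 is not None and self.Dh is not None:
            self.Re = reynolds(self.U0, self.Dh, self.nu)


def match_chip_operating_point(
    target_Re: float,
    chip: DuctGeometry = CHIP_OUTLET,
    nu: float = NU_WATER_26C,
    ratio_R: float = 1.0,
) -> dict:
    """Chip mean velocity and inlet flow rates that reproduce ``target_Re``.

    Inverts ``Re = U * Dh / nu`` for the chip's hydraulic diameter and
    splits the total flow ``Q`` between the two inlets according to the
    inlet flow ratio ``R = Q2/Q1`` with ``Q1 + Q2 = Q``.

    Returns a dict with ``U_chip`` (m/s), ``Q`` (m³/s), ``Q1``/``Q2``
    (m³/s) and ``Q1_ml_h``/``Q2_ml_h`` (mL/h).
    """
    if target_Re < 0:
        raise ValueError(f"target Reynolds number must be >= 0, got {target_Re}")
    if not 0 < ratio_R <= 1:
        raise ValueError(f"inlet ratio R must lie in (0, 1], got {ratio_R}")
    Dh = chip.hydraulic_diameter
    if Dh <= 0:
        raise ValueError("degenerate chip geometry")
    U_chip = target_Re * nu / Dh
    Q = U_chip * chip.area
    Q1 = Q / (1.0 + ratio_R)
    Q2 = ratio_R * Q / (1.0 + ratio_R)
    return {
        "U_chip": U_chip,
        "Dh_chip": Dh,
        "Q": Q,
        "Q1": Q1,
        "Q2": Q2,
        "Q_ml_h": m3s_to_ml_h(Q),
        "Q1_ml_h": m3s_to_ml_h(Q1),
        "Q2_ml_h": m3s_to_ml_h(Q2),
        "Re": target_Re,
        "ratio_R": ratio_R,
    }


def rect_duct_profile(
    geometry: DuctGeometry,
    U0: float = 1.0,
    truncation_N: int = 101,
    grid: int = 201,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Fully developed laminar velocity field in a rectangular duct.

    Evaluates the classical Fourier-series solution for pressure-driven
    laminar flow in a duct of half-width ``a`` (long side) and half-height
    ``b`` (short side),

        u(y, z) ~ sum over odd n of
            (1/n³) [1 − cosh(nπy/2b)/cosh(nπa/2b)] cos(nπz/2b),

    on a ``grid x grid`` mesh, then rescales so the cross-section mean
    equals ``U0``.

    Parameters
    ----------
    truncation_N : number of odd series terms (>= 25). The result is
        convergence-checked against half the terms; failure to agree to
        0.1 % on the max/mean ratio raises.

    Returns
    -------
    (y, z, u, max_over_mean) : coordinate vectors (m), the velocity field
        with mean ``U0``, and the centerline-maximum to mean ratio.
    """
    if truncation_N < 25:
        raise ValueError("truncation_N must be >= 25 odd terms")
    long_side = max(geometry.width, geometry.height)
    short_side = min(geometry.width, geometry.height)
    a = long_side / 2.0
    b = short_side / 2.0
    y = np.linspace(-a, a, grid)
    z = np.linspace(-b, b, grid)

    def _series(n_terms: int) -> np.ndarray:
        Y, Z = np.meshgrid(y, z, indexing="ij")
        u = np.zeros_like(Y)
        for k in range(n_terms):
            n = 2 * k + 1
            beta = n * np.pi / (2.0 * b)
            # cosh ratio computed via exp to stay finite for large n*a/b
            ratio = np.exp(beta * (np.abs(Y) - a)) * (
                (1.0 + np.exp(-2.0 * beta * np.abs(Y)))
                / (1.0 + np.exp(-2.0 * beta * a))
            )
            sign = (-1.0) ** k  # sin(nπ/2) for odd n
            u += sign / n**3 * (1.0 - ratio) * np.cos(beta * Z)
        return u

    def _max_over_mean(u: np.ndarray) -> float:
        mean = np.trapezoid(np.trapezoid(u, z, axis=1), y) / (4.0 * a * b)
        return float(u.max() / mean)

    u_full = _series(truncation_N)
    r_full = _max_over_mean(u_full)
    r_half = _max_over_mean(_series(max(truncation_N // 2, 13)))
    if abs(r_full - r_half) / r_full > 1e-3:
        raise ValueError(
            f"series not converged to 0.1% at N={truncation_N} terms "
            f"(ratio {r_full:.5f} vs {r_half:.5f} at half the terms)"
        )

    mean = np.trapezoid(np.trapezoid(u_full, z, axis=1), y) / (4.0 * a * b)
    u_scaled = u_full * (U0 / mean)
    return y, z, u_scaled, r_full
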